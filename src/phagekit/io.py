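"""Readers and writers for the pipeline's plain-text formats.

FASTA handling goes through Biopython; distance matrices support PHYLIP
square and TSV dialects; tabular inputs (measurements, links, host maps,
contig metadata) are TSV via pandas; orthogroup tables follow the
OrthoFinder ``Orthogroups.tsv`` dialect (one column per genome, comma-space
separated gene lists).  Readers reject malformed input rather than coercing
it; every writer produces files its own reader accepts.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .comparative import OrthogroupTable
from .cophylogeny import AssociationMatrix, DistanceMatrix
from .errors import ParseError
from .geometry import CapsidMeasurement
from .triage import ContigRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_links",
    "read_orthogroups",
    "read_host_map",
    "read_measurements",
    "read_contigs",
    "write_manifest",
]


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str


def read_fasta(path: str | Path, dna: bool = True) -> list[FastaRecord]:
    """Read a FASTA file into (id, sequence) records.

    Sequences are upper-cased; U is mapped to T with a warning when ``dna``.
    An empty file yields an empty list with a warning; text before the first
    header is a parse error carrying the line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: expected FASTA header, got {line.strip()[:40]!r}"
                )
            break
        else:
            logger.warning("%s: empty FASTA file", path)
            return []
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if dna and "U" in seq:
            logger.warning("%s: sequence %s contains U; mapped to T", path, rec.id)
            seq = seq.replace("U", "T")
        records.append(FastaRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[FastaRecord | tuple[str, str]],
                path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, FastaRecord):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# distance matrices


def _symmetrize(path: Path, labels: list[str], values: np.ndarray
                ) -> DistanceMatrix:
    asym = float(np.abs(values - values.T).max()) if values.size else 0.0
    if asym > 1e-6:
        raise ParseError(f"{path}: matrix asymmetric beyond tolerance ({asym:.2g})")
    if asym > 1e-8:
        logger.warning("%s: symmetrizing matrix (max asymmetry %.2g)", path, asym)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values)


def read_distance_matrix(path: str | Path, dialect: str = "phylip_square"
                         ) -> DistanceMatrix:
    """Read a labelled square distance matrix (``phylip_square`` or ``tsv``)."""
    path = Path(path)
    if dialect == "phylip_square":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise ParseError(f"{path}: empty PHYLIP file")
        try:
            n = int(lines[0].split()[0])
        except ValueError as exc:
            raise ParseError(f"{path}:1: expected taxon count") from exc
        if len(lines) - 1 != n:
            raise ParseError(f"{path}: expected {n} rows, found {len(lines) - 1}")
        labels, rows = [], []
        for i, line in enumerate(lines[1:], start=2):
            parts = line.split()
            if len(parts) != n + 1:
                raise ParseError(
                    f"{path}:{i}: expected label plus {n} values, got "
                    f"{len(parts)} fields"
                )
            labels.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-numeric distance") from exc
        return _symmetrize(path, labels, np.array(rows))
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ParseError(f"{path}: matrix is not square {df.shape}")
        if list(df.index) != list(df.columns):
            raise ParseError(f"{path}: row and column labels differ")
        return _symmetrize(path, [str(x) for x in df.index],
                           df.to_numpy(dtype=float))
    raise ParseError(f"unknown distance-matrix dialect {dialect!r}")


def write_distance_matrix(d: DistanceMatrix, path: str | Path,
                          dialect: str = "phylip_square") -> None:
    path = Path(path)
    if dialect == "phylip_square":
        with open(path, "w") as fh:
            fh.write(f"{d.n}\n")
            for label, row in zip(d.labels, d.values):
                vals = " ".join(f"{x:.10g}" for x in row)
                fh.write(f"{label:<12s} {vals}\n")
    elif dialect == "tsv":
        pd.DataFrame(d.values, index=list(d.labels),
                     columns=list(d.labels)).to_csv(path, sep="\t")
    else:
        raise ParseError(f"unknown distance-matrix dialect {dialect!r}")


# ---------------------------------------------------------------------------
# tabular inputs


def read_links(path: str | Path,
               parasite_labels: Sequence[str] | None = None,
               host_labels: Sequence[str] | None = None) -> AssociationMatrix:
    """TSV with columns parasite_id, host_id (header optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    first = df.iloc[0]
    if {str(first[0]).lower(), str(first[1]).lower()} & {"parasite_id", "phage_id"}:
        df = df.iloc[1:]
    pairs = [(str(r[0]).strip(), str(r[1]).strip())
             for r in df.itertuples(index=False)]
    return AssociationMatrix.from_pairs(pairs, parasite_labels, host_labels)


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """OrthoFinder ``Orthogroups.tsv``: first column the orthogroup id, one
    column per genome, cells are comma-space gene lists (empty allowed)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need an orthogroup column plus genome columns")
    og_col = df.columns[0]
    genomes = [str(c) for c in df.columns[1:]]
    groups: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = str(row[og_col]).strip()
        if not og:
            raise ParseError(f"{path}: empty orthogroup id")
        if og in groups:
            raise ParseError(f"{path}: duplicate orthogroup id {og!r}")
        groups[og] = {
            g: [x.strip() for x in str(row[g]).split(",") if x.strip()]
            for g in genomes
        }
    try:
        return OrthogroupTable(groups, genomes=genomes)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_host_map(path: str | Path) -> dict[str, str]:
    """TSV with columns genome_id, host_id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    first = df.iloc[0]
    if str(first[0]).lower() == "genome_id":
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    for r in df.itertuples(index=False):
        g, h = str(r[0]).strip(), str(r[1]).strip()
        if g in mapping and mapping[g] != h:
            raise ParseError(f"{path}: genome {g!r} mapped to two hosts")
        mapping[g] = h
    return mapping


def read_measurements(path: str | Path
                      ) -> list[tuple[CapsidMeasurement, int]]:
    """TSV with columns phage_id, diameter_nm, diameter_sd_nm, tail_nm,
    genome_bp.  Returns (measurement, genome_length) pairs."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"phage_id", "diameter_nm", "genome_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        m = CapsidMeasurement(
            phage_id=str(row["phage_id"]),
            circumscribed_diameter=float(row["diameter_nm"]),
            diameter_sd=(float(row["diameter_sd_nm"])
                         if "diameter_sd_nm" in df.columns
                         and pd.notna(row.get("diameter_sd_nm")) else None),
            tail_length=(float(row["tail_nm"]) if "tail_nm" in df.columns
                         and pd.notna(row.get("tail_nm")) else None),
        )
        out.append((m, int(row["genome_bp"])))
    return out


_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """TSV with columns contig_id, sample_id, length, viral, coverage,
    completeness."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"contig_id", "sample_id", "length", "viral", "coverage",
                "completeness"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        vs = str(row["viral"]).strip().lower()
        if vs in _TRUE:
            viral = True
        elif vs in _FALSE:
            viral = False
        else:
            raise ParseError(f"{path}: row {i}: viral flag {row['viral']!r} "
                             "is not boolean")
        records.append(ContigRecord(
            contig_id=str(row["contig_id"]),
            sample_id=str(row["sample_id"]),
            length=int(row["length"]),
            viral=viral,
            coverage=float(row["coverage"]),
            completeness=str(row["completeness"]).strip().lower(),
        ))
    return records


# ---------------------------------------------------------------------------
# run manifests


def write_manifest(path: str | Path, command: str, inputs: dict,
                   config: dict) -> None:
    """JSON record of a pipeline invocation: inputs, configuration, versions."""
    import phagekit

    manifest = {
        "command": command,
        "inputs": inputs,
        "config": config,
        "phagekit_version": phagekit.__version__,
        "python_version": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
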