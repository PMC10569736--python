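"""Comparative genomics: orthogroup filters, fragment ANI, species calls.

Orthogroup operations consume an OrthoFinder-style table (orthogroup ->
genome -> genes) plus a genome-to-host map, and extract host-exclusive
orthogroups and gene-duplication retention signals.  Average nucleotide
identity uses the classic fragment scheme: the query is cut into ~1 kb
pieces, each is located on the reference by exact-seed matching and aligned;
retained fragments give the mean identity and the aligned coverage, which
feed the ICTV-style species rule (>= 95 % identity over >= 85 % coverage).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import edlib

from .errors import InvalidInputError, LabelError

__all__ = [
    "OrthogroupTable",
    "AniResult",
    "host_specific_orthogroups",
    "duplication_flag",
    "compute_ani",
    "species_call",
]


@dataclass(frozen=True)
class OrthogroupTable:
    """orthogroup_id -> {genome_id -> tuple of gene ids}; genes unique."""

    groups: Mapping[str, Mapping[str, tuple[str, ...]]]
    genomes: tuple[str, ...]

    def __init__(self, groups: Mapping[str, Mapping[str, Sequence[str]]],
                 genomes: Optional[Sequence[str]] = None):
        frozen: dict[str, dict[str, tuple[str, ...]]] = {}
        seen: dict[str, str] = {}
        universe: list[str] = list(genomes) if genomes is not None else []
        known = set(universe)
        for og, members in groups.items():
            row: dict[str, tuple[str, ...]] = {}
            for genome, genes in members.items():
                if genomes is not None and genome not in known:
                    raise InvalidInputError(
                        f"genome {genome!r} in orthogroup {og!r} is outside "
                        f"the genome universe"
                    )
                if genomes is None and genome not in known:
                    known.add(genome)
                    universe.append(genome)
                genes = tuple(genes)
                for g in genes:
                    if g in seen:
                        raise InvalidInputError(
                            f"gene {g!r} appears in both {seen[g]!r} and {og!r}"
                        )
                    seen[g] = og
                row[genome] = genes
            frozen[og] = row
        object.__setattr__(self, "groups", frozen)
        object.__setattr__(self, "genomes", tuple(universe))

    def member_genomes(self, og: str) -> list[str]:
        if og not in self.groups:
            raise LabelError(f"unknown orthogroup {og!r}")
        return [g for g, genes in self.groups[og].items() if genes]


def host_specific_orthogroups(
    table: OrthogroupTable,
    host_map: Mapping[str, str],
    host: str,
    min_genomes: int = 2,
) -> set[str]:
    """Orthogroups whose member genes all come from genomes of one host.

    Returns the orthogroups where every genome contributing a gene maps to
    ``host`` and at least ``min_genomes`` distinct genomes contribute.
    """
    if host not in set(host_map.values()):
        raise LabelError(f"host {host!r} not present in the host map")
    out: set[str] = set()
    for og in table.groups:
        members = table.member_genomes(og)
        if len(members) < min_genomes:
            continue
        try:
            hosts = {host_map[g] for g in members}
        except KeyError as exc:
            raise LabelError(f"genome missing from host map: {exc}") from exc
        if hosts == {host}:
            out.add(og)
    return out


def duplication_flag(
    table: OrthogroupTable,
    og: str,
    retention_threshold: float = 0.5,
) -> tuple[bool, float]:
    """Fraction of member genomes retaining >= 2 gene copies, and whether it
    reaches ``retention_threshold`` (inclusive)."""
    members = table.member_genomes(og)
    if not members:
        return False, 0.0
    n_dup = sum(1 for g in members if len(table.groups[og][g]) >= 2)
    frac = n_dup / len(members)
    return frac >= retention_threshold, frac


# ---------------------------------------------------------------------------
# fragment-based ANI


@dataclass(frozen=True)
class AniResult:
    """Mean identity of retained fragments (%) and aligned query coverage (%).

    ``identity_percent`` is NaN when no fragment was retained.
    """

    identity_percent: float
    coverage_percent: float
    n_fragments: int
    n_retained: int

    @property
    def identity_defined(self) -> bool:
        return not math.isnan(self.identity_percent)


def _kmer_index(seq: str, k: int, max_hits: int = 8) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        hits = index.setdefault(kmer, [])
        if len(hits) < max_hits:
            hits.append(i)
    return index


def _best_band(fragment: str, index: Mapping[str, list[int]], k: int,
               probe_step: int, band_width: int) -> Optional[int]:
    """Diagonal (reference offset) receiving the most exact k-mer seeds."""
    votes: Counter[int] = Counter()
    diags: dict[int, int] = {}
    for i in range(0, len(fragment) - k + 1, probe_step):
        for pos in index.get(fragment[i:i + k], ()):
            diag = pos - i
            band = diag // band_width
            votes[band] += 1
            diags.setdefault(band, diag)
    if not votes:
        return None
    best = votes.most_common(1)[0][0]
    return diags[best]


def compute_ani(
    query: str,
    reference: str,
    fragment_length: int = 1020,
    min_fragment_identity: float = 30.0,
    min_fragment_cover: float = 0.7,
    seed_k: int = 15,
    band_margin: int = 100,
) -> AniResult:
    """Fragment-based average nucleotide identity of ``query`` vs ``reference``.

    The query is cut into consecutive ``fragment_length`` pieces (a trailing
    remnant shorter than the seed length is merged into the previous piece).
    Each piece is placed on the reference by exact ``seed_k``-mer voting over
    diagonals and aligned end-to-end within the winning band; unseeded pieces
    are unaligned.  Pieces passing the identity and cover filters are
    retained; identity is their mean identity and coverage the retained
    fraction of the query length.
    """
    query = query.upper()
    reference = reference.upper()
    if not query or not reference:
        raise InvalidInputError("query and reference must be non-empty")
    index = _kmer_index(reference, seed_k)
    starts = list(range(0, len(query), fragment_length))
    bounds = [(s, min(s + fragment_length, len(query))) for s in starts]
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < seed_k:
        last = bounds.pop()
        bounds[-1] = (bounds[-1][0], last[1])

    identities: list[float] = []
    retained_len = 0
    total_len = len(query)
    for lo, hi in bounds:
        frag = query[lo:hi]
        if len(frag) < seed_k:
            continue
        diag = _best_band(frag, index, seed_k, probe_step=max(1, seed_k // 2),
                          band_width=band_margin)
        if diag is None:
            continue
        w_lo = max(0, diag - band_margin)
        w_hi = min(len(reference), diag + len(frag) + band_margin)
        res = edlib.align(frag, reference[w_lo:w_hi], mode="HW", task="distance")
        dist = res["editDistance"]
        if dist < 0:
            continue
        identity = max(0.0, 100.0 * (len(frag) - dist) / len(frag))
        cover = 1.0  # end-to-end placement aligns the whole fragment
        if identity >= min_fragment_identity and cover >= min_fragment_cover:
            identities.append(identity)
            retained_len += len(frag)
    n_frag = len(bounds)
    if not identities:
        return AniResult(float("nan"), 0.0, n_frag, 0)
    return AniResult(
        identity_percent=float(sum(identities) / len(identities)),
        coverage_percent=100.0 * retained_len / total_len,
        n_fragments=n_frag,
        n_retained=len(identities),
    )


def species_call(
    result: AniResult,
    min_identity: float = 95.0,
    min_coverage: float = 85.0,
) -> Optional[bool]:
    """ICTV-style same-species decision: identity >= 95 % over >= 85 %
    coverage (both inclusive).  Returns None when identity is undefined."""
    if not result.identity_defined:
        return None
    return bool(
        result.identity_percent >= min_identity
        and result.coverage_percent >= min_coverage
    )
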