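"""Seeded generators emulating each analysis stage's inputs.

These generators reproduce the statistical structure the real inputs carry —
codon alignments diverged at a controlled dN/dS ratio, host/parasite distance
structures that are congruent or independent, normally-noised TEM capsid
measurements, and contig metadata tables with a planted complete genome — so
every pipeline stage can be exercised and calibrated without downloads.
All outputs are bit-reproducible under a fixed seed, and every generator
records its ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.spatial.distance import pdist, squareform

from .codonsel import SENSE_CODONS, CodonAlignment, is_transition
from .cophylogeny import AssociationMatrix, DistanceMatrix
from .errors import InvalidInputError
from .geometry import CapsidMeasurement
from .triage import ContigRecord

__all__ = [
    "SimulationConfig",
    "sim_codon_alignment",
    "sim_cophylo_system",
    "sim_capsid_measurements",
    "sim_contig_table",
    "SimulatedContigs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs for all generators.

    ``omega`` is the nonsynonymous/synonymous rate ratio of the codon
    simulator; ``kappa`` the transition/transversion rate ratio (default 1 so
    the neutral condition omega=1 makes synonymous and nonsynonymous rates
    per site exactly equal under degeneracy-class counting); ``branch_length``
    is expected substitutions per nucleotide site from the ancestor to each
    tip of the star tree.  ``congruence_mode`` picks how host and parasite
    distance structures relate.
    """

    seed: int = 0
    n_sequences: int = 10
    n_codons: int = 300
    n_hosts: int = 6
    n_parasites: int = 6
    genome_length: int = 100_000
    n_samples: int = 10
    omega: float = 1.0
    kappa: float = 1.0
    branch_length: float = 0.1
    mutation_rate: float = 0.02
    congruence_mode: str = "independent"
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise InvalidInputError("omega must be > 0")
        if self.kappa <= 0 or self.branch_length < 0 or self.mutation_rate < 0:
            raise InvalidInputError("rates must be non-negative (kappa > 0)")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.congruence_mode not in ("congruent", "independent", "noisy"):
            raise InvalidInputError(
                f"unknown congruence_mode {self.congruence_mode!r}"
            )

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# codon alignments


@lru_cache(maxsize=16)
def _transition_matrix(omega: float, kappa: float, branch_length: float
                       ) -> np.ndarray:
    """P = expm(Q b) for the 61-state codon process.

    Single-base exchanges get rate kappa (transition) or 1 (transversion),
    scaled by omega when the amino acid changes; multi-base exchanges are
    forbidden; stop codons are unreachable.  Q is scaled so one unit of
    branch length is one expected substitution per nucleotide site (three per
    codon) at the uniform stationary distribution.
    """
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    fwd = unambiguous_dna_by_id[1].forward_table
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            rate = kappa if is_transition(ci[k], cj[k]) else 1.0
            if fwd[ci] != fwd[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -q.diagonal().mean()  # per codon under uniform stationarity
    q *= 3.0 / mean_rate
    return expm(q * branch_length)


def sim_codon_alignment(cfg: SimulationConfig) -> CodonAlignment:
    """Evolve ``n_sequences`` codon sequences on a star tree.

    The ancestor is uniform over sense codons; each tip diverges
    ``branch_length`` expected substitutions per site under the
    omega/kappa-scaled codon process.  The true omega is recorded in
    ``meta``.
    """
    if cfg.n_sequences < 2 or cfg.n_codons < 1:
        raise InvalidInputError("need n_sequences >= 2 and n_codons >= 1")
    rng = np.random.default_rng(cfg.seed)
    n_states = len(SENSE_CODONS)
    ancestor = rng.integers(n_states, size=cfg.n_codons)
    if cfg.branch_length == 0:
        tips = np.tile(ancestor, (cfg.n_sequences, 1))
    else:
        p = _transition_matrix(cfg.omega, cfg.kappa, cfg.branch_length)
        cum = np.cumsum(p, axis=1)
        tips = np.empty((cfg.n_sequences, cfg.n_codons), dtype=np.int64)
        for s in range(cfg.n_sequences):
            u = rng.random(cfg.n_codons)
            rows = cum[ancestor]  # (n_codons, 61)
            tips[s] = (u[:, None] > rows).sum(axis=1)
    ids = [f"seq{i:03d}" for i in range(cfg.n_sequences)]
    rows = ["".join(SENSE_CODONS[k] for k in tip) for tip in tips]
    return CodonAlignment(
        ids, rows,
        meta={
            "true_omega": cfg.omega,
            "kappa": cfg.kappa,
            "branch_length": cfg.branch_length,
            "seed": cfg.seed,
        },
    )


# ---------------------------------------------------------------------------
# cophylogenetic systems


def _euclidean_distances(rng: np.random.Generator, labels: list[str],
                         n_dim: int = 3) -> DistanceMatrix:
    pts = rng.normal(size=(len(labels), n_dim))
    return DistanceMatrix(labels, squareform(pdist(pts)))


def sim_cophylo_system(
    cfg: SimulationConfig,
) -> tuple[DistanceMatrix, DistanceMatrix, AssociationMatrix]:
    """Host distances, parasite distances, and links under a chosen regime.

    ``congruent`` (or ``noisy`` with ``noise_sd`` > 0): parasite distances
    copy the host distances plus symmetric Gaussian noise floored at zero,
    with one-to-one links (requires n_hosts == n_parasites).  ``independent``:
    the two distance structures are drawn independently and each parasite is
    linked to one uniformly chosen host.
    """
    if cfg.n_hosts < 3 or cfg.n_parasites < 3:
        raise InvalidInputError("need at least 3 hosts and 3 parasites")
    rng = np.random.default_rng(cfg.seed)
    hosts = [f"H{i:02d}" for i in range(cfg.n_hosts)]
    parasites = [f"P{i:02d}" for i in range(cfg.n_parasites)]
    host_d = _euclidean_distances(rng, hosts)
    if cfg.congruence_mode in ("congruent", "noisy"):
        if cfg.n_hosts != cfg.n_parasites:
            raise InvalidInputError(
                "congruent mode requires n_hosts == n_parasites"
            )
        values = host_d.values.copy()
        if cfg.noise_sd > 0:
            noise = rng.normal(scale=cfg.noise_sd,
                               size=(cfg.n_parasites, cfg.n_parasites))
            noise = (noise + noise.T) / 2.0
            np.fill_diagonal(noise, 0.0)
            values = np.clip(values + noise, 0.0, None)
            np.fill_diagonal(values, 0.0)
        parasite_d = DistanceMatrix(parasites, values)
        links = np.eye(cfg.n_parasites)
    else:
        parasite_d = _euclidean_distances(rng, parasites)
        links = np.zeros((cfg.n_parasites, cfg.n_hosts))
        links[np.arange(cfg.n_parasites),
              rng.integers(cfg.n_hosts, size=cfg.n_parasites)] = 1.0
    return host_d, parasite_d, AssociationMatrix(parasites, hosts, links)


# ---------------------------------------------------------------------------
# capsid measurements


def sim_capsid_measurements(
    true_diameter: float,
    sd: float,
    n: int,
    seed: int = 0,
    phage_id: str = "sim",
) -> CapsidMeasurement:
    """Mean and SD of ``n`` Gaussian diameter draws, rounded to whole nm as
    TEM studies report them."""
    if n < 1:
        raise InvalidInputError("need n >= 1 virions")
    if sd < 0:
        raise InvalidInputError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    draws = rng.normal(true_diameter, sd, size=n) if sd > 0 else np.full(
        n, float(true_diameter))
    mean = float(np.round(draws.mean()))
    spread = float(np.round(draws.std(ddof=1))) if n > 1 else 0.0
    return CapsidMeasurement(
        phage_id=phage_id,
        circumscribed_diameter=mean,
        diameter_sd=spread,
        n_virions=n,
    )


# ---------------------------------------------------------------------------
# contig tables


@dataclass(frozen=True)
class SimulatedContigs:
    """Generated contig records plus the planted truth per sample."""

    records: tuple[ContigRecord, ...]
    planted: dict[str, str] = field(compare=False)


def sim_contig_table(cfg: SimulationConfig, min_length: int = 90_000
                     ) -> SimulatedContigs:
    """Per sample, one planted complete genome among single-fault decoys.

    The planted contig passes every criterion (length > ``min_length``,
    viral, complete, top coverage).  Each decoy violates exactly one: too
    short, non-viral, not classified complete, or lower coverage than the
    planted contig.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[ContigRecord] = []
    planted: dict[str, str] = {}
    for s in range(cfg.n_samples):
        sample = f"S{s:03d}"
        true_id = f"{sample}_u1"
        cov = float(rng.uniform(200.0, 1000.0))
        length = int(rng.integers(min_length + 5_000, min_length + 15_000))
        records.append(ContigRecord(true_id, sample, length, True, cov, "complete"))
        planted[sample] = true_id
        low_cov = float(cov * rng.uniform(0.2, 0.8))
        decoys = [
            # too short
            ContigRecord(f"{sample}_u2", sample,
                         int(rng.integers(10_000, min_length - 1)),
                         True, float(cov * rng.uniform(1.5, 3.0)), "complete"),
            # non-viral
            ContigRecord(f"{sample}_u3", sample,
                         int(rng.integers(min_length + 1, min_length + 30_000)),
                         False, float(cov * rng.uniform(1.5, 3.0)), "complete"),
            # not complete
            ContigRecord(f"{sample}_u4", sample,
                         int(rng.integers(min_length + 1, min_length + 30_000)),
                         True, float(cov * rng.uniform(1.5, 3.0)), "high"),
            # lower coverage
            ContigRecord(f"{sample}_u5", sample,
                         int(rng.integers(min_length + 1, min_length + 30_000)),
                         True, low_cov, "complete"),
        ]
        records.extend(decoys)
    return SimulatedContigs(records=tuple(records), planted=planted)
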