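"""Pairwise dN/dS estimation (Li-Wu-Luo) and the codon-based z-test.

Every codon position is classified by degeneracy: nondegenerate (no
single-base change is synonymous), twofold (some but not all are), or
fourfold (all three are).  Transitions and transversions between two aligned
sequences are tallied per degeneracy class; codons differing at more than one
position are resolved by averaging over all minimal mutational pathways that
avoid stop codons, each pathway weighted equally.  A Kimura two-parameter
correction per class yields the synonymous (dS, per synonymous site) and
nonsynonymous (dN, per nonsynonymous site) substitution estimates:

    dS = (L2 A2 + L4 K4) / (L2/3 + L4)
    dN = (L2 B2 + L0 K0) / (2 L2/3 + L0)

with L0/L2/L4 the mean per-class site counts of the pair, A the
transitional and B the transversional component of the K2P distance, and
K = A + B.

The z-test of strict neutrality (dN = dS) averages dN and dS over all valid
sequence pairs and estimates the standard error of the difference by
bootstrap over codon columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy.stats import norm

from .errors import (
    ClassificationError,
    DegenerateVarianceError,
    InvalidInputError,
    UntestableError,
)

__all__ = [
    "CodonAlignment",
    "SiteCounts",
    "PairwiseKaKs",
    "SelectionTest",
    "classify_degeneracy",
    "pairwise_kaks",
    "codon_ztest",
    "ALTERNATIVES",
]

_BASES = "TCAG"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

_STANDARD = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(b1 + b2 + b3
           for b1 in _BASES for b2 in _BASES for b3 in _BASES
           if b1 + b2 + b3 not in STOP_CODONS)
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

ALTERNATIVES = ("dN_gt_dS", "dN_lt_dS", "two_sided")


def _aa(codon: str) -> str:
    return _STANDARD.forward_table[codon]


def is_transition(a: str, b: str) -> bool:
    """True when a<->b is purine<->purine or pyrimidine<->pyrimidine."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


@lru_cache(maxsize=None)
def classify_degeneracy(codon: str) -> tuple[int, int, int]:
    """Degeneracy class (0, 2 or 4) of each position of a sense codon.

    A position is 4-fold when all three single-base changes are synonymous,
    0-fold when none is, 2-fold otherwise (changes to stop codons count as
    nonsynonymous).
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ClassificationError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ClassificationError(f"stop codon {codon!r} has no degeneracy class")
    aa0 = _aa(codon)
    classes = []
    for pos in range(3):
        n_syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut not in STOP_CODONS and _aa(mut) == aa0:
                n_syn += 1
        classes.append(4 if n_syn == 3 else (0 if n_syn == 0 else 2))
    return tuple(classes)


def _site_vector(codon: str) -> np.ndarray:
    """Counts of (0-fold, 2-fold, 4-fold) positions; sums to 3."""
    v = np.zeros(3)
    for cls in classify_degeneracy(codon):
        v[{0: 0, 2: 1, 4: 2}[cls]] += 1.0
    return v


def _step_counts(cur: str, nxt: str, pos: int) -> np.ndarray:
    """Per-class transition/transversion tally for a single-base step.

    The degeneracy of the changing position generally differs between the two
    codons; half a count is attributed to each codon's class.  Layout:
    [S0, S2, S4, V0, V2, V4].
    """
    out = np.zeros(6)
    offset = 0 if is_transition(cur[pos], nxt[pos]) else 3
    for codon in (cur, nxt):
        cls = classify_degeneracy(codon)[pos]
        out[offset + {0: 0, 2: 1, 4: 2}[cls]] += 0.5
    return out


def _pathway_average(c1: str, c2: str) -> np.ndarray:
    """Mean per-class substitution counts over all stop-free minimal pathways.

    If every pathway passes through a stop codon (possible only for 3-step
    pairs), the endpoints classify each differing position directly.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return np.zeros(6)
    path_sums = []
    for order in permutations(diffs):
        cur = c1
        acc = np.zeros(6)
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            acc += _step_counts(cur, nxt, pos)
            cur = nxt
        if ok:
            path_sums.append(acc)
    if path_sums:
        return np.mean(path_sums, axis=0)
    acc = np.zeros(6)
    for pos in diffs:
        offset = 0 if is_transition(c1[pos], c2[pos]) else 3
        for codon in (c1, c2):
            cls = classify_degeneracy(codon)[pos]
            acc[offset + {0: 0, 2: 1, 4: 2}[cls]] += 0.5
    return acc


@lru_cache(maxsize=1)
def _tables() -> tuple[np.ndarray, np.ndarray]:
    """(site_counts[61, 3], pair_counts[61, 61, 6]) over sense codons."""
    sites = np.vstack([_site_vector(c) for c in SENSE_CODONS])
    pairs = np.zeros((N_SENSE, N_SENSE, 6))
    for i, c1 in enumerate(SENSE_CODONS):
        for j in range(i + 1, N_SENSE):
            pairs[i, j] = pairs[j, i] = _pathway_average(c1, SENSE_CODONS[j])
    return sites, pairs


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SiteCounts:
    """Mean per-class site totals of a sequence pair; L0+L2+L4 = 3 x codons."""

    L0: float
    L2: float
    L4: float


@dataclass(frozen=True)
class PairwiseKaKs:
    Ks: float
    Ka: float
    valid: bool


@dataclass(frozen=True)
class SelectionTest:
    mean_dN: float
    mean_dS: float
    z_statistic: float
    p_value: float
    alternative: str
    n_bootstrap: int
    seed: int
    n_pairs: int
    se: float


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame aligned coding sequences.

    Rows must be equal length, divisible by 3, contain only ACGT and gap
    characters, and carry no internal stop codons when gaps are removed.
    """

    sequence_ids: tuple[str, ...]
    codon_rows: tuple[str, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __init__(self, sequence_ids: Sequence[str], rows: Sequence[str],
                 meta: Optional[dict] = None):
        ids = tuple(str(x) for x in sequence_ids)
        rows = tuple(s.upper().replace("U", "T") for s in rows)
        if len(ids) != len(rows):
            raise InvalidInputError("ids and rows differ in number")
        if len(rows) < 2:
            raise InvalidInputError("need at least 2 sequences")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise InvalidInputError("rows are not aligned (unequal lengths)")
        (length,) = lengths
        if length % 3:
            raise InvalidInputError(f"aligned length {length} not divisible by 3")
        for sid, row in zip(ids, rows):
            bad = set(row) - set("ACGT-.")
            if bad:
                raise InvalidInputError(
                    f"{sid}: unexpected characters {sorted(bad)} in codon alignment"
                )
            ungapped = row.replace("-", "").replace(".", "")
            for k in range(0, len(ungapped) - 3, 3):
                if ungapped[k:k + 3] in STOP_CODONS:
                    raise InvalidInputError(
                        f"{sid}: internal stop codon at ungapped position {k}"
                    )
        object.__setattr__(self, "sequence_ids", ids)
        object.__setattr__(self, "codon_rows", rows)
        object.__setattr__(self, "meta", dict(meta or {}))

    @property
    def length_codons(self) -> int:
        return len(self.codon_rows[0]) // 3

    @property
    def n_sequences(self) -> int:
        return len(self.codon_rows)

    def codon_indices(self) -> np.ndarray:
        """(n_sequences, n_codons) sense-codon indices; -1 for gapped codons
        and for terminal stops."""
        n, m = self.n_sequences, self.length_codons
        out = np.full((n, m), -1, dtype=np.int64)
        for i, row in enumerate(self.codon_rows):
            for j in range(m):
                cod = row[3 * j:3 * j + 3]
                out[i, j] = _CODON_INDEX.get(cod, -1)
        return out


# ---------------------------------------------------------------------------
# estimation


def _kaks_from_counts(counts: np.ndarray, sites: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Li-Wu-Luo estimate.

    ``counts``: (..., 6) per-class [S0,S2,S4,V0,V2,V4]; ``sites``: (..., 3)
    [L0,L2,L4].  Returns (Ka, Ks, valid); a class with zero sites contributes
    nothing.
    """
    counts = np.asarray(counts, dtype=float)
    sites = np.asarray(sites, dtype=float)
    s = counts[..., 0:3]
    v = counts[..., 3:6]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(sites > 0, s / np.where(sites > 0, sites, 1.0), 0.0)
        q = np.where(sites > 0, v / np.where(sites > 0, sites, 1.0), 0.0)
        arg_a = 1.0 - 2.0 * p - q
        arg_b = 1.0 - 2.0 * q
        ok = (arg_a > 0) & (arg_b > 0)
        big_a = 0.5 * np.log(np.where(ok, 1.0 / np.where(arg_a > 0, arg_a, 1.0), 1.0)) \
            - 0.25 * np.log(np.where(ok, 1.0 / np.where(arg_b > 0, arg_b, 1.0), 1.0))
        big_b = 0.5 * np.log(np.where(ok, 1.0 / np.where(arg_b > 0, arg_b, 1.0), 1.0))
    big_k = big_a + big_b
    l0, l2, l4 = sites[..., 0], sites[..., 1], sites[..., 2]
    # classes without sites must not invalidate the pair
    used = sites > 0
    valid = (ok | ~used).all(axis=-1)
    syn_sites = l2 / 3.0 + l4
    non_sites = 2.0 * l2 / 3.0 + l0
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = np.where(
            syn_sites > 0,
            (l2 * big_a[..., 1] + l4 * big_k[..., 2]) / np.where(syn_sites > 0, syn_sites, 1.0),
            np.nan,
        )
        ka = np.where(
            non_sites > 0,
            (l2 * big_b[..., 1] + l0 * big_k[..., 0]) / np.where(non_sites > 0, non_sites, 1.0),
            np.nan,
        )
    valid = valid & np.isfinite(ks) & np.isfinite(ka)
    return ka, ks, valid


def pairwise_kaks(seq_a: str, seq_b: str) -> tuple[SiteCounts, PairwiseKaKs]:
    """Li-Wu-Luo Ka and Ks for one pair of in-frame aligned sequences.

    Codons gapped or ambiguous in either sequence are dropped (pairwise
    completion).  ``valid=False`` marks saturation (a K2P logarithm is
    undefined).
    """
    aln = CodonAlignment(("a", "b"), (seq_a, seq_b))
    idx = aln.codon_indices()
    both = (idx >= 0).all(axis=0)
    ia, ib = idx[0, both], idx[1, both]
    if ia.size == 0:
        raise InvalidInputError("no pairwise-complete codons")
    site_tab, pair_tab = _tables()
    sites = (site_tab[ia] + site_tab[ib]).sum(axis=0) / 2.0
    counts = pair_tab[ia, ib].sum(axis=0)
    ka, ks, valid = _kaks_from_counts(counts, sites)
    sc = SiteCounts(L0=float(sites[0]), L2=float(sites[1]), L4=float(sites[2]))
    if not valid:
        return sc, PairwiseKaKs(Ks=float("nan"), Ka=float("nan"), valid=False)
    return sc, PairwiseKaKs(Ks=float(ks), Ka=float(ka), valid=True)


def _per_column_contributions(aln: CodonAlignment
                              ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """(n_codons, n_pairs, 9) per-column [counts(6) | sites(3)] tensor.

    Columns where either member of a pair is gapped contribute zeros for that
    pair, so resampling columns automatically resamples pairwise completion.
    """
    idx = aln.codon_indices()
    site_tab, pair_tab = _tables()
    pairs = list(combinations(range(aln.n_sequences), 2))
    n_cols = aln.length_codons
    pc = np.zeros((n_cols, len(pairs), 9))
    for k, (i, j) in enumerate(pairs):
        both = (idx[i] >= 0) & (idx[j] >= 0)
        ia, ib = idx[i, both], idx[j, both]
        pc[both, k, :6] = pair_tab[ia, ib]
        pc[both, k, 6:] = (site_tab[ia] + site_tab[ib]) / 2.0
    return pc, pairs


def codon_ztest(
    aln: CodonAlignment,
    alternative: str,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> SelectionTest:
    """Codon-based z-test of strict neutrality (dN = dS).

    dN and dS are averaged over all valid sequence pairs; the variance of
    their difference is estimated by resampling codon columns with
    replacement (``n_bootstrap`` replicates).  ``alternative`` selects the
    tail: ``dN_gt_dS`` (positive selection), ``dN_lt_dS`` (purifying), or
    ``two_sided``.
    """
    if alternative not in ALTERNATIVES:
        raise InvalidInputError(
            f"alternative must be one of {ALTERNATIVES}, got {alternative!r}"
        )
    if n_bootstrap < 2:
        raise InvalidInputError("n_bootstrap must be >= 2")
    pc, pairs = _per_column_contributions(aln)
    n_cols = pc.shape[0]
    observed = pc.sum(axis=0)  # (n_pairs, 9)
    ka, ks, valid = _kaks_from_counts(observed[:, :6], observed[:, 6:])
    if not valid.any():
        raise UntestableError("every sequence pair is saturated or empty")
    mean_dn = float(ka[valid].mean())
    mean_ds = float(ks[valid].mean())

    rng = np.random.default_rng(seed)
    weights = rng.multinomial(n_cols, np.full(n_cols, 1.0 / n_cols),
                              size=n_bootstrap).astype(float)
    boot = np.tensordot(weights, pc, axes=1)  # (n_boot, n_pairs, 9)
    bka, bks, bvalid = _kaks_from_counts(boot[..., :6], boot[..., 6:])
    diff = np.where(bvalid, bka - bks, np.nan)
    usable = np.isfinite(diff).any(axis=1)
    boot_means = np.full(diff.shape[0], np.nan)
    if usable.any():
        boot_means[usable] = np.nanmean(diff[usable], axis=1)
    boot_means = boot_means[np.isfinite(boot_means)]
    if boot_means.size < 2:
        raise DegenerateVarianceError("bootstrap produced < 2 usable replicates")
    se = float(boot_means.std(ddof=1))
    if se == 0.0:
        raise DegenerateVarianceError(
            "bootstrap variance is zero (no substitution signal)"
        )
    z = (mean_dn - mean_ds) / se
    if alternative == "dN_gt_dS":
        p = float(norm.sf(z))
    elif alternative == "dN_lt_dS":
        p = float(norm.cdf(z))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return SelectionTest(
        mean_dN=mean_dn,
        mean_dS=mean_ds,
        z_statistic=float(z),
        p_value=p,
        alternative=alternative,
        n_bootstrap=n_bootstrap,
        seed=seed,
        n_pairs=int(valid.sum()),
        se=se,
    )
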