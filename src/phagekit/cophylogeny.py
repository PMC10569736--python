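"""Host-parasite cophylogenetic congruence testing (ParaFit-style).

The global test asks whether the evolutionary distance structure of a set of
parasites (here, phages) mirrors that of their hosts, given a binary
association matrix linking each parasite to the host(s) it infects.  Both
distance matrices are made Euclidean-embeddable with the Cailliez additive
correction, embedded by principal coordinates analysis (PCoA), and combined
through the fourth-corner cross-product

    S = C' A B,    ParaFitGlobal = sum of squared entries of S,

where B and C hold the host and parasite principal coordinates and A the
binary links (parasite x host).  The null distribution is obtained by
independently permuting, for every parasite, its host assignments (the row of
A), which randomizes which hosts a parasite infects while preserving how many.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, LabelError, UndefinedDistanceError

__all__ = [
    "DistanceMatrix",
    "AssociationMatrix",
    "Ordination",
    "ParafitResult",
    "msa_distance",
    "cailliez_correction",
    "pcoa",
    "parafit_global",
]

#: relative eigenvalue tolerance: axes below this fraction of the largest
#: eigenvalue are discarded by PCoA.
EIGEN_REL_TOL = 1e-8


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = tuple(str(x) for x in labels)
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise InvalidInputError(
                f"distance matrix shape {values.shape} does not match {n} labels"
            )
        if len(set(labels)) != n:
            raise InvalidInputError("duplicate labels in distance matrix")
        if not np.allclose(values, values.T, atol=1e-8):
            raise InvalidInputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise InvalidInputError("distance matrix diagonal is not zero")
        if (values < -1e-12).any():
            raise InvalidInputError("distance matrix has negative entries")
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = list(labels)
        try:
            idx = [self.labels.index(l) for l in labels]
        except ValueError as exc:
            raise LabelError(f"label not in distance matrix: {exc}") from exc
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary parasite x host link matrix; every parasite has >= 1 host."""

    parasite_labels: tuple[str, ...]
    host_labels: tuple[str, ...]
    links: np.ndarray

    def __init__(
        self,
        parasite_labels: Sequence[str],
        host_labels: Sequence[str],
        links: np.ndarray,
    ):
        parasite_labels = tuple(str(x) for x in parasite_labels)
        host_labels = tuple(str(x) for x in host_labels)
        links = np.asarray(links)
        if links.shape != (len(parasite_labels), len(host_labels)):
            raise InvalidInputError(
                f"links shape {links.shape} does not match "
                f"{len(parasite_labels)} parasites x {len(host_labels)} hosts"
            )
        if not np.isin(links, (0, 1)).all():
            raise InvalidInputError("association links must be 0/1")
        links = links.astype(float)
        if (links.sum(axis=1) < 1).any():
            bad = [
                p for p, s in zip(parasite_labels, links.sum(axis=1)) if s < 1
            ]
            raise InvalidInputError(f"parasites with no host link: {bad}")
        object.__setattr__(self, "parasite_labels", parasite_labels)
        object.__setattr__(self, "host_labels", host_labels)
        object.__setattr__(self, "links", links)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        parasite_labels: Sequence[str] | None = None,
        host_labels: Sequence[str] | None = None,
    ) -> "AssociationMatrix":
        """Build from (parasite_id, host_id) pairs."""
        pairs = list(pairs)
        if parasite_labels is None:
            parasite_labels = sorted({p for p, _ in pairs})
        if host_labels is None:
            host_labels = sorted({h for _, h in pairs})
        p_idx = {p: i for i, p in enumerate(parasite_labels)}
        h_idx = {h: i for i, h in enumerate(host_labels)}
        links = np.zeros((len(parasite_labels), len(host_labels)))
        for p, h in pairs:
            if p not in p_idx:
                raise LabelError(f"unknown parasite label {p!r}")
            if h not in h_idx:
                raise LabelError(f"unknown host label {h!r}")
            links[p_idx[p], h_idx[h]] = 1.0
        return cls(parasite_labels, host_labels, links)


@dataclass(frozen=True)
class Ordination:
    """PCoA result: objects x axes coordinates, eigenvalues non-increasing."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class ParafitResult:
    global_statistic: float
    p_value: float
    n_permutations: int
    seed: int
    null_statistics: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# distances from alignments


def msa_distance(
    ids: Sequence[str],
    sequences: Sequence[str],
    model: str = "uncorrected",
) -> DistanceMatrix:
    """Pairwise distances from an aligned set of nucleotide sequences.

    Gap handling is pairwise deletion: a column counts for a pair only when
    neither sequence has a gap ('-' or '.') or an N there.  ``model`` is
    ``uncorrected`` (proportion of differing sites, the EMBOSS distmat
    default) or ``jukes_cantor``.
    """
    if len(sequences) < 2:
        raise InvalidInputError("need at least 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise InvalidInputError(f"sequences are not aligned: lengths {sorted(lengths)}")
    if model not in ("uncorrected", "jukes_cantor"):
        raise InvalidInputError(f"unknown distance model {model!r}")
    arr = np.array([list(s.upper().replace("U", "T")) for s in sequences])
    valid = (arr != "-") & (arr != ".") & (arr != "N")
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if model == "jukes_cantor":
                if p >= 0.75:
                    raise UndefinedDistanceError(
                        f"Jukes-Cantor saturated (p={p:.3f}) for "
                        f"{ids[i]!r} vs {ids[j]!r}"
                    )
                p = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Cailliez correction and PCoA


def _gower_center(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    row = m.mean(axis=1, keepdims=True)
    col = m.mean(axis=0, keepdims=True)
    return m - row - col + m.mean()


def cailliez_correction(d: DistanceMatrix) -> tuple[DistanceMatrix, float]:
    """Smallest additive constant making the matrix Euclidean-embeddable.

    The constant is the largest real eigenvalue of the 2n x 2n companion
    matrix built from the Gower-centred forms of -D^2/2 and -D/2; it is added
    to every off-diagonal distance.  Already-Euclidean matrices return c = 0.
    """
    dv = d.values
    n = d.n
    if n <= 2:
        return d, 0.0
    delta1 = _gower_center(-0.5 * dv**2)
    delta2 = _gower_center(-0.5 * dv)
    top = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    bottom = np.hstack([-np.eye(n), -4.0 * delta2])
    companion = np.vstack([top, bottom])
    eigs = np.linalg.eigvals(companion)
    c = max(float(np.max(eigs.real)), 0.0)
    if c <= 1e-10:
        return d, 0.0
    corrected = dv + c
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(d.labels, corrected), c


def pcoa(d: DistanceMatrix, rel_tol: float = EIGEN_REL_TOL) -> Ordination:
    """Principal coordinates of a distance matrix.

    Gower double-centring of -D^2/2, symmetric eigendecomposition, and
    coordinates = eigenvectors scaled by sqrt(eigenvalue) for the axes whose
    eigenvalue exceeds ``rel_tol`` x the largest eigenvalue.
    """
    b = _gower_center(-0.5 * d.values**2)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if d.n == 1 or eigval[0] <= 0:
        return Ordination(np.zeros((d.n, 0)), np.zeros(0))
    keep = eigval > rel_tol * eigval[0]
    eigval = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval)
    return Ordination(coords, eigval)


# ---------------------------------------------------------------------------
# the global congruence statistic


def _parafit_matrices(
    host_d: DistanceMatrix,
    parasite_d: DistanceMatrix,
    links: AssociationMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    missing_h = set(links.host_labels) - set(host_d.labels)
    missing_p = set(links.parasite_labels) - set(parasite_d.labels)
    if missing_h or missing_p:
        raise LabelError(
            f"labels in links but not in distance matrices: "
            f"hosts {sorted(missing_h)}, parasites {sorted(missing_p)}"
        )
    host_d = host_d.reorder(links.host_labels)
    parasite_d = parasite_d.reorder(links.parasite_labels)
    b = pcoa(cailliez_correction(host_d)[0]).coordinates
    c = pcoa(cailliez_correction(parasite_d)[0]).coordinates
    return c, links.links.copy(), b


def _global_stat(c: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    s = c.T @ a @ b
    return float((s * s).sum())


def parafit_global(
    host_d: DistanceMatrix,
    parasite_d: DistanceMatrix,
    links: AssociationMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    keep_null: bool = False,
) -> ParafitResult:
    """Global host-parasite congruence permutation test.

    ``p = (1 + #{null >= observed}) / (1 + n_permutations)``, one-tailed
    upper.  Fixed ``seed`` gives bit-reproducible results.
    """
    if n_permutations < 1:
        raise InvalidInputError("n_permutations must be >= 1")
    c, a, b = _parafit_matrices(host_d, parasite_d, links)
    observed = _global_stat(c, a, b)
    rng = np.random.default_rng(seed)
    n_p, n_h = a.shape
    null = np.empty(n_permutations)
    a_perm = np.empty_like(a)
    for k in range(n_permutations):
        for i in range(n_p):
            a_perm[i] = a[i, rng.permutation(n_h)]
        null[k] = _global_stat(c, a_perm, b)
    n_ge = int((null >= observed - 1e-12).sum())
    p = (1 + n_ge) / (1 + n_permutations)
    return ParafitResult(
        global_statistic=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        null_statistics=null if keep_null else None,
    )


def parafit_exhaustive_null(
    host_d: DistanceMatrix,
    parasite_d: DistanceMatrix,
    links: AssociationMatrix,
) -> tuple[float, float]:
    """Exact p-value by enumerating the permutation scheme's full null space.

    Each parasite row of A is independently replaced by each of its distinct
    permutations; the null is uniform over the Cartesian product.  Only
    feasible for small systems.  Returns (observed statistic, exact p).
    """
    from itertools import permutations, product

    c, a, b = _parafit_matrices(host_d, parasite_d, links)
    observed = _global_stat(c, a, b)
    n_p, n_h = a.shape
    # distinct row arrangements with multiplicities
    row_options: list[list[tuple[np.ndarray, int]]] = []
    for i in range(n_p):
        counts: dict[tuple, int] = {}
        for perm in permutations(range(n_h)):
            key = tuple(a[i, list(perm)])
            counts[key] = counts.get(key, 0) + 1
        row_options.append(
            [(np.array(k, dtype=float), m) for k, m in counts.items()]
        )
    total = 0
    n_ge = 0
    for combo in product(*row_options):
        a_perm = np.vstack([row for row, _ in combo])
        weight = 1
        for _, m in combo:
            weight *= m
        total += weight
        if _global_stat(c, a_perm, b) >= observed - 1e-12:
            n_ge += weight
    return observed, n_ge / total
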