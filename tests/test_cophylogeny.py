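"""Distances, Cailliez correction, PCoA and the congruence permutation test."""

import shutil
import subprocess

import numpy as np
import pytest

from phagekit.cophylogeny import (
    AssociationMatrix,
    DistanceMatrix,
    cailliez_correction,
    msa_distance,
    parafit_exhaustive_null,
    parafit_global,
    pcoa,
)
from phagekit.errors import InvalidInputError, LabelError, UndefinedDistanceError
from phagekit.io import write_distance_matrix
from phagekit.synthesize import SimulationConfig, sim_cophylo_system


class TestMsaDistance:
    def test_identical_sequences_are_at_distance_zero(self):
        d = msa_distance(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        assert d.values[0, 1] == 0.0

    def test_uncorrected_p_distance_counts_mismatches(self):
        d = msa_distance(["a", "b"], ["ACGTACGTAC", "ACGTACGTTT"])
        assert d.values[0, 1] == pytest.approx(0.2)

    def test_pairwise_deletion_shrinks_the_denominator(self):
        # 2 mismatches over 8 comparable columns (2 gapped)
        d = msa_distance(["a", "b"], ["ACGTACGTAC", "--GTACGTTT"])
        assert d.values[0, 1] == pytest.approx(2 / 8)

    def test_jukes_cantor_applies_the_log_correction(self):
        d = msa_distance(["a", "b"], ["ACGTACGTAC", "ACGTACGTTT"],
                         model="jukes_cantor")
        assert d.values[0, 1] == pytest.approx(-0.75 * np.log(1 - 4 * 0.2 / 3))

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(UndefinedDistanceError):
            msa_distance(["a", "b"], ["AC--", "--GT"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            msa_distance(["a", "b"], ["ACGT", "ACG"])


class TestCailliez:
    def test_collinear_points_need_no_correction(self):
        # points at 0, 1, 3 on a line: already Euclidean
        d = DistanceMatrix(list("abc"),
                           [[0, 1, 3], [1, 0, 2], [3, 2, 0]])
        _, c = cailliez_correction(d)
        assert c == 0.0

    def test_triangle_violation_gets_positive_constant(self):
        vals = np.array([
            [0, 1, 1, 3],
            [1, 0, 1, 1],
            [1, 1, 0, 1],
            [3, 1, 1, 0],
        ], dtype=float)
        d = DistanceMatrix(list("abcd"), vals)
        corrected, c = cailliez_correction(d)
        assert c > 0
        # corrected matrix passes the PCoA eigenvalue check
        b = -0.5 * corrected.values**2
        n = 4
        j = np.eye(n) - np.ones((n, n)) / n
        eig = np.linalg.eigvalsh(j @ b @ j)
        assert eig.min() > -1e-8 * max(eig.max(), 1.0)

    def test_constant_invariant_to_label_permutation(self):
        vals = np.array([
            [0, 1, 1, 3],
            [1, 0, 1, 1],
            [1, 1, 0, 1],
            [3, 1, 1, 0],
        ], dtype=float)
        d = DistanceMatrix(list("abcd"), vals)
        _, c1 = cailliez_correction(d)
        _, c2 = cailliez_correction(d.reorder(["d", "a", "c", "b"]))
        assert c1 > 0
        assert c1 == pytest.approx(c2, rel=1e-9)


class TestPcoa:
    def test_single_object_gives_zero_dimensional_ordination(self):
        d = DistanceMatrix(["a"], [[0.0]])
        ord_ = pcoa(d)
        assert ord_.coordinates.shape == (1, 0)

    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        d = DistanceMatrix(list("abc"),
                           [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        ord_ = pcoa(d)
        assert len(ord_.eigenvalues) == 2
        assert ord_.eigenvalues[0] == pytest.approx(ord_.eigenvalues[1], rel=1e-9)

    def test_coordinates_reconstruct_euclidean_distances(self):
        d = DistanceMatrix(list("abcd"),
                           [[0, 1, 2, 5], [1, 0, 1, 4], [2, 1, 0, 3],
                            [5, 4, 3, 0]])
        coords = pcoa(d).coordinates
        from scipy.spatial.distance import pdist, squareform
        rec = squareform(pdist(coords))
        assert np.allclose(rec, d.values, atol=1e-9)

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform
        vals = squareform(pdist(pts))
        d = DistanceMatrix([f"o{i}" for i in range(6)], vals)
        mine = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(vals, ids=d.labels))
        np.testing.assert_allclose(
            mine.eigenvalues, theirs.eigvals.to_numpy()[:len(mine.eigenvalues)],
            atol=1e-8)


def _one_to_one(n):
    labels_p = [f"P{i:02d}" for i in range(n)]
    labels_h = [f"H{i:02d}" for i in range(n)]
    return AssociationMatrix(labels_p, labels_h, np.eye(n))


class TestParafit:
    def test_seed_reproducibility_and_p_range(self):
        hd, pd_, links = sim_cophylo_system(
            SimulationConfig(seed=4, congruence_mode="independent"))
        r1 = parafit_global(hd, pd_, links, 199, seed=7)
        r2 = parafit_global(hd, pd_, links, 199, seed=7)
        assert r1.global_statistic == r2.global_statistic
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1

    def test_statistic_invariant_to_simultaneous_reordering(self):
        hd, pd_, links = sim_cophylo_system(
            SimulationConfig(seed=8, congruence_mode="congruent",
                             noise_sd=0.2))
        r1 = parafit_global(hd, pd_, links, 99, seed=1)
        order_h = list(links.host_labels)[::-1]
        order_p = list(links.parasite_labels)[::-1]
        idx_p = [links.parasite_labels.index(p) for p in order_p]
        idx_h = [links.host_labels.index(h) for h in order_h]
        links2 = AssociationMatrix(order_p, order_h,
                                   links.links[np.ix_(idx_p, idx_h)])
        r2 = parafit_global(hd.reorder(order_h), pd_.reorder(order_p),
                            links2, 99, seed=1)
        # axis retention near the eigenvalue cutoff limits exact agreement
        assert r1.global_statistic == pytest.approx(r2.global_statistic,
                                                    rel=1e-5)

    def test_parasite_without_host_is_rejected(self):
        with pytest.raises(InvalidInputError):
            AssociationMatrix(["p1", "p2"], ["h1"], [[1], [0]])

    def test_label_mismatch_raises(self):
        hd, pd_, links = sim_cophylo_system(
            SimulationConfig(seed=4, congruence_mode="independent"))
        bad = AssociationMatrix(["zz"] + list(links.parasite_labels)[1:],
                                links.host_labels, links.links)
        with pytest.raises(LabelError):
            parafit_global(hd, pd_, bad, 9, seed=0)

    def test_monte_carlo_p_converges_to_exhaustive_enumeration(self):
        hd, pd_, links = sim_cophylo_system(
            SimulationConfig(seed=3, congruence_mode="congruent",
                             n_hosts=4, n_parasites=4))
        obs, p_exact = parafit_exhaustive_null(hd, pd_, links)
        r = parafit_global(hd, pd_, links, 20_000, seed=9)
        assert r.global_statistic == pytest.approx(obs, rel=1e-12)
        mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(r.p_value - p_exact) < mc_err + 1e-4

    def test_statistic_matches_ape_parafit(self, tmp_path):
        """Independent oracle: ape::parafit with Cailliez correction."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        hd, pd_, links = sim_cophylo_system(
            SimulationConfig(seed=11, congruence_mode="noisy", noise_sd=0.3,
                             n_hosts=5, n_parasites=5))
        write_distance_matrix(hd, tmp_path / "h.phy")
        write_distance_matrix(pd_, tmp_path / "p.phy")
        np.savetxt(tmp_path / "links.txt", links.links.T, fmt="%d")
        script = (
            'suppressMessages(library(ape));'
            f'h <- as.matrix(read.table("{tmp_path}/h.phy", skip=1, row.names=1));'
            f'p <- as.matrix(read.table("{tmp_path}/p.phy", skip=1, row.names=1));'
            f'hp <- as.matrix(read.table("{tmp_path}/links.txt"));'
            'res <- parafit(h, p, hp, nperm=0, correction="cailliez", silent=TRUE);'
            'cat(sprintf("%.10f", res$ParaFitGlobal))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ape_stat = float(out.stdout.strip().split()[-1])
        mine = parafit_global(hd, pd_, links, 9, seed=0).global_statistic
        assert mine == pytest.approx(ape_stat, rel=1e-6)
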