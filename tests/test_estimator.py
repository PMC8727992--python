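"""Tests of the mixture-cost estimator: filtering, cost, scalar and
k-fraction optimization, against brute-force grid oracles."""

import numpy as np
import pandas as pd
import pytest

from sfae import estimator
from sfae import simulate as sim
from sfae.types import ExpressionTable, FractionTriplet


def make_table(c, n, w):
    genes = [f"g{i}" for i in range(len(c))]
    values = pd.DataFrame({"Cyto": c, "Nuc": n, "WC": w},
                          index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(
        {"fraction": ["cytosol", "nucleus", "whole_cell"],
         "cell_line": "x", "polya": "unknown"},
        index=["Cyto", "Nuc", "WC"])
    return ExpressionTable(values=values, sample_meta=meta)


def make_triplet(c, n, w):
    c = np.asarray(c, float)
    return FractionTriplet(gene_ids=np.arange(len(c)), c=c, n_vec=n, w=w)


class TestFilterTriplet:
    @pytest.mark.parametrize(
        "w, kept",
        [
            (5.0, True),    # strictly inside [2, 10]
            (12.0, False),  # above both fractions
            (10.0, True),   # on the boundary: inclusive
            (2.0, True),    # lower boundary inclusive
            (1.5, False),   # below both fractions
        ],
    )
    def test_between_range_rule(self, w, kept):
        table = make_table([10.0, 4.0], [2.0, 2.0], [w, 3.0])
        trip = estimator.filter_triplet(table, "Cyto", "Nuc", "WC")
        assert ("g0" in trip.gene_ids) == kept

    def test_nonpositive_removed_with_reason(self):
        table = make_table([0.0, 4.0], [2.0, 2.0], [1.0, 3.0])
        trip = estimator.filter_triplet(table, "Cyto", "Nuc", "WC")
        assert list(trip.gene_ids) == ["g1"]
        assert trip.n_removed_nonpositive == 1
        assert trip.n_removed_out_of_range == 0

    def test_empty_result_is_an_error(self):
        table = make_table([10.0], [2.0], [20.0])
        with pytest.raises(ValueError, match="empty estimation set"):
            estimator.filter_triplet(table, "Cyto", "Nuc", "WC")

    def test_missing_sample_is_an_error(self, tiny_table):
        with pytest.raises(ValueError, match="not in expression table"):
            estimator.filter_triplet(tiny_table, "Cyto", "Nuc", "nope")

    def test_gene_subset_restricts_estimation(self, tiny_table):
        trip = estimator.filter_triplet(
            tiny_table, "Cyto", "Nuc", "WC", gene_subset=["g1", "g3"])
        assert set(trip.gene_ids) == {"g1", "g3"}


class TestCost:
    def test_zero_when_prediction_matches(self):
        trip = make_triplet([4.0, 6.0], [2.0, 3.0], [4.0, 6.0])
        assert estimator.cost(1.0, trip) == 0.0

    def test_exact_mixture_gives_zero(self):
        trip = make_triplet([4.0], [2.0], [3.0])
        assert estimator.cost(0.5, trip) == pytest.approx(0.0, abs=1e-15)

    def test_single_gene_log_ratio(self):
        trip = make_triplet([4.0], [2.0], [3.0])
        assert estimator.cost(1.0, trip) == pytest.approx(
            np.log(4.0 / 3.0) ** 2, rel=1e-12)
        assert estimator.cost(1.0, trip) == pytest.approx(0.082761, abs=1e-6)

    def test_gene_order_and_duplication_invariance(self):
        rng = np.random.default_rng(0)
        n = rng.lognormal(1, 1, 50)
        c = n * rng.lognormal(0.5, 0.5, 50)
        w = 0.6 * c + 0.4 * n
        trip = make_triplet(c, n, w)
        perm = rng.permutation(50)
        trip_p = make_triplet(c[perm], n[perm], w[perm])
        trip_d = make_triplet(np.r_[c, c], np.r_[n, n], np.r_[w, w])
        for theta in (0.1, 0.37, 0.9):
            assert estimator.cost(theta, trip) == pytest.approx(
                estimator.cost(theta, trip_p), rel=1e-12)
            assert estimator.cost(theta, trip) == pytest.approx(
                estimator.cost(theta, trip_d), rel=1e-12)

    def test_theta_outside_unit_interval_rejected(self):
        trip = make_triplet([4.0], [2.0], [3.0])
        with pytest.raises(ValueError):
            estimator.cost(1.5, trip)


class TestGridProfile:
    def test_profile_length_and_minimum_location(self):
        trip = make_triplet([4.0, 8.0], [2.0, 2.0], [3.0, 5.0])  # theta=0.5 exact
        prof = estimator.grid_profile(trip, step=0.25)
        assert len(prof) == 5
        thetas, errs = zip(*prof)
        assert thetas == (0.0, 0.25, 0.5, 0.75, 1.0)
        assert np.argmin(errs) == 2

    @pytest.mark.parametrize("step,expected", [(0.1, 11), (0.07, 15), (0.01, 101)])
    def test_profile_length_formula(self, step, expected):
        trip = make_triplet([4.0], [2.0], [3.0])
        assert len(estimator.grid_profile(trip, step=step)) == expected

    def test_noisy_profiles_are_unimodal(self):
        for seed in range(50):
            table, _ = sim.simulate_fractionation(
                n_genes=300, theta=0.7, noise_sdlog=0.1,
                wc_noise_sdlog=0.05, seed=seed)
            trip = estimator.filter_triplet(table, "Cyto", "Nuc", "WC")
            errs = np.array([e for _, e in estimator.grid_profile(trip, step=0.02)])
            d = np.sign(np.diff(errs))
            # strictly decreasing then increasing: at most one sign change
            changes = np.count_nonzero(np.diff(d[d != 0]) != 0)
            assert changes <= 1


class TestEstimateCR:
    def test_boundary_identity(self):
        trip = make_triplet([4.0, 6.0], [2.0, 3.0], [4.0, 6.0])  # W == C
        est = estimator.estimate_cr(trip)
        assert est.theta == pytest.approx(1.0, abs=1e-5)

    def test_noise_free_forced_optimum(self):
        rng = np.random.default_rng(42)
        c = rng.lognormal(1, 1, 100)
        n = rng.lognormal(1, 1, 100)
        w = 0.3 * c + 0.7 * n
        est = estimator.estimate_cr(make_triplet(c, n, w))
        assert est.theta == pytest.approx(0.3, abs=1e-4)
        assert est.e_min == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_grid_oracle_under_noise(self):
        table, truth = sim.simulate_fractionation(
            n_genes=2000, theta=0.8, noise_sdlog=0.1, wc_noise_sdlog=0.1, seed=7)
        trip = estimator.filter_triplet(table, "Cyto", "Nuc", "WC")
        est = estimator.estimate_cr(trip)
        assert est.theta == pytest.approx(0.8, abs=0.03)
        thetas = np.linspace(0, 1, 10001)
        errs = [estimator.cost(t, trip) for t in thetas[::100]]  # coarse sanity
        grid = estimator._cost_grid(thetas, trip)
        assert np.allclose(grid[::100], errs)
        assert abs(est.theta - thetas[np.argmin(grid)]) < 2e-4

    def test_label_swap_symmetry(self):
        for seed in (0, 1, 2):
            table, _ = sim.simulate_fractionation(
                n_genes=500, theta=0.65, noise_sdlog=0.1,
                wc_noise_sdlog=0.05, seed=seed)
            trip = estimator.filter_triplet(table, "Cyto", "Nuc", "WC")
            swapped = estimator.filter_triplet(table, "Nuc", "Cyto", "WC")
            t1 = estimator.estimate_cr(trip).theta
            t2 = estimator.estimate_cr(swapped).theta
            assert t1 + t2 == pytest.approx(1.0, abs=1e-3)

    def test_profile_attachment_and_invariant(self):
        table, _ = sim.simulate_fractionation(n_genes=200, theta=0.6, seed=3)
        trip = estimator.filter_triplet(table, "Cyto", "Nuc", "WC")
        est = estimator.estimate_cr(trip, profile_step=0.05)
        assert len(est.profile) == 21
        assert all(est.e_min <= e + 1e-12 for _, e in est.profile)


class TestMultifraction:
    def test_k2_reduces_to_scalar_estimate(self):
        table, _ = sim.simulate_fractionation(
            n_genes=400, theta=0.55, noise_sdlog=0.08,
            wc_noise_sdlog=0.05, seed=5)
        trip = estimator.filter_triplet(table, "Cyto", "Nuc", "WC")
        theta_scalar = estimator.estimate_cr(trip).theta
        fs = estimator.filter_fraction_set(table, ["Cyto", "Nuc"], "WC")
        fs = estimator.estimate_multifraction(fs)
        assert fs.weights[0] == pytest.approx(theta_scalar, abs=1e-4)

    def test_noise_free_weight_recovery(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(1, 1, size=(200, 3))
        true_w = np.array([0.5, 0.3, 0.2])
        wc = x @ true_w
        genes = pd.Index([f"g{i}" for i in range(200)])
        from sfae.types import FractionSet
        fs = FractionSet(gene_ids=genes.to_numpy(),
                         fractions=pd.DataFrame(x, index=genes,
                                                columns=["F1", "F2", "F3"]),
                         w=wc)
        fs = estimator.estimate_multifraction(fs)
        assert np.allclose(fs.weights, true_w, atol=1e-3)

    def test_four_fraction_recovery_matches_simplex_grid_oracle(self):
        true_w = np.array([0.4, 0.3, 0.2, 0.1])
        table, truth = sim.simulate_fractionation(
            n_genes=200, weights=true_w, noise_sdlog=0.1,
            wc_noise_sdlog=0.1, seed=11)
        fs = estimator.filter_fraction_set(table, ["F1", "F2", "F3", "F4"], "WC")
        fs = estimator.estimate_multifraction(fs)
        assert np.all(np.abs(fs.weights - true_w) < 0.05)
        grid_w, _ = estimator._simplex_grid_argmin(
            fs.fractions.to_numpy(float), fs.w, 4, 0.01)
        assert np.all(np.abs(fs.weights - grid_w) <= 0.05)

    def test_identical_fractions_flagged_non_identifiable(self):
        x = np.full((50, 3), 7.0)
        genes = pd.Index([f"g{i}" for i in range(50)])
        from sfae.types import FractionSet
        fs = FractionSet(gene_ids=genes.to_numpy(),
                         fractions=pd.DataFrame(x, index=genes,
                                                columns=list("ABC")),
                         w=np.full(50, 7.0))
        fs = estimator.estimate_multifraction(fs)
        assert fs.non_identifiable
        assert np.allclose(fs.weights, 1 / 3)
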