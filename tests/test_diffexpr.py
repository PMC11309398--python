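"""Size factors, filtering, the two-group NB Wald test, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synloc import (
    CountSimParams,
    bh_adjust,
    estimate_size_factors,
    filter_features,
    overlap_concordance,
    simulate_count_dataset,
    two_group_de,
)

from conftest import make_dataset


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios implementation (explicit loops)."""
    G, n = counts.shape
    refs, rows = [], []
    for g in range(G):
        if all(counts[g, s] > 0 for s in range(n)):
            log_sum = sum(np.log(counts[g, s]) for s in range(n))
            refs.append(np.exp(log_sum / n))
            rows.append(g)
    factors = []
    for s in range(n):
        ratios = [counts[g, s] / ref for g, ref in zip(rows, refs)]
        factors.append(float(np.median(ratios)))
    return np.array(factors)


class TestSizeFactors:
    def test_identical_samples_get_equal_factors(self):
        ds = make_dataset(np.tile([[10], [20], [5]], (1, 4)))
        sf = estimate_size_factors(ds)
        assert np.allclose(sf, sf.iloc[0])

    def test_elementwise_doubling_doubles_the_factor(self):
        a = np.array([[10], [20], [5], [100]])
        ds = make_dataset(np.hstack([a, 2 * a]))
        sf = estimate_size_factors(ds)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_oracle_exactly(self, rng):
        counts = rng.integers(0, 500, size=(50, 6))
        counts[:10] += 1  # guarantee some all-positive rows
        ds = make_dataset(counts)
        sf = estimate_size_factors(ds)
        assert np.allclose(sf.to_numpy(), brute_force_size_factors(counts),
                           rtol=1e-13, atol=0)

    def test_invariant_under_feature_permutation(self, rng):
        counts = rng.integers(1, 500, size=(40, 6))
        ds = make_dataset(counts)
        perm = rng.permutation(40)
        ds_perm = make_dataset(counts[perm])
        assert np.allclose(
            estimate_size_factors(ds), estimate_size_factors(ds_perm)
        )

    def test_no_common_feature_raises_with_fallback_hint(self):
        counts = np.array([[0, 5], [7, 0]])
        ds = make_dataset(counts)
        with pytest.raises(ValueError, match="pseudo_reference"):
            estimate_size_factors(ds)
        sf = estimate_size_factors(ds, allow_pseudo_reference=True)
        assert (sf > 0).all()


class TestFilterFeatures:
    def test_boundary_equality_is_kept(self):
        ds = make_dataset(np.full((1, 9), 10))
        assert filter_features(ds, 10, 9).counts.shape[0] == 1

    def test_strictly_below_threshold_is_removed(self):
        ds = make_dataset(np.full((1, 9), 9))
        assert filter_features(ds, 10, 9).counts.shape[0] == 0

    @pytest.mark.parametrize("min_count,min_samples", [(10, 9), (4, 5)])
    def test_matches_brute_force_scan(self, rng, min_count, min_samples):
        counts = rng.integers(0, 15, size=(200, 12))
        ds = make_dataset(counts)
        kept = filter_features(ds, min_count, min_samples)
        expected = [
            f"f{g + 1}"
            for g in range(200)
            if sum(counts[g, s] >= min_count for s in range(12)) >= min_samples
        ]
        assert list(kept.counts.index) == expected

    def test_order_preserved(self, rng):
        counts = rng.integers(0, 30, size=(100, 6))
        ds = make_dataset(counts)
        kept = filter_features(ds, 4, 5)
        positions = [ds.feature_ids.index(f) for f in kept.feature_ids]
        assert positions == sorted(positions)


def _two_group_dataset(G, reps, beta=None, dispersion=0.1, seed=0):
    """Synaptosome-only subset: case vs control with `reps` samples each."""
    params = CountSimParams(
        n_genes=G, replicates=reps, beta_condition=beta,
        dispersion=dispersion, seed=seed,
    )
    ds, _ = simulate_count_dataset(params)
    return ds.subset_samples(ds.samples_where(fraction="synaptosome"))


class TestTwoGroupDE:
    def test_null_pvalues_are_uniform_at_large_n(self):
        ds = _two_group_dataset(2000, 25, seed=11)
        de = two_group_de(ds, ds.condition, ("case", "control"))
        assert stats.kstest(de["p"], "uniform").pvalue > 0.01
        # and the Wald statistics themselves are close to standard normal
        assert stats.kstest(de["wald"], "norm").pvalue > 0.01

    def test_null_level_close_to_nominal_at_n6(self):
        levels = [
            (two_group_de(d, d.condition, ("case", "control"))["p"] < 0.05).mean()
            for d in (_two_group_dataset(2000, 6, seed=s) for s in (0, 1, 2))
        ]
        assert 0.03 <= np.mean(levels) <= 0.07

    def test_planted_fourfold_change_recovered(self):
        G = 2000
        beta = np.zeros(G)
        beta[:100] = 2.0
        ds = _two_group_dataset(G, 20, beta=beta, dispersion=0.05, seed=5)
        de = two_group_de(ds, ds.condition, ("case", "control"))
        assert abs(de["log2fc"][:100].mean() - 2.0) < 0.1

    def test_contrast_swap_negates_log2fc_and_preserves_p(self, rng):
        ds = _two_group_dataset(100, 4, seed=3)
        fwd = two_group_de(ds, ds.condition, ("case", "control"))
        rev = two_group_de(ds, ds.condition, ("control", "case"))
        assert np.array_equal(fwd["log2fc"].to_numpy(), -rev["log2fc"].to_numpy())
        assert np.array_equal(fwd["p"].to_numpy(), rev["p"].to_numpy())

    def test_wald_times_se_recovers_log2fc(self):
        ds = _two_group_dataset(50, 3, seed=8)
        de = two_group_de(ds, ds.condition, ("case", "control"))
        assert np.allclose(de["wald"] * de["se"], de["log2fc"], atol=1e-12)

    def test_all_zero_feature_degenerates_gracefully(self):
        counts = np.vstack([np.zeros((1, 8), dtype=int),
                            np.full((3, 8), 50, dtype=int)])
        ds = make_dataset(counts, fraction=["synaptosome"] * 8)
        de = two_group_de(ds, ds.condition, ("case", "control"))
        row = de.set_index("feature_id").loc["f1"]
        assert row["log2fc"] == 0.0 and row["p"] == 1.0 and row["se"] > 0

    def test_group_smaller_than_two_raises(self):
        ds = make_dataset(np.full((3, 3), 10), fraction=["synaptosome"] * 3,
                          condition=["case", "case", "control"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            two_group_de(ds, ds.condition, ("case", "control"))


class TestBenjaminiHochberg:
    def test_matches_brute_force_oracle(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        # independent step-up implementation
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert np.allclose(q, adj, atol=1e-12)

    def test_q_at_least_p_and_monotone_in_rank(self, rng):
        p = rng.uniform(size=500)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestOverlapConcordance:
    @staticmethod
    def _table(ids, lfc, p):
        return pd.DataFrame({"feature_id": ids, "log2fc": lfc, "p": p})

    def test_identical_tables_are_fully_concordant(self):
        t = self._table(["a", "b", "c"], [1.0, -2.0, 0.5], [0.01, 0.2, 0.001])
        res = overlap_concordance(t, t, alpha=0.05)
        assert res["n_overlap"] == res["n_sig_A"] == 2
        assert res["pct_concordant_sign"] == 100.0

    def test_disjoint_significant_sets_give_nan_pct(self):
        a = self._table(["a", "b"], [1.0, 1.0], [0.01, 0.9])
        b = self._table(["a", "b"], [1.0, 1.0], [0.9, 0.01])
        res = overlap_concordance(a, b, alpha=0.05)
        assert res["n_overlap"] == 0
        assert np.isnan(res["pct_concordant_sign"])

    def test_matches_set_arithmetic_oracle(self, rng):
        ids = [f"f{i}" for i in range(300)]
        a = self._table(ids, rng.normal(size=300), rng.uniform(size=300))
        b = self._table(ids, rng.normal(size=300), rng.uniform(size=300))
        res = overlap_concordance(a, b, alpha=0.1)
        sa = {f for f, p in zip(ids, a["p"]) if p < 0.1}
        sb = {f for f, p in zip(ids, b["p"]) if p < 0.1}
        inter = sa & sb
        conc = sum(
            1
            for f in inter
            if np.sign(a.set_index("feature_id").loc[f, "log2fc"])
            == np.sign(b.set_index("feature_id").loc[f, "log2fc"])
        )
        assert res["n_sig_A"] == len(sa)
        assert res["n_sig_B"] == len(sb)
        assert res["n_overlap"] == len(inter)
        assert res["pct_concordant_sign"] == pytest.approx(100 * conc / len(inter))
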