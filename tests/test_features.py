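"""Regularization, subsampling, and correlation-graph feature selection."""
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morpholink as ml

rng = np.random.default_rng(42)


class TestClassification:
    @pytest.mark.parametrize("sample,family", [
        (np.exp(rng.normal(size=500)), 1),            # right-skewed non-negative
        (rng.poisson(3.0, size=500).astype(float), 2),  # integer counts
        (rng.beta(2, 5, size=500), 3),                # bounded in [0, 1]
        (rng.normal(size=500), 4),                    # symmetric
        (rng.standard_t(1.2, size=500) * 10, 5),      # signed heavy tails
    ])
    def test_family_rules(self, sample, family):
        assert ml.classify_feature_distribution(sample) == family

    def test_constant_sentinel(self):
        assert ml.classify_feature_distribution(np.full(50, 5.0)) == 0

    def test_too_few_values_errors(self):
        with pytest.raises(ml.ConfigurationError):
            ml.classify_feature_distribution(np.arange(10.0))


class TestRegularize:
    def test_log_family_worked_example(self):
        mat = pd.DataFrame({"f": [0.0, 1.0, 3.0]})
        reg, cat = ml.regularize_features(mat, families={"f": 1})
        assert np.allclose(reg["f"], [0.0, 500.0, 1000.0])

    def test_constant_feature_dropped_and_flagged(self):
        mat = pd.DataFrame({"c": [5.0] * 30, "ok": rng.normal(size=30)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg, cat = ml.regularize_features(mat, families={"c": 0, "ok": 4})
        assert "c" not in reg.columns
        assert not cat.loc["c", "retained"]

    def test_full_range_after_scaling(self, xfit):
        reg = xfit.regularized
        assert np.allclose(reg.min(axis=0), 0.0)
        assert np.allclose(reg.max(axis=0), 1000.0)

    @pytest.mark.parametrize("family", [1, 2, 3, 4, 5, 6])
    def test_monotone_transforms_preserve_rank_order(self, family):
        base = {1: np.exp(rng.normal(size=200)),
                2: rng.poisson(5.0, size=200).astype(float),
                3: rng.beta(2, 2, size=200),
                4: rng.normal(size=200),
                5: rng.standard_t(2, size=200),
                6: rng.normal(size=200) ** 3}[family]
        reg, _ = ml.regularize_features(pd.DataFrame({"f": base}), families={"f": family})
        rho = stats.spearmanr(base, reg["f"]).statistic
        assert rho == pytest.approx(1.0)

    def test_log_family_restores_normality(self):
        """Log-normally generated intensity features become approximately
        normal (|skewness| < 0.5) after the log transform."""
        sample = np.exp(rng.normal(loc=5.0, size=2000))  # intensity-scale values
        reg, _ = ml.regularize_features(pd.DataFrame({"f": sample}), families={"f": 1})
        assert abs(stats.skew(reg["f"])) < 0.5


class TestSubsample:
    def test_cap_rule(self):
        mat = pd.DataFrame(rng.normal(size=(4500, 3)),
                           index=[f"c{i}" for i in range(4500)])
        pops = pd.Series(["A"] * 3000 + ["B"] * 1500, index=mat.index)
        sub = ml.stratified_subsample(mat, pops, max_per_pop=2000,
                                      target_range=(100, 10**6), seed=0)
        counts = pops.loc[sub.index].value_counts()
        assert counts["A"] == 2000 and counts["B"] == 1500

    def test_cap_reduced_to_reach_target_range(self):
        mat = pd.DataFrame(rng.normal(size=(900, 2)), index=[f"c{i}" for i in range(900)])
        pops = pd.Series(np.repeat(list("ABC"), 300), index=mat.index)
        sub = ml.stratified_subsample(mat, pops, max_per_pop=300,
                                      target_range=(100, 450), seed=0)
        assert len(sub) <= 450
        assert pops.loc[sub.index].value_counts().max() == 150

    def test_identity_when_below_range(self):
        mat = pd.DataFrame(rng.normal(size=(50, 2)), index=[f"c{i}" for i in range(50)])
        pops = pd.Series(["A"] * 50, index=mat.index)
        sub = ml.stratified_subsample(mat, pops, seed=0)
        assert set(sub.index) == set(mat.index)

    def test_determinism_and_population_preservation(self, study):
        reg = study.cp.feature_matrix()
        pops = study.cp.cells["population"]
        a = ml.stratified_subsample(reg, pops, max_per_pop=50, target_range=(10, 10**6), seed=9)
        b = ml.stratified_subsample(reg, pops, max_per_pop=50, target_range=(10, 10**6), seed=9)
        assert list(a.index) == list(b.index)
        assert set(pops.loc[a.index]) == set(pops)


class TestBootstrapCorrelation:
    def test_full_size_gives_unit_correlation(self):
        mat = pd.DataFrame(rng.normal(size=(200, 5)))
        tbl = ml.bootstrap_subsample_correlation(mat, sizes=[200], reps=3, seed=0)
        assert tbl.loc[200, "mean_correlation"] == pytest.approx(1.0)

    def test_larger_subsamples_correlate_more(self):
        mat = pd.DataFrame(rng.normal(size=(2000, 20)) + rng.normal(size=20))
        tbl = ml.bootstrap_subsample_correlation(mat, sizes=[20, 1000], reps=20, seed=1)
        assert tbl.loc[1000, "mean_correlation"] >= tbl.loc[20, "mean_correlation"]

    def test_degenerate_inputs(self):
        mat = pd.DataFrame(rng.normal(size=(50, 4)))
        with pytest.raises(ml.ConfigurationError):
            ml.bootstrap_subsample_correlation(mat, sizes=[10], reps=0)
        with pytest.warns(UserWarning):
            ml.bootstrap_subsample_correlation(mat, sizes=[1], reps=2, seed=0)


# ---------------------------------------------------------------------------
# Greedy modularity
# ---------------------------------------------------------------------------

def oracle_greedy_modularity(n, edges):
    """Brute-force agglomeration: recompute modularity from scratch for every
    candidate merge and take the best (same smallest-index tie-break)."""
    m = len(edges)

    def modularity(partition):
        q = 0.0
        for comm in partition:
            inside = sum(1 for u, v in edges if u in comm and v in comm)
            deg = sum(1 for u, v in edges for x in (u, v) if x in comm)
            q += inside / m - (deg / (2 * m)) ** 2
        return q

    parts = [frozenset([i]) for i in range(n)]
    connected = lambda a, b: any((u in a and v in b) or (u in b and v in a) for u, v in edges)
    while True:
        best = None
        for a, b in itertools.combinations(parts, 2):
            if not connected(a, b):
                continue
            cand = [p for p in parts if p not in (a, b)] + [a | b]
            gain = modularity(cand) - modularity(parts)
            tie = tuple(sorted((min(a), min(b))))
            if best is None or gain > best[0] + 1e-12 or (abs(gain - best[0]) <= 1e-12 and tie < best[1]):
                best = (gain, tie, a, b)
        if best is None or best[0] <= 1e-12:
            break
        _, _, a, b = best
        parts = [p for p in parts if p not in (a, b)] + [a | b]
    return sorted([set(p) for p in parts], key=min)


@pytest.mark.parametrize("seed", range(12))
def test_greedy_modularity_matches_exhaustive_oracle(seed):
    g = np.random.default_rng(seed)
    n = int(g.integers(4, 13))
    edges = [(i, j) for i, j in itertools.combinations(range(n), 2)
             if g.random() < 0.35]
    if not edges:
        edges = [(0, 1)]
    got = sorted([set(c) for c in ml.greedy_modularity_communities(n, edges)], key=min)
    assert got == oracle_greedy_modularity(n, edges)


def test_greedy_modularity_two_cliques():
    edges = [(i, j) for i, j in itertools.combinations(range(4), 2)]
    edges += [(i + 4, j + 4) for i, j in itertools.combinations(range(4), 2)]
    edges += [(0, 4)]
    got = ml.greedy_modularity_communities(8, edges)
    assert sorted(map(sorted, got)) == [[0, 1, 2, 3], [4, 5, 6, 7]]


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def exact_corr_pair(n, rho, seed=0):
    """Two vectors with empirical Pearson correlation exactly rho."""
    g = np.random.default_rng(seed)
    x = g.normal(size=n)
    z = g.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)
    z /= z.std()
    return x, rho * x + np.sqrt(1 - rho ** 2) * z


class TestFeatureSelection:
    def test_exact_duplicate_collapsed(self):
        x = rng.normal(size=100)
        mat = pd.DataFrame({"f1": x, "f1_Copy": x, "f3": rng.normal(size=100)})
        sel = ml.select_nonredundant_features(mat)
        assert sel.retained == ["f1", "f3"]  # parsimony: fewer tokens

    def test_correlation_below_threshold_keeps_both(self):
        x, y = exact_corr_pair(500, 0.98)
        mat = pd.DataFrame({"a": x, "b": y})
        sel = ml.select_nonredundant_features(mat, r_threshold=0.99)
        assert sorted(sel.retained) == ["a", "b"]

    def test_exclusion_patterns_dropped(self):
        x = rng.normal(size=100)
        mat = pd.DataFrame({
            "Cell_AreaShape_Center_X": rng.normal(size=100),
            "Nuclei_Zernike_0_0": rng.normal(size=100),
            "Cel_Neighbors_AngleBtNghbors_Adjacent": rng.normal(size=100),
            "Cell_Intensity_Mean_mito": x,
        })
        sel = ml.select_nonredundant_features(mat)
        assert sel.retained == ["Cell_Intensity_Mean_mito"]
        assert len(sel.excluded) == 3

    def test_planted_blocks_never_merged(self, study, xfit):
        """Module blocks are correlated below 0.99, so selection communities
        never span two planted blocks."""
        blocks = study.truth.module_blocks
        comm_of = xfit.selection.community_map
        by_comm = {}
        for f, c in comm_of.items():
            by_comm.setdefault(c, set()).add(blocks[f])
        assert all(len(bs) == 1 for bs in by_comm.values())

    def test_planted_duplicates_removed(self, study, xfit):
        for a, b in study.truth.redundant_pairs:
            assert not (a in xfit.selection.retained and b in xfit.selection.retained)
            assert xfit.selection.community_map[a] == xfit.selection.community_map[b]

    def test_nan_column_errors(self):
        mat = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ml.ConfigurationError, match="a"):
            ml.select_nonredundant_features(mat)
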