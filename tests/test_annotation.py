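"""Marker scores, cell-cycle transfer, representative features, marker genes,
label transfer, batch correction, and abundance association."""


import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import morpholink as ml

rng = np.random.default_rng(21)


class TestCellCycleTransfer:
    def test_planted_linear_score_recovered(self):
        g = np.random.default_rng(0)
        X = pd.DataFrame(g.normal(size=(500, 20)),
                         columns=[f"f{i}" for i in range(20)])
        s = 0.5 * X["f3"] - 0.2 * X["f7"] + 0.02 * g.normal(size=500)
        g2m = 0.3 * X["f1"] + 0.02 * g.normal(size=500)
        train, test = X.iloc[:400], X.iloc[400:]
        model = ml.fit_cellcycle_transfer(train, s.iloc[:400], g2m.iloc[:400], alpha=0.01)
        pred = model.predict(test)
        assert np.corrcoef(pred["S"], s.iloc[400:])[0, 1] > 0.9
        assert np.corrcoef(pred["G2M"], g2m.iloc[400:])[0, 1] > 0.9
        # two independent models, never one joint fit
        assert not np.allclose(model.s_coef, model.g2m_coef)

    def test_constant_score_rejected(self):
        X = pd.DataFrame(rng.normal(size=(50, 5)))
        s = pd.Series(rng.normal(size=50), index=X.index)
        flat = pd.Series(1.0, index=X.index)
        with pytest.raises(ml.ConfigurationError, match="G2M"):
            ml.fit_cellcycle_transfer(X, s, flat)


class TestMarkerScores:
    def test_shifted_feature_scores_positive_for_its_group(self):
        X = pd.DataFrame({"f": np.r_[rng.normal(size=50) + 10, rng.normal(size=50)]},
                         index=[f"c{i}" for i in range(100)])
        lab = pd.Series(["A"] * 50 + ["B"] * 50, index=X.index)
        ms = ml.marker_scores(X, lab)
        assert ms.loc["A", "f"] > 3 and ms.loc["B", "f"] < -3

    def test_cohens_d_oracle_two_group_toy(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]},
                         index=list("abcdef"))
        lab = pd.Series(["g1"] * 3 + ["g2"] * 3, index=X.index)
        ms = ml.marker_scores(X, lab)
        a, b = X["f"][:3], X["f"][3:]
        pooled = np.sqrt(((2) * a.var(ddof=1) + (2) * b.var(ddof=1)) / 4)
        assert ms.loc["g1", "f"] == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_single_group_rejected(self):
        X = pd.DataFrame({"f": rng.normal(size=10)})
        with pytest.raises(ml.ConfigurationError):
            ml.marker_scores(X, pd.Series(["A"] * 10, index=X.index))


class TestCorrelateMarkerScores:
    def make(self):
        m = pd.DataFrame(rng.normal(size=(4, 10)),
                         index=list("ABCD"), columns=[f"f{i}" for i in range(10)])
        return m

    def test_self_correlation_diagonal_one(self):
        m = self.make()
        c = ml.correlate_marker_scores(m, m)
        assert np.allclose(np.diag(c), 1.0)

    def test_shape_and_symmetry_under_swap(self):
        a, b = self.make(), self.make().iloc[:3]
        c1 = ml.correlate_marker_scores(a, b)
        c2 = ml.correlate_marker_scores(b, a)
        assert c1.shape == (4, 3)
        assert np.allclose(c1.to_numpy(), c2.to_numpy().T)

    def test_too_few_common_features_errors(self):
        a = self.make()[["f0", "f1"]]
        with pytest.raises(ml.ConfigurationError):
            ml.correlate_marker_scores(a, a)


class TestRepresentativeFeatures:
    def make_model(self, features, intercepts, coefsums):
        coef = np.zeros((3, len(features)))
        coef[0] = coefsums  # single gene carries the sum
        return ml.CrossModalModel(
            genes=["g0", "g1", "g2"], features=list(features), coef=coef,
            intercept=pd.Series(intercepts, index=features),
            cv_stats=pd.DataFrame(index=features))

    def test_forced_arithmetic_example(self):
        ms = ml.FeatureModuleSet(
            modules={0: ["fA", "fB"]},
            loadings={0: pd.Series([0.5, 1.0], index=["fA", "fB"])},
            names={0: "m"})
        model = self.make_model(["fA", "fB"], [1.0, 1.0], [10.0, 2.0])
        tbl = ml.select_representative_features(ms, model)
        assert tbl.loc[(0, "fA"), "score"] == pytest.approx(5.0)
        assert tbl.loc[(0, "fB"), "score"] == pytest.approx(2.0)
        assert tbl.loc[(0, "fA"), "selected"]

    def test_single_feature_module_contribution_one(self):
        ms = ml.FeatureModuleSet(modules={0: ["solo"]},
                                 loadings={0: pd.Series([0.4], index=["solo"])},
                                 names={0: "m"})
        model = self.make_model(["solo"], [2.0], [4.0])
        tbl = ml.select_representative_features(ms, model)
        assert tbl.loc[(0, "solo"), "contribution"] == pytest.approx(1.0)
        assert tbl.loc[(0, "solo"), "selected"]

    def test_near_zero_intercept_guard(self):
        ms = ml.FeatureModuleSet(modules={0: ["f"]},
                                 loadings={0: pd.Series([1.0], index=["f"])},
                                 names={0: "m"})
        model = self.make_model(["f"], [0.0], [1.0])
        tbl = ml.select_representative_features(ms, model)
        assert tbl.loc[(0, "f"), "intercept_near_zero"]
        assert np.isfinite(tbl.loc[(0, "f"), "score"])


class TestFeatureMarkerGenes:
    def make_gc(self, slopes):
        s = pd.DataFrame({"f": slopes}, index=[f"g{i}" for i in range(len(slopes))])
        return ml.GeneCoefficientMatrix(slopes=s, intercepts=pd.Series({"f": 1.0}))

    def test_normal_slopes_match_two_sided_tail_count(self):
        n = 17370
        gc = self.make_gc(np.random.default_rng(5).normal(size=n))
        mk = ml.feature_marker_genes(gc, "f", sd_threshold=2.5)
        p = 2 * sps.norm.sf(2.5)
        expected = p * n
        assert abs(len(mk) - expected) <= 3 * np.sqrt(n * p * (1 - p))

    def test_outlier_gene_included(self):
        vals = np.r_[np.random.default_rng(6).normal(size=500), [30.0]]
        gc = self.make_gc(vals)
        mk = ml.feature_marker_genes(gc, "f")
        assert "g500" in mk.index

    def test_equal_slopes_give_empty_set(self):
        gc = self.make_gc(np.ones(100))
        with pytest.warns(UserWarning):
            mk = ml.feature_marker_genes(gc, "f")
        assert len(mk) == 0

    def test_count_monotone_in_threshold(self):
        gc = self.make_gc(np.random.default_rng(7).normal(size=2000))
        counts = [len(ml.feature_marker_genes(gc, "f", sd_threshold=t))
                  for t in (1.0, 1.5, 2.0, 2.5, 3.0)]
        assert counts == sorted(counts, reverse=True)


class TestLabelTransfer:
    def make_ref(self, n=50, d=10, seed=0):
        g = np.random.default_rng(seed)
        ref = pd.DataFrame(g.normal(size=(n, d)) * 10,
                           index=[f"r{i}" for i in range(n)])
        labels = pd.Series(g.integers(0, 3, size=n), index=ref.index)
        return ref, labels

    def test_identical_query_gets_label_at_distance_zero(self):
        ref, lab = self.make_ref()
        res = ml.transfer_labels_knn(ref, lab, ref.iloc[[7]])
        assert res.assignments["distance"].iloc[0] == 0.0
        assert res.assignments["label"].iloc[0] == lab.iloc[7]

    def test_distance_exactly_max_is_unassigned(self):
        ref = pd.DataFrame([[0.0]], index=["r"], columns=["f"])
        lab = pd.Series([1], index=["r"])
        res = ml.transfer_labels_knn(ref, lab, pd.DataFrame([[400.0]], index=["q"], columns=["f"]))
        assert res.assignments["label"].isna().all()
        near = ml.transfer_labels_knn(ref, lab, pd.DataFrame([[399.9]], index=["q"], columns=["f"]))
        assert near.assignments["label"].iloc[0] == 1

    def test_brute_force_nearest_neighbor_oracle(self):
        ref, lab = self.make_ref(n=50, seed=1)
        g = np.random.default_rng(2)
        query = pd.DataFrame(g.normal(size=(20, 10)) * 10,
                             index=[f"q{i}" for i in range(20)])
        res = ml.transfer_labels_knn(ref, lab, query, max_dist=np.inf)
        R, Q = ref.to_numpy(), query.to_numpy()
        for qi in range(20):
            dists = np.sqrt(((R - Q[qi]) ** 2).sum(axis=1))
            assert res.assignments["distance"].iloc[qi] == pytest.approx(dists.min())
            assert res.assignments["label"].iloc[qi] == lab.iloc[int(np.argmin(dists))]

    def test_jittered_query_recovers_most_labels(self):
        """Per-feature jitter of sd 5 in a 200-feature space stays well under
        the 400 distance budget, so nearly all labels transfer."""
        g = np.random.default_rng(3)
        centers = g.normal(size=(4, 200)) * 50
        ref = pd.DataFrame(np.repeat(centers, 100, axis=0) + g.normal(size=(400, 200)),
                           index=[f"r{i}" for i in range(400)])
        lab = pd.Series(np.repeat(np.arange(4), 100), index=ref.index)
        query = ref + g.normal(size=ref.shape) * 5
        query.index = [f"q{i}" for i in range(400)]
        res = ml.transfer_labels_knn(ref, lab, query)
        got = res.assignments["label"].to_numpy()
        assert (pd.notna(got)).all()
        assert (got == lab.to_numpy()).mean() >= 0.95
        # push one query cell out of reach
        far = query.copy()
        far.iloc[0] += 1000
        res2 = ml.transfer_labels_knn(ref, lab, far)
        assert pd.isna(res2.assignments["label"].iloc[0])

    def test_feature_mismatch_errors(self):
        ref, lab = self.make_ref()
        with pytest.raises(ml.ConfigurationError):
            ml.transfer_labels_knn(ref, lab, ref.iloc[:, :5])


class TestBatchCorrect:
    def test_constant_offset_removed(self):
        X = pd.DataFrame(rng.normal(size=(100, 5)))
        X.iloc[50:] += 100
        batches = pd.Series(["b1"] * 50 + ["b2"] * 50, index=X.index)
        corr = ml.batch_correct(X, batches)
        med1 = corr.iloc[:50].median()
        med2 = corr.iloc[50:].median()
        assert np.allclose(med1, med2)

    def test_single_batch_identity(self):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        out = ml.batch_correct(X, pd.Series(["b"] * 20, index=X.index))
        pd.testing.assert_frame_equal(out, X)

    def test_cluster_structure_preserved(self):
        g = np.random.default_rng(4)
        blobs = np.vstack([g.normal(size=(100, 10)), g.normal(size=(100, 10)) + 8])
        X = pd.DataFrame(np.vstack([blobs, blobs + 50]))
        batches = pd.Series(["b1"] * 200 + ["b2"] * 200, index=X.index)
        truth = np.tile(np.repeat([0, 1], 100), 2)
        corr = ml.batch_correct(X, batches)
        for mask in (slice(0, 200), slice(200, 400)):
            before = KMeans(2, n_init=5, random_state=0).fit_predict(X.iloc[mask])
            after = KMeans(2, n_init=5, random_state=0).fit_predict(corr.iloc[mask])
            assert adjusted_rand_score(before, after) >= 0.95


class TestAbundanceAssociation:
    def make(self, counts):
        cells = []
        for (line, cl), k in counts.items():
            cells += [(line, cl)] * k
        idx = [f"c{i}" for i in range(len(cells))]
        lab = pd.Series([c for _, c in cells], index=idx)
        lines = pd.Series([l for l, _ in cells], index=idx)
        return lab, lines

    def test_symmetric_table_log_or_zero(self):
        lab, lines = self.make({("L1", "A"): 10, ("L1", "B"): 90,
                                ("L2", "A"): 10, ("L2", "B"): 90})
        or_table, ami, ab = ml.abundance_association(lab, lines)
        assert or_table.loc[("L1", "A"), "log2_odds_ratio"] == pytest.approx(0.0)

    def test_forced_arithmetic_odds_ratio(self):
        # a=20, b=80, c=10, d=90 -> OR = 2.25
        lab, lines = self.make({("L1", "A"): 20, ("L1", "B"): 80,
                                ("L2", "A"): 10, ("L2", "B"): 90})
        or_table, _, _ = ml.abundance_association(lab, lines)
        assert or_table.loc[("L1", "A"), "log2_odds_ratio"] == pytest.approx(np.log2(2.25))

    def test_haldane_correction_on_zero_cell(self):
        lab, lines = self.make({("L1", "A"): 10, ("L1", "B"): 10,
                                ("L2", "B"): 20})
        or_table, _, _ = ml.abundance_association(lab, lines)
        v = or_table.loc[("L2", "A"), "log2_odds_ratio"]
        assert np.isfinite(v) and v < 0

    def test_ami_identity_permutation_and_oracle(self):
        lab, lines = self.make({("L1", "A"): 5, ("L2", "B"): 5})
        _, ami, _ = ml.abundance_association(lab, lines)
        assert ami["all"] == pytest.approx(1.0)
        # permuting labels does not change AMI
        remap = lab.map({"A": "B", "B": "A"})
        _, ami2, _ = ml.abundance_association(remap, lines)
        assert ami2["all"] == pytest.approx(ami["all"])

    def test_ami_matches_direct_formula_small(self):
        """AMI = (MI - E[MI]) / (mean(H_u, H_v) - E[MI]), with MI and the
        hypergeometric E[MI] computed from first principles on a 10-cell toy."""
        from math import comb, log

        lab, lines = self.make({("L1", "A"): 3, ("L1", "B"): 2,
                                ("L2", "A"): 1, ("L2", "B"): 4})
        _, ami, _ = ml.abundance_association(lab, lines)

        ct = pd.crosstab(lines, lab).to_numpy()
        N = ct.sum()
        a, b = ct.sum(axis=1), ct.sum(axis=0)
        mi = sum(
            (ct[i, j] / N) * log(N * ct[i, j] / (a[i] * b[j]))
            for i in range(len(a)) for j in range(len(b)) if ct[i, j] > 0
        )
        emi = 0.0
        for i in range(len(a)):
            for j in range(len(b)):
                lo = max(1, a[i] + b[j] - N)
                for nij in range(lo, min(a[i], b[j]) + 1):
                    p = (comb(b[j], nij) * comb(N - b[j], a[i] - nij)) / comb(N, a[i])
                    emi += p * (nij / N) * log(N * nij / (a[i] * b[j]))
        h = lambda w: -sum((x / N) * log(x / N) for x in w)
        oracle = (mi - emi) / ((h(a) + h(b)) / 2 - emi)
        assert ami["all"] == pytest.approx(oracle, abs=1e-10)

    def test_single_cluster_errors(self):
        lab, lines = self.make({("L1", "A"): 5, ("L2", "A"): 5})
        with pytest.raises(ml.ConfigurationError):
            ml.abundance_association(lab, lines)
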