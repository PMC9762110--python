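"""Effect sizes, KS tests and correlation pruning."""

import numpy as np
import pandas as pd
import pytest

from dceprost.stats import (
    cohens_d,
    correlation_prune,
    effect_size_bin,
    effect_size_report,
    ks_two_sample,
)


def brute_force_ks(a, b):
    """Max ECDF difference by scanning every pooled sample point."""
    pooled = np.concatenate([a, b])
    best = 0.0
    for x in pooled:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestCohensD:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(x, x) == 0.0

    def test_hand_computed_pooled_sd_case(self):
        # a = {2,4,6,8}, b = {1,3,5,7}: means 5 and 4, each sample variance
        # (9+1+1+9)/3 = 20/3, so s_pooled = sqrt(20/3) and d = 1/sqrt(20/3)
        a = [2.0, 4.0, 6.0, 8.0]
        b = [1.0, 3.0, 5.0, 7.0]
        assert cohens_d(a, b) == pytest.approx(1.0 / np.sqrt(20.0 / 3.0), rel=1e-12)

    def test_antisymmetric_under_swap(self, rng):
        a = rng.normal(1, 1, 40)
        b = rng.normal(0, 1.5, 60)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), rel=1e-12)

    def test_invariant_under_common_affine_transform(self, rng):
        a = rng.normal(2, 1, 50)
        b = rng.normal(0, 2, 50)
        d0 = cohens_d(a, b)
        assert cohens_d(3.7 * a + 11, 3.7 * b + 11) == pytest.approx(d0, rel=1e-10)

    def test_zero_pooled_variance_not_estimable(self):
        assert np.isnan(cohens_d([1.0, 1.0, 1.0], [1.0, 1.0]))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])

    def test_interpretation_bins(self):
        assert effect_size_bin(0.1) == "negligible"
        assert effect_size_bin(-0.35) == "small"
        assert effect_size_bin(0.65) == "medium"
        assert effect_size_bin(-1.2) == "large"


class TestKolmogorovSmirnov:
    def test_identical_samples_zero(self):
        x = np.arange(10.0)
        stat, p = ks_two_sample(x, x)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports_one(self):
        stat, _ = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert stat == 1.0

    def test_matches_brute_force_scan(self, rng):
        """Statistic equals the exhaustive ECDF-difference scan, 100 cases."""
        for _ in range(100):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.uniform(-1, 1), 1, nb)
            stat, _ = ks_two_sample(a, b)
            assert stat == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.5, 1, 60)
        s0, _ = ks_two_sample(a, b)
        s1, _ = ks_two_sample(np.exp(a), np.exp(b))
        assert s1 == pytest.approx(s0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0, 2.0])


class TestCorrelationPrune:
    def test_duplicate_feature_collapses_to_one(self, rng):
        x = rng.normal(size=200)
        table = pd.DataFrame({"a": x, "b": x * 2 + 1e-9 * rng.normal(size=200), "c": rng.normal(size=200)})
        retained, corr = correlation_prune(table, ["a", "b", "c"], 0.65)
        assert sorted(retained)[-1] == "c" and len(retained) == 2

    def test_independent_features_all_retained(self, rng):
        table = pd.DataFrame(rng.normal(size=(10_000, 5)), columns=list("abcde"))
        retained, _ = correlation_prune(table, list("abcde"), 0.65)
        assert retained == list("abcde")

    def test_loose_threshold_keeps_everything(self, rng):
        x = rng.normal(size=500)
        table = pd.DataFrame({"a": x, "b": 0.5 * x + rng.normal(size=500)})
        retained, _ = correlation_prune(table, ["a", "b"], 0.999)
        assert retained == ["a", "b"]

    def test_constant_column_rejected(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        with pytest.raises(ValueError, match="constant"):
            correlation_prune(table, ["a", "b"], 0.65)

    def test_reproduces_study_retained_set(self, rng):
        """On a feature table with the study's correlation structure, pruning
        at 0.65 keeps exactly Ktrans, Ve, TTP and AUC among the DCE features.
        """
        names = ["ttp", "ire", "me", "auc", "ktrans_parker", "ve_parker", "iaugc60"]
        corr = np.eye(7)

        def put(a, b, r):
            i, j = names.index(a), names.index(b)
            corr[i, j] = corr[j, i] = r

        # supra-threshold structure of the study: Ktrans strongly tracks
        # iAUGC60 and IRE, iAUGC60 tracks IRE and ME, and AUC tracks ME;
        # sub-threshold entries chosen so the matrix is positive definite
        put("ktrans_parker", "iaugc60", 0.85)
        put("ktrans_parker", "ire", 0.75)
        put("iaugc60", "ire", 0.74)
        put("iaugc60", "me", 0.72)
        put("me", "auc", 0.95)
        put("auc", "iaugc60", 0.55)
        put("ktrans_parker", "me", 0.45)
        put("ire", "me", 0.50)
        put("auc", "ktrans_parker", 0.35)
        put("auc", "ire", 0.40)
        put("ttp", "ire", -0.35)
        put("ttp", "ktrans_parker", -0.30)
        put("ttp", "iaugc60", -0.25)
        put("ttp", "me", -0.10)
        put("ttp", "auc", -0.10)
        put("ve_parker", "me", 0.20)
        put("ve_parker", "auc", 0.20)
        put("ve_parker", "ktrans_parker", 0.15)
        put("ve_parker", "iaugc60", 0.10)
        put("ve_parker", "ire", 0.10)
        assert np.linalg.eigvalsh(corr).min() > 0
        x = rng.multivariate_normal(np.zeros(7), corr, size=20_000)
        table = pd.DataFrame(x, columns=names)
        retained, _ = correlation_prune(table, names, 0.65)
        assert set(retained) == {"ktrans_parker", "ve_parker", "ttp", "auc"}

    def test_deterministic(self, rng):
        table = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        table["e"] = table["a"] + 0.1 * rng.normal(size=300)
        r1, _ = correlation_prune(table, list("abcde"), 0.65)
        r2, _ = correlation_prune(table, list("abcde"), 0.65)
        assert r1 == r2


class TestEffectSizeReport:
    def make_table(self, rng, n=400):
        half = n // 2
        rows = []
        for stratum, shift in (("benign", 0.0), ("low_grade", 0.4), ("high_grade", 1.0)):
            m = half if stratum == "benign" else half // 2
            rows.append(
                pd.DataFrame(
                    {
                        "adc": rng.normal(-shift, 1, m),
                        "ttp": rng.normal(-0.5 * shift, 1, m),
                        "label": "benign" if stratum == "benign" else "tumour",
                        "stratum": stratum,
                        "patient_id": "p0",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_report_shape_and_ordering(self, rng):
        table = self.make_table(rng)
        report = effect_size_report(table, features=["adc", "ttp"])
        assert set(report["stratum"]) == {"low_grade", "high_grade", "all"}
        assert len(report) == 6
        # parameters ordered by |d| over all tumours, mirroring the table layout
        all_rows = report[report["stratum"] == "all"]
        ds = all_rows.sort_index()["cohens_d_abs"].to_numpy()
        assert ds[0] >= ds[1]

    def test_counts_and_bins_present(self, rng):
        report = effect_size_report(self.make_table(rng), features=["adc"])
        assert (report["n_benign"] > 1).all()
        assert report["effect_size_bin"].isin(["negligible", "small", "medium", "large"]).all()
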