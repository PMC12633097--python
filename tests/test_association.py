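"""Trait associations: correlations, group tests, regression scans,
multiplicity control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vascnet as v
from vascnet.synthio import ordinal4_probabilities
from conftest import make_matrix
from _oracles import bh_oracle, tukey_oracle


def _manifest(n, **cols):
    idx = [f"S{j}" for j in range(n)]
    base = {"batch": ["b"] * n, "is_gis": [False] * n}
    base.update(cols)
    return v.SampleManifest(pd.DataFrame(base, index=idx))


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("bonferroni", "BH"):
            assert v.adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_stepup_forced_example(self):
        out = v.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert np.allclose(out, 0.04)

    def test_bonferroni(self):
        assert np.allclose(v.adjust_pvalues([0.01, 0.4], "bonferroni"),
                           [0.02, 0.8])

    def test_random_vectors_match_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 40))
            assert np.allclose(v.adjust_pvalues(p, "BH"), bh_oracle(p),
                               atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            v.adjust_pvalues([0.1, 1.2], "BH")

    def test_bonferroni_set_subset_of_bh_set(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(0, 1e-4, 5), rng.uniform(size=50)])
        bonf = v.adjust_pvalues(p, "bonferroni") < 0.05
        bh = v.adjust_pvalues(p, "BH") < 0.05
        assert np.all(bh[bonf])


class TestMeTrait:
    def test_trait_equal_to_me_gives_r_one(self):
        rng = np.random.default_rng(2)
        ME = pd.DataFrame(rng.normal(size=(2, 50)), index=["M1", "M2"],
                          columns=[f"S{j}" for j in range(50)])
        man = _manifest(50, mytrait=ME.loc["M1"].to_numpy())
        out = v.me_trait_association(ME, man, ["mytrait"])
        row = out[(out["id"] == "M1")].iloc[0]
        assert row["effect"] == pytest.approx(1.0)
        assert row["p"] <= 1e-300

    def test_p_matches_t_tail_oracle(self):
        rng = np.random.default_rng(3)
        ME = pd.DataFrame(rng.normal(size=(1, 40)), index=["M1"],
                          columns=[f"S{j}" for j in range(40)])
        y = 0.4 * ME.loc["M1"].to_numpy() + rng.normal(size=40)
        man = _manifest(40, mytrait=y)
        out = v.me_trait_association(ME, man, ["mytrait"]).iloc[0]
        r = out["effect"]
        t = r * np.sqrt((40 - 2) / (1 - r ** 2))
        assert out["p"] == pytest.approx(2 * stats.t.sf(abs(t), 38), rel=1e-10)

    def test_constant_trait_rejected(self):
        ME = pd.DataFrame(np.random.default_rng(4).normal(size=(1, 20)),
                          index=["M1"], columns=[f"S{j}" for j in range(20)])
        man = _manifest(20, flat=np.ones(20))
        with pytest.raises(ValueError, match="constant"):
            v.me_trait_association(ME, man, ["flat"])

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        hits, total = 0, 0
        for _ in range(40):
            ME = pd.DataFrame(rng.normal(size=(10, 120)),
                              index=[f"M{i}" for i in range(10)],
                              columns=[f"S{j}" for j in range(120)])
            man = _manifest(120, mytrait=rng.normal(size=120))
            out = v.me_trait_association(ME, man, ["mytrait"])
            hits += int((out["p"] < 0.05).sum())
            total += len(out)
        frac = hits / total
        half = 1.96 * np.sqrt(0.05 * 0.95 / total)
        assert abs(frac - 0.05) < half + 0.01


class TestDifferentialAbundance:
    def test_identical_groups_zero_log2fc(self):
        vals = np.tile(np.arange(1.0, 11.0), (3, 1))
        X = make_matrix(vals, scale_tag="regressed")
        man = _manifest(10, group=["a"] * 5 + ["b"] * 5)
        # make group means equal: values repeat the same pattern per half
        vals2 = np.column_stack([vals[:, :5], vals[:, :5]])
        X = make_matrix(vals2, scale_tag="regressed")
        out = v.differential_abundance(X, man, "group", mode="ttest")
        assert np.allclose(out["effect"], 0.0)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(6)
        n_per = 30
        vals = rng.normal(0, 0.3, size=(50, 2 * n_per))
        vals[:, n_per:] += 1.0
        X = make_matrix(vals, scale_tag="regressed")
        man = _manifest(2 * n_per, group=["ctl"] * n_per + ["dz"] * n_per)
        out = v.differential_abundance(X, man, "group", mode="ttest")
        assert out["effect"].between(0.8, 1.2).mean() > 0.95
        assert (out["p"] < 0.05).all()

    def test_tukey_matches_studentized_range(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, size=12) for m in (0.0, 0.6, 1.5)]
        vals = np.concatenate(groups)[None, :]
        X = make_matrix(vals, scale_tag="regressed")
        man = _manifest(36, group=np.repeat(["a", "b", "c"], 12))
        out = v.differential_abundance(X, man, "group", mode="anova_tukey")
        for _, row in out.iterrows():
            j, i = row["comparison"].split("-")
            gi = {"a": 0, "b": 1, "c": 2}
            expected = tukey_oracle(groups, gi[i], gi[j])
            assert row["p"] == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_tiny_tukey_p_replaced_by_bonferroni(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 0.05, size=25) for m in (0.0, 4.0, 9.0)]
        vals = np.concatenate(groups)[None, :]
        X = make_matrix(vals, scale_tag="regressed")
        man = _manifest(75, group=np.repeat(["a", "b", "c"], 25))
        out = v.differential_abundance(X, man, "group", mode="anova_tukey")
        assert (out["flag"] == "bonferroni_fallback").any()
        fb = out[out["flag"] == "bonferroni_fallback"].iloc[0]
        assert 0 <= fb["p"] <= 1

    def test_small_group_skipped(self):
        vals = np.ones((2, 5)) * np.arange(5)
        X = make_matrix(vals, scale_tag="regressed")
        man = _manifest(5, group=["a"] * 4 + ["b"])
        out = v.differential_abundance(X, man, "group", mode="ttest")
        assert (out["flag"] == "too_few_obs").all()


class TestProteomewideScan:
    @staticmethod
    def _ordinal_outcome(rng, x, beta):
        cum = 1 / (1 + np.exp(-(np.array([-1.1, 0.0, 1.1])[None, :]
                                - beta * x[:, None])))
        u = rng.random(len(x))
        return (u[:, None] > np.hstack([cum, np.ones((len(x), 1))])).sum(1)

    def test_ordinal_recovers_planted_beta(self):
        rng = np.random.default_rng(9)
        n, p = 500, 30
        vals = rng.standard_normal((p, n))
        y = self._ordinal_outcome(rng, vals[0], 0.8)
        # outcome driven by protein 0 only
        man = _manifest(n, caa=y)
        X = make_matrix(vals[:1], scale_tag="regressed")
        out = v.proteomewide_scan(X, man, "caa", "ordinal")
        assert 0.6 <= out["effect"].iloc[0] <= 1.0
        assert out["p"].iloc[0] < 1e-6

    def test_linear_matches_ols_oracle(self):
        rng = np.random.default_rng(10)
        n = 80
        vals = rng.standard_normal((3, n))
        y = 0.5 * vals[0] + rng.normal(size=n)
        man = _manifest(n, wmh=y)
        X = make_matrix(vals, scale_tag="regressed")
        out = v.proteomewide_scan(X, man, "wmh", "linear")
        lr = stats.linregress(vals[0], y)
        # outcome ~ protein: slope and p agree with the two-variable fit
        assert out["effect"].iloc[0] == pytest.approx(lr.slope, rel=1e-10)
        assert out["p"].iloc[0] == pytest.approx(lr.pvalue, rel=1e-8)

    def test_logistic_sign_and_significance(self):
        rng = np.random.default_rng(11)
        n = 400
        x = rng.standard_normal(n)
        pr = 1 / (1 + np.exp(-0.9 * x))
        yb = (rng.random(n) < pr).astype(int)
        man = _manifest(n, mb=yb)
        X = make_matrix(x[None, :], scale_tag="regressed")
        out = v.proteomewide_scan(X, man, "mb", "logistic")
        assert out["effect"].iloc[0] > 0
        assert out["p"].iloc[0] < 1e-4

    def test_bonferroni_cutoff_reported(self):
        rng = np.random.default_rng(12)
        vals = rng.standard_normal((20, 60))
        man = _manifest(60, wmh=rng.normal(size=60))
        X = make_matrix(vals, scale_tag="regressed")
        out = v.proteomewide_scan(X, man, "wmh", "linear", adjust="bonferroni")
        assert out.attrs["bonferroni_cutoff"] == pytest.approx(0.05 / 20)

    def test_covariate_adjustment_changes_fit(self):
        rng = np.random.default_rng(13)
        n = 200
        age = rng.normal(75, 8, n)
        x = 0.05 * age + rng.standard_normal(n)
        y = 0.1 * (age - 75) + rng.normal(size=n)   # outcome driven by age
        man = _manifest(n, wmh=y, age=age)
        X = make_matrix(x[None, :], scale_tag="regressed")
        raw = v.proteomewide_scan(X, man, "wmh", "linear")
        adj = v.proteomewide_scan(X, man, "wmh", "linear", covariates=["age"])
        assert raw["p"].iloc[0] < adj["p"].iloc[0]


class TestProteinTraitBicor:
    def test_trait_equal_to_protein(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(size=(5, 40))
        man = _manifest(40, caa=vals[2])
        X = make_matrix(vals, scale_tag="regressed")
        out = v.protein_trait_bicor(X, man, "caa")
        assert out.set_index("id").loc["P2", "effect"] == pytest.approx(1.0)

    def test_matches_direct_bicor_and_t(self):
        rng = np.random.default_rng(15)
        vals = rng.normal(size=(8, 35))
        y = rng.normal(size=35)
        man = _manifest(35, caa=y)
        X = make_matrix(vals, scale_tag="regressed")
        out = v.protein_trait_bicor(X, man, "caa").set_index("id")
        for g in range(8):
            r = v.bicor(vals[g], y)
            t = r * np.sqrt(33 / (1 - r ** 2))
            assert out.loc[f"P{g}", "effect"] == pytest.approx(r, abs=1e-12)
            assert out.loc[f"P{g}", "p"] == pytest.approx(
                2 * stats.t.sf(abs(t), 33), rel=1e-9)

    def test_positive_negative_split_counts(self):
        rng = np.random.default_rng(16)
        y = rng.normal(size=60)
        vals = np.vstack([y + rng.normal(0, 0.2, 60),
                          -y + rng.normal(0, 0.2, 60),
                          rng.normal(size=(5, 60))])
        man = _manifest(60, caa=y)
        out = v.protein_trait_bicor(make_matrix(vals, scale_tag="regressed"),
                                    man, "caa")
        assert out.attrs["n_positive_significant"] >= 1
        assert out.attrs["n_negative_significant"] >= 1
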