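import math

import numpy as np
import pandas as pd
import pytest

from hipecpk.compare import compare_tissues, limits_of_agreement, oneway_reml

Z95 = 1.959963984540054


def paired_table(diffs, base=100.0):
    """Balanced two-tissue design: one catheter per tissue per animal;
    animal i has log-difference diffs[i] between tissue b and tissue a."""
    rows = []
    for i, d in enumerate(diffs):
        animal_mean = math.log(base) + 0.3 * i  # animal effect
        rows.append(
            {"animal_id": f"p{i}", "catheter_id": f"p{i}a", "tissue": "a", "auc_0_last": math.exp(animal_mean)}
        )
        rows.append(
            {"animal_id": f"p{i}", "catheter_id": f"p{i}b", "tissue": "b", "auc_0_last": math.exp(animal_mean + d)}
        )
    return pd.DataFrame(rows)


class TestCompareTissues:
    def test_identical_values_give_null(self):
        df = paired_table([0.0] * 4)
        df["auc_0_last"] = 50.0
        r = compare_tissues(df, "auc_0_last", "a", "b")
        assert r.ratio == 1.0 and r.p_value == pytest.approx(1.0)

    def test_exact_twofold_shift(self):
        df = paired_table([math.log(2.0)] * 5)
        r = compare_tissues(df, "auc_0_last", "a", "b")
        assert r.ratio == pytest.approx(2.0, rel=1e-6)

    def test_balanced_design_matches_paired_difference_oracle(self):
        # with one observation per tissue per animal, the REML mixed model
        # reduces to the classic paired analysis: estimate = mean log-diff,
        # SE = sd(diff)/sqrt(n·2)... the mixed Wald SE equals sd(diff)/sqrt(n)
        rng = np.random.default_rng(8)
        diffs = rng.normal(0.4, 0.25, size=6)
        df = paired_table(list(diffs))
        r = compare_tissues(df, "auc_0_last", "a", "b")
        est = float(np.mean(diffs))
        se = float(np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
        assert math.log(r.ratio) == pytest.approx(est, abs=1e-6)
        assert math.log(r.ci_high) == pytest.approx(est + Z95 * se, abs=1e-4)
        assert math.log(r.ci_low) == pytest.approx(est - Z95 * se, abs=1e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        df = paired_table(list(rng.normal(0.5, 0.3, size=5)))
        r_ab = compare_tissues(df, "auc_0_last", "a", "b")
        r_ba = compare_tissues(df, "auc_0_last", "b", "a")
        assert r_ab.ratio * r_ba.ratio == pytest.approx(1.0, rel=1e-9)
        assert r_ab.p_value == pytest.approx(r_ba.p_value, abs=1e-9)

    def test_no_animal_variance_reduces_to_two_sample_estimate(self):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(6):
            for t, mu in (("a", 1.0), ("b", 1.7)):
                rows.append(
                    {
                        "animal_id": f"p{i}",
                        "catheter_id": f"p{i}{t}",
                        "tissue": t,
                        "auc_0_last": math.exp(rng.normal(mu, 0.2)),
                    }
                )
        df = pd.DataFrame(rows)
        r = compare_tissues(df, "auc_0_last", "a", "b")
        la = np.log(df[df.tissue == "a"]["auc_0_last"])
        lb = np.log(df[df.tissue == "b"]["auc_0_last"])
        assert math.log(r.ratio) == pytest.approx(float(lb.mean() - la.mean()), abs=1e-4)

    def test_missing_tissue_rejected(self):
        df = paired_table([0.1] * 3)
        with pytest.raises(ValueError):
            compare_tissues(df, "auc_0_last", "a", "zz")

    def test_single_animal_rejected(self):
        df = paired_table([0.1])
        with pytest.raises(ValueError):
            compare_tissues(df, "auc_0_last", "a", "b")


def duplicate_table(animal_offsets, d):
    """Each animal has two catheters with log-values (offset − d, offset + d)."""
    rows = []
    for i, off in enumerate(animal_offsets):
        for k, sign in enumerate((-1, 1)):
            rows.append(
                {
                    "animal_id": f"p{i}",
                    "catheter_id": f"p{i}c{k}",
                    "organ": "liver",
                    "c_max": math.exp(off + sign * d),
                }
            )
    return pd.DataFrame(rows)


class TestLimitsOfAgreement:
    def test_identical_duplicates_give_factor_one(self):
        df = duplicate_table([1.0, 2.0, 1.5], d=0.0)
        r = limits_of_agreement(df, "liver", "c_max", ci=False)
        assert r.loa_factor == pytest.approx(1.0)
        assert r.sigma_within == 0.0

    def test_two_by_two_matches_anova_oracle(self):
        # 2 animals far apart, pairs at ±d: within mean square = 2 d²
        d = 0.2
        df = duplicate_table([0.0, 3.0], d=d)
        r = limits_of_agreement(df, "liver", "c_max", ci=False)
        sigma_e = math.sqrt(2.0) * d  # sqrt of the within-animal mean square
        assert r.sigma_within == pytest.approx(sigma_e, rel=1e-6)
        assert r.loa_factor == pytest.approx(math.exp(Z95 * math.sqrt(2.0) * sigma_e), rel=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        df = duplicate_table(list(rng.normal(1.0, 0.5, size=6)), d=0.15)
        r1 = limits_of_agreement(df, "liver", "c_max", ci=False)
        df2 = df.copy()
        df2["c_max"] *= 37.5
        r2 = limits_of_agreement(df2, "liver", "c_max", ci=False)
        assert r2.loa_factor == pytest.approx(r1.loa_factor, rel=1e-6)

    def test_monte_carlo_recovery_of_known_sigma(self):
        # 100 quick replicates: the mean estimated factor approaches the truth
        sigma, sigma_animal = 0.25, 0.4
        truth = math.exp(Z95 * math.sqrt(2.0) * sigma)
        rng = np.random.default_rng(12)
        factors = []
        for _ in range(100):
            rows = []
            for i in range(8):
                a = rng.normal(0.0, sigma_animal)
                for k in range(2):
                    rows.append(
                        {
                            "animal_id": f"p{i}",
                            "catheter_id": f"p{i}c{k}",
                            "organ": "rectum",
                            "c_max": math.exp(1.0 + a + rng.normal(0.0, sigma)),
                        }
                    )
            r = limits_of_agreement(pd.DataFrame(rows), "rectum", "c_max", ci=False)
            factors.append(r.loa_factor)
        assert np.mean(factors) == pytest.approx(truth, rel=0.15)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(13)
        df = duplicate_table(list(rng.normal(0.0, 0.4, size=8)), d=0.2)
        # jitter so the duplicates are not perfectly symmetric
        df["c_max"] *= np.exp(rng.normal(0.0, 0.05, size=len(df)))
        r = limits_of_agreement(df, "liver", "c_max", n_boot=200, seed=5)
        assert r.ci_low <= r.loa_factor <= r.ci_high
        assert r.ci_low >= 1.0

    def test_bootstrap_deterministic_given_seed(self):
        df = duplicate_table([0.0, 1.0, 2.0], d=0.1)
        r1 = limits_of_agreement(df, "liver", "c_max", n_boot=100, seed=9)
        r2 = limits_of_agreement(df, "liver", "c_max", n_boot=100, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_no_duplicates_rejected(self):
        df = pd.DataFrame(
            {
                "animal_id": ["p1", "p2"],
                "catheter_id": ["c1", "c2"],
                "organ": ["liver", "liver"],
                "c_max": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            limits_of_agreement(df, "liver", "c_max")


class TestOnewayREML:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(14)
        y, g = [], []
        for i in range(7):
            a = rng.normal(0.0, 0.35)
            for _ in range(3):
                y.append(0.5 + a + rng.normal(0.0, 0.2))
                g.append(i)
        y, g = np.array(y), np.array(g)
        mu, sa, se = oneway_reml(y, g)
        fit = sm.MixedLM(y, np.ones((len(y), 1)), groups=g).fit(reml=True)
        assert mu == pytest.approx(float(fit.params[0]), abs=1e-5)
        assert se == pytest.approx(float(np.sqrt(fit.scale)), rel=1e-3)
        assert sa == pytest.approx(float(np.sqrt(np.asarray(fit.cov_re)[0, 0])), rel=1e-3)
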