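"""Ordered-quantile transform, mixed models, LRT, slope contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import formantmod as fm
from formantmod.stats import ModelSpec


def brute_force_ordernorm(train, x):
    """Independent rank implementation: score of each training value is
    Phi^-1((rank - 0.5)/n) with average ranks for ties."""
    train = np.sort(np.asarray(train, dtype=float))
    n = train.size
    scores = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    out = []
    for v in np.atleast_1d(x):
        exact = np.nonzero(train == v)[0]
        if exact.size:
            out.append(scores[exact].mean())
        else:
            out.append(np.interp(v, train, scores))
    return np.array(out)


def make_linear_dataset(rng, slope_bl=0.0, slope_cd=0.02, n_groups=30, per_group=6,
                        group_sd=0.5, noise_sd=1.0):
    rows = []
    for g in range(n_groups):
        vt = "BL" if g % 2 == 0 else "CD"
        b = rng.normal(0, group_sd)
        for _ in range(per_group):
            day = rng.integers(1, 55)
            slope = slope_bl if vt == "BL" else slope_cd
            rows.append(
                {
                    "voc_id": f"g{g}",
                    "session_id": f"s{g % 10}",
                    "vocal_type": vt,
                    "day": float(day),
                    "value": 10 + b + slope * day + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


class TestOrderNorm:
    def test_median_maps_to_zero_odd_n(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.0])
        t = fm.ordernorm_fit(np.r_[x, 10, 11, 12])  # n = 10 -> even; use odd:
        t = fm.ordernorm_fit(np.r_[x, 10, 11, 12, 13])  # n = 11
        assert t.apply(np.median(np.r_[x, 10, 11, 12, 13])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_rank_implementation(self):
        rng = np.random.default_rng(0)
        train = rng.gamma(2.0, 3.0, size=101)
        t = fm.ordernorm_fit(train)
        assert np.allclose(t.apply(train), brute_force_ordernorm(train, train), atol=1e-10)

    def test_training_sample_hits_normal_score_grid(self):
        rng = np.random.default_rng(1)
        train = rng.lognormal(size=51)  # distinct values a.s.
        t = fm.ordernorm_fit(train)
        got = np.sort(t.apply(train))
        expected = sps.norm.ppf((np.arange(1, 52) - 0.5) / 51)
        assert np.allclose(got, expected, atol=1e-10)

    def test_monotonicity_with_extrapolation(self):
        rng = np.random.default_rng(2)
        t = fm.ordernorm_fit(rng.normal(size=40))
        grid = np.linspace(-10, 10, 500)
        out = t.apply(grid)
        assert np.all(np.diff(out) >= 0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fm.ordernorm_fit(np.full(20, 3.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fm.ordernorm_fit(np.arange(5.0))


class TestFitModel:
    def test_null_equals_full_gives_unit_p(self):
        rng = np.random.default_rng(3)
        df = make_linear_dataset(rng)
        spec = ModelSpec(response="value", fixed="1", random="voc_id",
                         drop_nonsig_interactions=False)
        res = fm.fit_model(spec, df)
        assert res.lrt_chi2 == pytest.approx(0.0, abs=1e-6)
        assert res.lrt_p == 1.0

    def test_known_slopes_recovered(self):
        """Simulated BL slope 0, CD slope +0.02/day: both inside their 95% CIs."""
        rng = np.random.default_rng(4)
        df = make_linear_dataset(rng, n_groups=60, per_group=8)
        spec = ModelSpec(response="value", fixed="vocal_type * day", random="voc_id",
                         transform="none", drop_nonsig_interactions=False)
        res = fm.fit_model(spec, df)
        slopes, contrast = fm.group_slopes(res, df)
        bl = slopes[slopes.vocal_type == "BL"].iloc[0]
        cd = slopes[slopes.vocal_type == "CD"].iloc[0]
        assert bl.ci_lo <= 0.0 <= bl.ci_hi
        assert cd.ci_lo <= 0.02 <= cd.ci_hi
        assert contrast["p"] < 0.05

    def test_ci_coverage_of_true_slope(self):
        """95% CIs cover the simulated CD slope at close to nominal rate."""
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            df = make_linear_dataset(rng, n_groups=24, per_group=5)
            spec = ModelSpec(response="value", fixed="vocal_type * day", random="voc_id",
                             transform="none", drop_nonsig_interactions=False)
            res = fm.fit_model(spec, df)
            slopes, _ = fm.group_slopes(res, df)
            cd = slopes[slopes.vocal_type == "CD"].iloc[0]
            hits += cd.ci_lo <= 0.02 <= cd.ci_hi
        # binomial(40, 0.95) central mass
        assert hits >= 33

    def test_interaction_type_one_error_rate(self):
        """With no true interaction, the retention rule keeps it ~5% of the
        time (binomial check at alpha = 0.05)."""
        rng = np.random.default_rng(6)
        kept = 0
        n_rep = 100
        for _ in range(n_rep):
            df = make_linear_dataset(rng, slope_bl=0.01, slope_cd=0.01,
                                     n_groups=20, per_group=4)
            spec = ModelSpec(response="value", fixed="vocal_type * day", random="voc_id",
                             transform="none")
            res = fm.fit_model(spec, df)
            kept += ":" in " ".join(res.coefficients.index)
        # 95% binomial band around 5/100
        assert kept <= 11

    def test_singular_fit_falls_back_to_session(self):
        """Zero group variance with one row per group triggers the session
        fallback."""
        rng = np.random.default_rng(7)
        df = make_linear_dataset(rng, n_groups=40, per_group=1, group_sd=0.0)
        df["voc_id"] = [f"v{i}" for i in range(len(df))]
        spec = ModelSpec(response="value", fixed="vocal_type * day", random="voc_id",
                         fallback_random="session_id", transform="none")
        res = fm.fit_model(spec, df)
        assert res.random_group == "session_id"

    def test_single_vocal_type_rejected(self):
        rng = np.random.default_rng(8)
        df = make_linear_dataset(rng)
        with pytest.raises(ValueError):
            fm.fit_model(
                ModelSpec(response="value", fixed="day", random="voc_id"),
                df[df.vocal_type == "BL"],
            )


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(9)
    df = make_linear_dataset(rng, n_groups=40, per_group=6)
    spec = ModelSpec(response="value", fixed="vocal_type * day", random="voc_id",
                     transform="none", drop_nonsig_interactions=False)
    res = fm.fit_model(spec, df)
    return res, df


class TestGroupSlopes:
    def test_slope_algebra(self, fitted):
        """CD slope = beta_day + beta_day:CD; BL slope = beta_day."""
        res, df = fitted
        slopes, _ = fm.group_slopes(res, df)
        beta = res.coefficients["estimate"]
        b_day = beta["day"]
        b_int = beta[[i for i in beta.index if ":" in i and "day" in i][0]]
        assert slopes[slopes.vocal_type == "BL"].slope.iloc[0] == pytest.approx(b_day)
        assert slopes[slopes.vocal_type == "CD"].slope.iloc[0] == pytest.approx(b_day + b_int)

    def test_contrast_se_is_interaction_se(self, fitted):
        """With two groups the slope-difference SE equals the SE of the
        day:vocal_type coefficient (covariance algebra)."""
        res, df = fitted
        _, contrast = fm.group_slopes(res, df)
        int_term = [i for i in res.coefficients.index if ":" in i and "day" in i][0]
        assert contrast["se"] == pytest.approx(res.coefficients.loc[int_term, "se"], rel=1e-6)

    def test_lrt_invariant_to_day_shift(self):
        rng = np.random.default_rng(10)
        df = make_linear_dataset(rng)
        spec = ModelSpec(response="value", fixed="vocal_type * day", random="voc_id",
                         transform="none", drop_nonsig_interactions=False)
        r1 = fm.fit_model(spec, df)
        df2 = df.assign(day=df.day * 2.0 + 100.0)
        r2 = fm.fit_model(spec, df2)
        assert r1.lrt_chi2 == pytest.approx(r2.lrt_chi2, rel=1e-4)
        assert r1.lrt_chi2 >= 0

    def test_model_without_day_rejected(self):
        rng = np.random.default_rng(11)
        df = make_linear_dataset(rng)
        spec = ModelSpec(response="value", fixed="vocal_type", random="voc_id",
                         transform="none", drop_nonsig_interactions=False)
        res = fm.fit_model(spec, df)
        with pytest.raises(ValueError):
            fm.group_slopes(res, df)


class TestDivergenceRecovery:
    def test_md_slope_contrast_on_synthetic_training(self, cleaned_dataset):
        """On generated training data the modulation-depth model finds a
        steeper CD-than-BL day slope for F1 (the learning signature)."""
        cleaned, _ = cleaned_dataset
        from formantmod.metrics import metric_long_table

        lt = metric_long_table(cleaned)
        md = lt[(lt.metric == "md") & (lt.formant == "F1")]
        spec = ModelSpec(response="value", fixed="vocal_type * day", random="voc_id",
                         fallback_random="session_id")
        res = fm.fit_model(spec, md)
        slopes, contrast = fm.group_slopes(res, md)
        cd = slopes[slopes.vocal_type == "CD"].slope.iloc[0]
        bl = slopes[slopes.vocal_type == "BL"].slope.iloc[0]
        assert cd > bl
        assert contrast["p"] < 0.05
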