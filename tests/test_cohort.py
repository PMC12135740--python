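import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from equirhythm.cohort import (
    DegenerateModelError,
    GROUP_ALL,
    GROUP_CARDIAC,
    GROUP_NON_CARDIAC,
    build_design,
    build_group_summary,
    chan_band,
    collinearity_screen,
    fit_mixed_logistic,
    fit_mixed_poisson,
    prevalence,
    render_pct,
    round_pct,
    spearman,
    summary_to_frame,
)
from equirhythm.datasets import reference_workouts


class TestPrevalence:
    def test_exact_values(self):
        assert round_pct(prevalence(109, 202)) == 54.0
        assert round_pct(prevalence(0, 7)) == 0.0
        assert round_pct(prevalence(13, 737)) == 1.8

    def test_full_precision_retained(self):
        assert prevalence(1, 3) == pytest.approx(100 / 3)

    def test_scale_free(self):
        for count, n in [(3, 7), (10, 40), (0, 5)]:
            assert prevalence(count, n) == pytest.approx(prevalence(5 * count, 5 * n))

    def test_zero_n_undefined(self):
        with pytest.raises(ValueError):
            prevalence(0, 0)

    def test_render_drops_trailing_zero(self):
        assert render_pct(prevalence(109, 202)) == "54"
        assert render_pct(prevalence(141, 535)) == "26.4"


class TestChanBand:
    @pytest.mark.parametrize(
        "rho,band",
        [
            (0.0, "None"),
            (0.1, "Poor"),
            (0.2, "Fair"),  # right-open boundaries
            (0.37, "Fair"),
            (0.6, "Moderate"),
            (0.8, "Strong"),
            (0.999, "Strong"),
            (1.0, "Perfect"),
            (-0.37, "Fair"),
            (-1.0, "Perfect"),
        ],
    )
    def test_bands(self, rho, band):
        assert chan_band(rho) == band

    def test_domain(self):
        with pytest.raises(ValueError):
            chan_band(1.2)


class TestSpearman:
    def test_perfect_increasing(self):
        result = spearman([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], range(10))
        assert result.rho == pytest.approx(1.0)
        assert result.band == "Perfect"

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base)
        assert spearman(x, y**3).rho == pytest.approx(base)

    def test_null_bound(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert abs(spearman(x, y).rho) < 0.08  # ~2.5 / sqrt(n)

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_p_small_n_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 2.0, 4.0, 3.0]
        result = spearman(x, y)
        # independent oracle: enumerate all permutations with scipy
        rho_obs = stats.spearmanr(x, y).statistic
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(stats.spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12:
                count += 1
        assert result.p_value == pytest.approx(count / total)

    def test_exact_p_perfect_n5(self):
        result = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        # only the identity and the reversal reach |rho| = 1: 2 / 5!
        assert result.p_value == pytest.approx(2 / 120)


@pytest.fixture(scope="module")
def rows():
    return build_group_summary(reference_workouts())


class TestGroupSummary:

    @staticmethod
    def pick(rows, group, type_):
        (row,) = [r for r in rows if r.group == group and r.type == type_]
        return row

    def test_cardiac_total(self, rows):
        total = self.pick(rows, GROUP_CARDIAC, "Total")
        assert total.n == 202
        assert total.arrhythmia_count == 109
        assert total.arrhythmia_pct == 54.0

    def test_non_cardiac_total(self, rows):
        total = self.pick(rows, GROUP_NON_CARDIAC, "Total")
        assert total.n == 535
        assert total.arrhythmia_count == 141
        assert total.deceleration_count == 50
        assert total.deceleration_pct == 9.3
        assert total.complex_count == 8
        assert total.complex_pct == 1.5

    def test_all_totals(self, rows):
        total = self.pick(rows, GROUP_ALL, "Total")
        assert total.n == 737
        assert total.arrhythmia_count == 250
        assert total.arrhythmia_pct == 33.9
        assert total.complex_count == 13
        assert total.complex_pct == 1.8

    def test_per_type_conservation(self, rows):
        for group in (GROUP_CARDIAC, GROUP_NON_CARDIAC, GROUP_ALL):
            block = [r for r in rows if r.group == group and r.type != "Total"]
            total = self.pick(rows, group, "Total")
            assert sum(r.n for r in block) == total.n
            for attr in ("arrhythmia_count", "deceleration_count", "complex_count"):
                assert sum(getattr(r, attr) for r in block) == getattr(total, attr)

    def test_all_equals_group_sum(self, rows):
        for type_ in ("Flat", "Gallop", "Total"):
            cardiac = self.pick(rows, GROUP_CARDIAC, type_)
            non_cardiac = self.pick(rows, GROUP_NON_CARDIAC, type_)
            combined = self.pick(rows, GROUP_ALL, type_)
            assert cardiac.n + non_cardiac.n == combined.n
            assert (
                cardiac.arrhythmia_count + non_cardiac.arrhythmia_count
                == combined.arrhythmia_count
            )

    def test_single_clean_workout(self):
        frame = reference_workouts().iloc[:1].copy()
        frame[["arrhythmia", "arrhythmia_deceleration", "arrhythmia_complex"]] = 0
        frame["n_pc"] = 0
        rows = build_group_summary(frame)
        total = [r for r in rows if r.type == "Total" and r.group == GROUP_ALL][0]
        assert total.arrhythmia_count == 0
        assert total.arrhythmia_pct == 0.0

    def test_unknown_type_rejected(self):
        frame = reference_workouts().iloc[:5].copy()
        frame.loc[frame.index[0], "type"] = "Dressage"
        with pytest.raises(ValueError, match="Dressage"):
            build_group_summary(frame)

    def test_excluded_workouts_dropped(self):
        frame = reference_workouts()
        frame.loc[frame.index[:100], "included"] = 0
        rows = build_group_summary(frame)
        total = [r for r in rows if r.group == GROUP_ALL and r.type == "Total"][0]
        assert total.n == 637

    def test_frame_shape(self, rows):
        frame = summary_to_frame(rows)
        assert {"group", "type", "n", "arrhythmia_pct"} <= set(frame.columns)


class TestCollinearityScreen:
    def test_type_mean_construction_flagged(self, rng):
        frame = reference_workouts()
        type_means = {"Flat": 140, "Hack": 147, "Trot": 145, "Jumping": 176,
                      "XC_School": 192, "Gallop": 192, "Competition": 211}
        frame["hr_peak"] = frame["type"].map(type_means) + rng.normal(0, 2, len(frame))
        design = build_design(frame, ["cardiac", "type", "hr_peak"])
        flagged = collinearity_screen(design)
        assert [name for name, _ in flagged] == ["hr_peak"]
        assert flagged[0][1] > 0.8

    def test_orthogonal_unflagged(self, rng):
        design = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        assert collinearity_screen(design) == []

    def test_duplicate_column_flagged_r2_one(self, rng):
        a = rng.normal(size=100)
        design = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
        flagged = collinearity_screen(design)
        assert len(flagged) == 1
        assert flagged[0][1] == pytest.approx(1.0)


def balanced_toy(n_horses=20, per_horse=10):
    """Every horse sees the same covariate/outcome pattern: zero
    between-horse variance by construction."""
    x = np.tile([1, 0], per_horse // 2)
    y = np.array([1, 0, 1, 0, 0, 1, 1, 0, 1, 0])
    rows = []
    for h in range(n_horses):
        for j in range(per_horse):
            rows.append(
                {"horse_id": f"H{h:02d}", "cardiac": int(x[j]), "outcome": int(y[j])}
            )
    return pd.DataFrame(rows)


class TestMixedModels:
    def test_zero_variance_reduces_to_pooled_logistic(self):
        import statsmodels.api as sm

        frame = balanced_toy()
        with pytest.warns(UserWarning, match="singular"):
            result = fit_mixed_logistic(frame, "outcome", ["cardiac"], screen=False)
        assert result.pooled_fallback
        X = np.column_stack([np.ones(len(frame)), frame["cardiac"].to_numpy(float)])
        glm = sm.GLM(
            frame["outcome"].to_numpy(float), X, family=sm.families.Binomial()
        ).fit()
        assert result.term("cardiac").ratio == pytest.approx(
            float(np.exp(glm.params[1])), abs=1e-3
        )

    def test_zero_variance_ml_hits_boundary(self):
        from equirhythm._glmm import fit_random_intercept
        import statsmodels.api as sm

        frame = balanced_toy()
        X = np.column_stack([np.ones(len(frame)), frame["cardiac"].to_numpy(float)])
        y = frame["outcome"].to_numpy(float)
        fit = fit_random_intercept(y, X, frame["horse_id"].to_numpy())
        assert fit.singular
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-3)

    def test_poisson_all_zero_degenerate(self):
        frame = balanced_toy()
        frame["n_pc"] = 0
        with pytest.raises(DegenerateModelError, match="zero"):
            fit_mixed_poisson(frame, "n_pc", ["cardiac"])

    def test_non_binary_outcome_rejected(self):
        frame = balanced_toy()
        frame["outcome"] = np.arange(len(frame))
        with pytest.raises(DegenerateModelError, match="binary"):
            fit_mixed_logistic(frame, "outcome", ["cardiac"])

    def test_effect_recovery_single_replicate(self, rng):
        n_h, n_w = 40, 10
        card = np.repeat(np.arange(n_h) < n_h // 2, n_w)
        u = np.repeat(rng.normal(0, 0.5, n_h), n_w)
        p = 1 / (1 + np.exp(-(-1.0 + np.log(3.0) * card + u)))
        frame = pd.DataFrame(
            {
                "horse_id": np.repeat([f"H{h}" for h in range(n_h)], n_w),
                "cardiac": card.astype(int),
                "arrhythmia": (rng.random(n_h * n_w) < p).astype(int),
            }
        )
        result = fit_mixed_logistic(frame, "arrhythmia", ["cardiac"])
        term = result.term("cardiac")
        assert term.ci_low <= 3.0 <= term.ci_high
        assert result.random_effect_sd < 2.0

    def test_type_reference_level(self):
        frame = reference_workouts()
        result = fit_mixed_logistic(frame, "arrhythmia", ["cardiac", "type"])
        names = [t.name for t in result.terms]
        assert "type[Flat]" not in names
        assert "type[Gallop]" in names
        assert result.reference_levels["type"] == "Flat"
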