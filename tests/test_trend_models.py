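"""Age trends: mixed model, power-series groups, aridity strata."""

import numpy as np
import pandas as pd
import pytest

from chronobef.synthetic_data import generate_study
from chronobef.trend_models import (
    bin_age_groups,
    fit_bef_age_lmm,
    group_trend,
    plot_covariates,
    stratify_aridity,
)
from conftest import one_family_bef, tiny_design


class TestBinAgeGroups:
    @pytest.mark.parametrize(
        "age, group",
        [
            (50, 2),
            (99.9, 2),
            (100, 3),
            (5_000, 4),
            (1_000, 4),  # exact power lands in the right-open interval above
            (10**6, 7),
            (9.9e6, 7),
            (5, 2),
        ],
    )
    def test_power_series_bounds(self, age, group):
        assert bin_age_groups(age) == group

    def test_overflow_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert bin_age_groups(5e8) == 7
        assert "clamped" in caplog.text

    @pytest.mark.parametrize("bad", [0, -5, float("nan")])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            bin_age_groups(bad)

    def test_representative_age_roundtrip(self):
        for g in range(2, 8):
            rep = 10 ** (g - 0.5)  # geometric midpoint of [10^(g-1), 10^g)
            assert bin_age_groups(rep) == g


def _synthetic_bef(samples, rho_fn):
    plots = plot_covariates(samples)
    return pd.DataFrame(
        dict(
            plot_id=plots.index,
            chronosequence_id=plots["chronosequence_id"],
            diversity_index="multidiversity",
            function_target="MF_avg",
            rho=[rho_fn(r) for _, r in plots.iterrows()],
            p=0.05,
            n=5,
        )
    ).reset_index(drop=True)


class TestFitBefAgeLmm:
    def test_recovers_negative_trend(self):
        s = generate_study(tiny_design(seed=1, n_chronosequences=8,
                                       plots_per_chronosequence=[4] * 8,
                                       coupling_slope=-0.12))
        bef, _, _ = one_family_bef(s, seed=1)
        fit = fit_bef_age_lmm(bef, s.samples)
        assert fit.slope < 0
        assert fit.se > 0
        assert fit.n == len(bef[~bef["rho"].isna()])

    def test_single_level_factor_matches_reduced_model(self):
        """A random factor with one observed level carries no information:
        dropping it reproduces the estimate of the model that never had it."""
        s = generate_study(tiny_design(seed=4, n_chronosequences=6,
                                       plots_per_chronosequence=[3] * 6))
        samples = s.samples.copy()
        samples["parent_material"] = "volcanic"  # collapse to one level
        bef, _, _ = one_family_bef(s, seed=4)
        fit = fit_bef_age_lmm(bef, samples)
        assert "parent_material" in fit.dropped_factors
        assert np.isfinite(fit.slope)

    def test_deterministic_response_matches_ols_exactly(self):
        """When rho is an exact linear function of log10(age), every
        variance component collapses and the fallback OLS recovers the
        line: the mixed-model slope equals the OLS slope at zero random
        variance."""
        s = generate_study(tiny_design(seed=2, n_chronosequences=6,
                                       plots_per_chronosequence=[3] * 6))
        bef = _synthetic_bef(s.samples, lambda r: 0.9 - 0.1 * r["logage"])
        fit = fit_bef_age_lmm(bef, s.samples)
        assert fit.slope == pytest.approx(-0.1, abs=1e-6)

    def test_constant_response_rejected(self):
        s = generate_study(tiny_design(seed=2))
        bef = _synthetic_bef(s.samples, lambda r: 0.5)
        with pytest.raises(ValueError, match="constant"):
            fit_bef_age_lmm(bef, s.samples)

    def test_too_few_plots_rejected(self):
        s = generate_study(tiny_design(seed=2))
        bef = _synthetic_bef(s.samples, lambda r: r["logage"])
        with pytest.raises(ValueError, match="plots"):
            fit_bef_age_lmm(bef.head(5), s.samples)


class TestGroupTrend:
    def test_linear_group_means_fit_exactly(self):
        s = generate_study(tiny_design(seed=6, age_range=(50.0, 9e6)))
        bef = _synthetic_bef(
            s.samples, lambda r: 0.8 - 0.1 * bin_age_groups(r["soil_age_years"])
        )
        gt = group_trend(bef, s.samples)
        assert gt.linear["b1"] == pytest.approx(-0.1, abs=1e-9)
        assert gt.linear["r2"] == pytest.approx(1.0)
        if not np.isnan(gt.quadratic["b2"]):
            assert gt.quadratic["b2"] == pytest.approx(0.0, abs=1e-9)

    def test_fits_match_normal_equations(self, default_study):
        bef, _, _ = one_family_bef(default_study, seed=1)
        gt = group_trend(bef, default_study.samples)
        x = gt.group_stats["age_group"].to_numpy(dtype=float)
        y = gt.group_stats["mean_rho"].to_numpy()
        # brute-force least squares via the normal equations
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert gt.linear["b0"] == pytest.approx(beta[0])
        assert gt.linear["b1"] == pytest.approx(beta[1])

    def test_default_study_group_trend_declines(self, default_study):
        bef, _, _ = one_family_bef(default_study, seed=1)
        gt = group_trend(bef, default_study.samples)
        assert gt.linear["b1"] < 0


class TestStratifyAridity:
    def test_boundary_convention(self, default_study):
        out = stratify_aridity(
            _synthetic_bef(default_study.samples, lambda r: 0.1 * r["logage"]),
            default_study.samples,
        )
        plots = plot_covariates(default_study.samples)
        part = out["partition"]
        assert (part[plots["aridity_index"] < 0.5] == "dryland").all()
        assert (part[plots["aridity_index"] >= 0.5] == "non_dryland").all()

    def test_partition_is_disjoint_and_covering(self, default_study):
        bef, _, _ = one_family_bef(default_study, seed=1)
        out = stratify_aridity(bef, default_study.samples)
        part = out["partition"]
        assert set(part.unique()) <= {"dryland", "non_dryland"}
        assert len(part) == default_study.samples["plot_id"].nunique()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_construction_oracle_dryland_flat_nondryland_declining(self, seed):
        """With zero coupling decay in drylands and a steep decay
        elsewhere, the stratified trends separate: non-drylands decline,
        drylands sit above them."""
        from chronobef.synthetic_data import StudyDesign
        s = generate_study(
            StudyDesign(seed=seed, coupling_slope=-0.15, dryland_coupling_slope=0.0,
                        organism_groups=tiny_design().organism_groups)
        )
        bef, _, _ = one_family_bef(s, seed=seed)
        out = stratify_aridity(bef, s.samples)
        dry, nondry = out["dryland"], out["non_dryland"]
        assert nondry is not None and nondry.slope < 0
        if dry is not None:
            assert dry.slope > nondry.slope
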