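"""Fitting strategies: closed forms, least squares, batch two-step."""

import numpy as np
import pytest

from filmcal import (
    CalibrationDataset,
    CalibrationParams,
    ConfigError,
    DomainError,
    DosePoint,
    FitInfeasibleError,
    UnidentifiableError,
    fit,
    FitConfig,
    fit_batch_two_step,
    fit_full,
    fit_method_i,
    fit_method_ii,
    fit_method_iii,
    generate_dataset,
    pixel_from_dose,
)
from conftest import random_valid_params

GEOM1 = CalibrationParams(247.0, 3585.0, 30.80)
GEOM3 = CalibrationParams(254.0, 3209.0, 40.18)
SCHEDULE = (16, 24, 32, 48, 64, 80, 96, 128)


def noiseless_dataset(params, doses=SCHEDULE, **kw):
    pts = tuple(DosePoint(d, pixel_from_dose(params, d)) for d in doses)
    kw.setdefault("background_pixel", params.P0)
    return CalibrationDataset(points=pts, **kw)


class TestDataset:
    def test_points_sorted_by_dose(self):
        ds = noiseless_dataset(GEOM1, doses=(128, 16, 64))
        assert tuple(ds.doses) == (16, 64, 128)

    @pytest.mark.parametrize(
        "doses", [(0.0, 40.0), (40.0, 40.0)], ids=["zero-dose", "duplicate-dose"]
    )
    def test_invalid_doses_rejected(self, doses):
        pts = tuple(DosePoint(d, 300 + i) for i, d in enumerate(doses))
        with pytest.raises(DomainError):
            CalibrationDataset(points=pts)

    def test_non_monotone_pixels_rejected(self):
        pts = (DosePoint(10, 500.0), DosePoint(20, 450.0))
        with pytest.raises(DomainError):
            CalibrationDataset(points=pts)


class TestFullFit:
    def test_recovers_reference_geometry_parameters(self):
        # truth = the bundled geometry-1 eight-point fit
        res = fit_full(noiseless_dataset(GEOM1))
        assert res.params.Ps == pytest.approx(3585.0, rel=5e-4)
        assert res.params.m == pytest.approx(30.80, rel=5e-4)
        assert res.rms < 1e-6

    def test_float_background_mode_recovers_p0(self):
        ds = noiseless_dataset(GEOM1)
        res = fit_full(ds, float_background=True)
        assert res.params.P0 == pytest.approx(247.0, rel=1e-3)
        assert res.params.m == pytest.approx(30.80, rel=1e-3)

    def test_generate_and_refit_oracle(self, rng):
        # noiseless synthetic curves must be recovered essentially exactly
        for _ in range(25):
            truth = random_valid_params(rng)
            res = fit_full(noiseless_dataset(truth))
            assert res.params.Ps == pytest.approx(truth.Ps, rel=1e-6)
            assert res.params.m == pytest.approx(truth.m, rel=1e-6)

    def test_low_dose_points_leave_ps_unidentifiable(self):
        # saturation never probed: m*D/Ps < 0.01 over the whole set
        truth = CalibrationParams(245.0, 3271.0, 31.7)
        ds = noiseless_dataset(truth, doses=(0.2, 0.5, 1.0))
        with pytest.raises(UnidentifiableError):
            fit_full(ds)

    def test_too_few_points_rejected(self):
        ds = noiseless_dataset(GEOM1, doses=(40, 120))
        with pytest.raises(ConfigError):
            fit_full(ds)

    def test_order_invariance(self):
        a = fit_full(noiseless_dataset(GEOM1, doses=SCHEDULE))
        b = fit_full(noiseless_dataset(GEOM1, doses=tuple(reversed(SCHEDULE))))
        assert a.params == b.params

    def test_noise_bias_below_half_percent(self, rng):
        # 1% readout noise, 8 points: the slope estimate is unbiased to <0.5%
        truth = CalibrationParams(245.0, 3271.0, 31.7)
        ms = []
        for i in range(400):
            ds = generate_dataset(truth, SCHEDULE, 0.01, seed=int(rng.integers(2**31)))
            ms.append(fit_full(ds).params.m)
        ms = np.array(ms)
        assert abs(ms.mean() / truth.m - 1) < 0.005
        # per-fit scatter is consistent with ~1% slope uncertainty
        assert 0.005 < ms.std(ddof=1) / truth.m < 0.02


class TestMethodI:
    UNIV = dict(universal_P0=245.0, universal_Ps=3542.0)

    def test_one_point_closed_form(self):
        truth = CalibrationParams(245.0, 3542.0, 31.28)
        ds = CalibrationDataset(points=(DosePoint(80, pixel_from_dose(truth, 80)),))
        res = fit_method_i(ds, **self.UNIV)
        assert res.params.m == pytest.approx(31.28, rel=1e-12)

    def test_two_consistent_points_match_one_point(self):
        truth = CalibrationParams(245.0, 3542.0, 31.28)
        ds1 = CalibrationDataset(points=(DosePoint(80, pixel_from_dose(truth, 80)),))
        ds2 = CalibrationDataset(
            points=tuple(DosePoint(d, pixel_from_dose(truth, d)) for d in (40, 80))
        )
        m1 = fit_method_i(ds1, **self.UNIV).params.m
        m2 = fit_method_i(ds2, **self.UNIV).params.m
        assert m2 == pytest.approx(m1, rel=1e-7)

    def test_pixel_at_background_is_invalid(self):
        ds = CalibrationDataset(points=(DosePoint(80, 245.0),))
        with pytest.raises((DomainError, FitInfeasibleError)):
            fit_method_i(ds, **self.UNIV)

    def test_pixel_beyond_saturation_infeasible(self):
        ds = CalibrationDataset(points=(DosePoint(80, 4000.0),))
        with pytest.raises(FitInfeasibleError):
            fit_method_i(ds, **self.UNIV)

    def test_dispatch_via_fit_config(self):
        truth = CalibrationParams(245.0, 3542.0, 31.28)
        ds = CalibrationDataset(points=(DosePoint(80, pixel_from_dose(truth, 80)),))
        res = fit(ds, FitConfig(method="I", **self.UNIV))
        assert res.method == "I"
        assert res.params.m == pytest.approx(31.28)

    def test_config_requires_universals(self):
        with pytest.raises(ConfigError):
            FitConfig(method="I")


class TestMethodII:
    def test_one_point_closed_form(self):
        truth = CalibrationParams(240.0, 3542.0, 33.50)
        ds = CalibrationDataset(
            points=(DosePoint(80, pixel_from_dose(truth, 80)),),
            background_pixel=240.0,
        )
        res = fit_method_ii(ds, universal_Ps=3542.0)
        assert res.params.P0 == 240.0
        assert res.params.m == pytest.approx(33.50, rel=1e-12)

    def test_background_above_exposed_pixel_infeasible(self):
        ds = CalibrationDataset(
            points=(DosePoint(80, 500.0),), background_pixel=600.0
        )
        with pytest.raises(FitInfeasibleError):
            fit_method_ii(ds, universal_Ps=3542.0)

    def test_two_point_recovery(self, rng):
        for _ in range(10):
            truth = random_valid_params(rng)
            ds = CalibrationDataset(
                points=tuple(
                    DosePoint(d, pixel_from_dose(truth, d)) for d in (40, 80)
                ),
                background_pixel=truth.P0,
            )
            res = fit_method_ii(ds, universal_Ps=truth.Ps)
            assert res.params.m == pytest.approx(truth.m, rel=1e-7)


class TestMethodIII:
    def test_two_point_exact_solution(self):
        ds = CalibrationDataset(
            points=tuple(DosePoint(d, pixel_from_dose(GEOM3, d)) for d in (40, 120)),
            background_pixel=254.0,
        )
        res = fit_method_iii(ds)
        assert res.params.Ps == pytest.approx(3209.0, rel=1e-3)
        assert res.params.m == pytest.approx(40.18, rel=1e-3)

    def test_proportional_points_unidentifiable(self):
        # pixels exactly linear in dose: the saturation value is unconstrained
        ds = CalibrationDataset(
            points=(DosePoint(40, 254.0 + 40 * 30), DosePoint(120, 254.0 + 120 * 30)),
            background_pixel=254.0,
        )
        with pytest.raises(UnidentifiableError):
            fit_method_iii(ds)

    def test_superlinear_points_infeasible(self):
        ds = CalibrationDataset(
            points=(DosePoint(40, 254.0 + 1000), DosePoint(120, 254.0 + 4000)),
            background_pixel=254.0,
        )
        with pytest.raises(FitInfeasibleError):
            fit_method_iii(ds)

    def test_three_point_recovery(self, rng):
        for _ in range(10):
            truth = random_valid_params(rng)
            ds = CalibrationDataset(
                points=tuple(
                    DosePoint(d, pixel_from_dose(truth, d)) for d in (40, 80, 120)
                ),
                background_pixel=truth.P0,
            )
            res = fit_method_iii(ds)
            assert res.params.Ps == pytest.approx(truth.Ps, rel=1e-6)
            assert res.params.m == pytest.approx(truth.m, rel=1e-6)

    def test_requires_background(self):
        ds = CalibrationDataset(
            points=tuple(DosePoint(d, pixel_from_dose(GEOM3, d)) for d in (40, 120))
        )
        with pytest.raises(ConfigError):
            fit_method_iii(ds)


class TestBatchTwoStep:
    def test_identical_truth_gives_truth_ps(self):
        truth = CalibrationParams(245.0, 3271.0, 31.7)
        datasets = [noiseless_dataset(truth) for _ in range(3)]
        optimal_ps, results = fit_batch_two_step(datasets)
        assert optimal_ps == pytest.approx(truth.Ps, rel=1e-6)
        for r in results:
            assert r.params.m == pytest.approx(truth.m, rel=1e-6)

    def test_optimal_ps_is_ensemble_mean(self, rng):
        # batch variation of the saturation value ~5.7% 1-sigma
        base = CalibrationParams(245.0, 3271.0, 31.7)
        ps_draws = base.Ps * (1 + rng.normal(0, 0.057, size=6))
        datasets = [
            noiseless_dataset(CalibrationParams(base.P0, ps, base.m))
            for ps in ps_draws
        ]
        optimal_ps, _ = fit_batch_two_step(datasets)
        assert optimal_ps == pytest.approx(float(np.mean(ps_draws)), rel=1e-6)

    def test_eightfield_reference_excluded_from_average(self):
        truth = CalibrationParams(245.0, 3271.0, 31.7)
        low_ps = CalibrationParams(245.0, 3000.0, 31.7)  # cross-talk-depressed
        datasets = [
            noiseless_dataset(truth),
            noiseless_dataset(truth),
            noiseless_dataset(low_ps, is_eightfield_reference=True),
        ]
        optimal_ps, _ = fit_batch_two_step(datasets)
        assert optimal_ps == pytest.approx(truth.Ps, rel=1e-6)

    def test_needs_two_nonreference_datasets(self):
        truth = CalibrationParams(245.0, 3271.0, 31.7)
        datasets = [
            noiseless_dataset(truth),
            noiseless_dataset(truth, is_eightfield_reference=True),
        ]
        with pytest.raises(ConfigError):
            fit_batch_two_step(datasets)
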