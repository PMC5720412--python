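"""Synthetic parameter draws, datasets and 8-field film images."""

import numpy as np
import pytest

from filmcal import (
    CalibrationDataset,
    CalibrationParams,
    ConfigError,
    DosePoint,
    FilmImage,
    GeneratorConfig,
    draw_day_params,
    extract_roi,
    fit_full,
    generate_dataset,
    pixel_from_dose,
    render_eightfield_image,
)
from filmcal.errors import DomainError
from filmcal.synthetic import (
    default_eightfield_layout,
    read_film_image,
    write_film_image,
)

MEAN = CalibrationParams(245.0, 3271.0, 31.7)


class TestDrawDayParams:
    def test_zero_sd_returns_mean(self):
        cfg = GeneratorConfig(inter_day_rel_sd=(0, 0, 0))
        assert draw_day_params(cfg, 3, seed=0) == [MEAN] * 3

    def test_deterministic_per_seed(self):
        cfg = GeneratorConfig()
        assert draw_day_params(cfg, 5, seed=42) == draw_day_params(cfg, 5, seed=42)

    def test_sample_rel_sds_match_configuration(self):
        cfg = GeneratorConfig()
        draws = draw_day_params(cfg, 10_000, seed=1)
        arr = np.array([[p.P0, p.Ps, p.m] for p in draws])
        rel_sd = arr.std(axis=0, ddof=1) / arr.mean(axis=0)
        for got, want in zip(rel_sd, (0.018, 0.057, 0.077)):
            se = want / np.sqrt(2 * len(draws))
            assert abs(got - want) < 3 * se

    def test_intra_day_draws_keep_background_fixed(self):
        draws = draw_day_params(GeneratorConfig(), 50, seed=2, which="intra")
        assert all(p.P0 == MEAN.P0 for p in draws)

    def test_unphysical_sds_rejected(self):
        cfg = GeneratorConfig(inter_day_rel_sd=(0.018, 0.9, 0.9))
        with pytest.raises(ConfigError):
            draw_day_params(cfg, 200, seed=0)


class TestGenerateDataset:
    def test_zero_noise_reproduces_model(self):
        ds = generate_dataset(MEAN, readout_rel_noise=0.0, seed=0)
        assert np.allclose(ds.pixels, pixel_from_dose(MEAN, ds.doses))
        assert ds.background_pixel == MEAN.P0

    def test_fit_closes_the_loop(self):
        ds = generate_dataset(MEAN, readout_rel_noise=0.0, seed=0)
        res = fit_full(ds)
        assert res.params.Ps == pytest.approx(MEAN.Ps, rel=1e-6)
        assert res.params.m == pytest.approx(MEAN.m, rel=1e-6)

    def test_noisy_fit_scatter_near_one_percent(self):
        # 1% readout noise propagates to ~1% scatter of the fitted slope
        ms = [
            fit_full(generate_dataset(MEAN, readout_rel_noise=0.01, seed=s)).params.m
            for s in range(300)
        ]
        rel_sd = np.std(ms, ddof=1) / np.mean(ms)
        assert 0.005 < rel_sd < 0.02

    def test_empty_schedule_rejected(self):
        with pytest.raises(DomainError):
            generate_dataset(MEAN, dose_schedule=())


class TestEightfieldImage:
    def test_layout_has_eight_subfields_on_grid(self):
        layout = default_eightfield_layout()
        assert len(layout) == 8
        rows = {r for r, _, _ in layout}
        cols = {c for _, c, _ in layout}
        assert len(rows) == 2 and len(cols) == 4

    def test_noiseless_subfield_centre_equals_model(self):
        img = render_eightfield_image(MEAN, noise=0.0)
        for r, c, dose in img.subfield_layout:
            i = int(round(r / img.pitch))
            j = int(round(c / img.pitch))
            assert img.pixels[i, j] == pytest.approx(
                pixel_from_dose(MEAN, dose), rel=1e-12
            )

    def test_background_between_subfields(self):
        img = render_eightfield_image(MEAN, noise=0.0)
        assert img.pixels[0, 0] == MEAN.P0

    def test_roi_then_fit_recovers_parameters(self):
        img = render_eightfield_image(MEAN, noise=0.0)
        points = tuple(
            DosePoint(d, extract_roi(img, (r, c), 1.23))
            for r, c, d in img.subfield_layout
        )
        ds = CalibrationDataset(points=points, background_pixel=extract_roi(
            img, (5.0, 5.0), 12.3 / 2))
        res = fit_full(ds)
        assert res.params.Ps == pytest.approx(MEAN.Ps, rel=1e-3)
        assert res.params.m == pytest.approx(MEAN.m, rel=1e-3)

    def test_crosstalk_depresses_fitted_saturation(self):
        def fitted_ps(crosstalk):
            img = render_eightfield_image(MEAN, noise=0.0, crosstalk=crosstalk)
            pts = tuple(
                DosePoint(d, extract_roi(img, (r, c), 1.23))
                for r, c, d in img.subfield_layout
            )
            ds = CalibrationDataset(points=pts, background_pixel=MEAN.P0)
            return fit_full(ds).params.Ps

        assert fitted_ps(0.02) < fitted_ps(0.0)

    def test_overlapping_subfields_rejected(self):
        layout = [(20.0, 20.0, 16.0), (21.0, 21.0, 32.0)]
        with pytest.raises(DomainError):
            render_eightfield_image(MEAN, layout=layout, noise=0.0)


class TestRoiExtraction:
    def uniform_image(self, value=1000.0, n=200):
        return FilmImage(pixels=np.full((n, n), value))

    def test_uniform_image_returns_value(self):
        assert extract_roi(self.uniform_image(), (12.0, 12.0), 1.23) == 1000.0

    def test_checkerboard_mean(self):
        img = np.indices((200, 200)).sum(axis=0) % 2 * 2.0  # values {0, 2}
        assert extract_roi(FilmImage(pixels=img), (12.3, 12.3), 1.23) == 1.0

    @pytest.mark.parametrize("size_mm, npix", [(1.23, 10), (12.3, 100)])
    def test_roi_pixel_counts_at_default_pitch(self, size_mm, npix):
        # mark a block of exactly npix^2 pixels; the ROI mean must hit only it
        n = 300
        arr = np.zeros((n, n))
        i0 = 100
        arr[i0 : i0 + npix, i0 : i0 + npix] = 7.0
        centre = (i0 + npix / 2) * 0.123
        img = FilmImage(pixels=arr)
        assert extract_roi(img, (centre, centre), size_mm) == 7.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(DomainError):
            extract_roi(self.uniform_image(n=50), (1.0, 1.0), 12.3)


class TestTiffRoundTrip:
    def test_write_read_preserves_pixels_and_pitch(self, tmp_path):
        img = render_eightfield_image(MEAN, noise=0.0)
        path = tmp_path / "film.tif"
        write_film_image(img, path)
        back = read_film_image(path)
        assert back.pitch == img.pitch
        assert back.pixels.shape == img.pixels.shape
        # 16-bit quantisation only
        assert np.max(np.abs(back.pixels - img.pixels)) <= 0.5
        assert back.subfield_layout == img.subfield_layout
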