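"""Split design, model grid, best-model rule, maps, determinism, leakage."""
import numpy as np
import pandas as pd
import pytest

import fruitspec as fs
from fruitspec.workflow import REPORT_COLUMNS, ModelReport


class TestSplit:
    def test_single_stratum_97_samples_rounds_toward_calibration(self):
        stages = np.zeros(97, dtype=int)
        cal, pred = fs.split(stages, fs.SplitSpec(0.70, stratify=False, seed=1))
        assert cal.size == 68 and pred.size == 29

    def test_stratified_100_samples_four_stages(self):
        stages = np.repeat(np.arange(4), 25)
        cal, pred = fs.split(stages, fs.SplitSpec(0.70, seed=2))
        assert cal.size + pred.size == 100
        assert np.intersect1d(cal, pred).size == 0
        for s in range(4):
            n_cal = np.sum(stages[cal] == s)
            assert n_cal >= 17
            assert np.sum(stages[pred] == s) >= 1

    def test_same_seed_reproduces_partition(self):
        stages = np.repeat(np.arange(4), 10)
        spec = fs.SplitSpec(0.70, seed=5)
        c1, p1 = fs.split(stages, spec)
        c2, p2 = fs.split(stages, spec)
        assert np.array_equal(c1, c2) and np.array_equal(p1, p2)

    def test_small_stratum_rejected(self):
        stages = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="stratum"):
            fs.split(stages, fs.SplitSpec(0.70, seed=0))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            fs.SplitSpec(calibration_fraction=1.0)


@pytest.fixture(scope="module")
def grid_result():
    cfg = fs.GeneratorConfig(
        n_samples=60, region="NIR", seed=19, constituents=("ssc", "ta")
    )
    batch = fs.generate_batch(cfg)
    return batch, fs.run_grid(
        batch.spectra,
        batch.concentrations,
        chain_codes=["SM + MC", "SM + 1st Dev + MC", "SM + Log + 1st Dev + MC"],
        split_spec=fs.SplitSpec(seed=19),
        settings=fs.GridSettings(max_lv=12, n_intervals=10, refine="best"),
    )


@pytest.fixture(scope="module")
def fitted_map_model():
    cfg = fs.GeneratorConfig(
        n_samples=50, region="NIR", seed=41, constituents=("ssc",),
        noise_sd=0.0, baseline_amplitude=0.0,
    )
    batch = fs.generate_batch(cfg)
    chain = fs.parse_chain("SM + MC")
    Xt = fs.fit_apply(chain, batch.spectra)
    model = fs.fit_pls(Xt.values, batch.concentrations.values("ssc"), 3)
    return batch, chain, model


class TestRunGrid:
    def test_three_chains_yield_three_populated_rows_each(self, grid_result):
        _, result = grid_result
        frame = result.frame()
        base = frame[~frame["effective_wavelength_range_nm"].str.contains(",")]
        for name in ("ssc", "ta"):
            rows = frame[frame["parameter"] == name]
            assert len(rows) == 4  # 3 grid rows + 1 refined
            for col in ("lvs", "r2_cal", "rmsec", "r2_cv", "rmsecv"):
                assert rows[col].notna().all()

    def test_report_column_order_matches_prediction_table(self, grid_result):
        _, result = grid_result
        cols = list(result.frame().columns)
        metric_block = [
            "lvs", "r2_cal", "rmsec", "r2_cv", "rmsecv", "r2_pred", "rmsep",
        ]
        start = cols.index("lvs")
        assert cols[start : start + len(metric_block)] == metric_block
        assert cols == REPORT_COLUMNS

    def test_noiseless_batch_calibrates_almost_exactly(self, noiseless_batch):
        b = noiseless_batch
        result = fs.run_grid(
            b.spectra,
            b.concentrations,
            chain_codes=["SM + Log + MC"],
            constituents=["ssc"],
            split_spec=fs.SplitSpec(seed=3),
            settings=fs.GridSettings(max_lv=8, refine="none"),
        )
        assert result.reports[0].r2_cal >= 0.99

    def test_refined_row_reports_intervals_and_outliers(self, grid_result):
        _, result = grid_result
        refined = [r for r in result.reports if r.refined]
        assert refined
        for r in refined:
            assert r.n_variables <= 161
            assert "-" in r.effective_wavelength_range_nm

    def test_no_leakage_prediction_rows_cannot_influence_calibration(self):
        cfg = fs.GeneratorConfig(
            n_samples=40, region="NIR", seed=23, constituents=("ta",)
        )
        batch = fs.generate_batch(cfg)
        settings = fs.GridSettings(max_lv=8, refine="none")
        res1 = fs.run_grid(
            batch.spectra, batch.concentrations, ["SM + MC"],
            split_spec=fs.SplitSpec(seed=23), settings=settings,
        )
        cal_idx, pred_idx = res1.split_indices["ta"]
        # corrupt every prediction-set spectrum, rerun: the calibration-side
        # numbers and the fitted coefficients must not move at all
        tampered = batch.spectra.values.copy()
        tampered[pred_idx] = 0.5
        spectra2 = fs.SpectrumSet(
            tampered, batch.spectra.wavelengths, batch.spectra.region
        )
        res2 = fs.run_grid(
            spectra2, batch.concentrations, ["SM + MC"],
            split_spec=fs.SplitSpec(seed=23), settings=settings,
        )
        r1, r2 = res1.reports[0], res2.reports[0]
        assert (r1.r2_cal, r1.rmsec, r1.r2_cv, r1.rmsecv, r1.lvs) == (
            r2.r2_cal, r2.rmsec, r2.r2_cv, r2.rmsecv, r2.lvs
        )
        m1 = res1.models[("ta", "SM + MC", False)][0]
        m2 = res2.models[("ta", "SM + MC", False)][0]
        assert np.array_equal(m1.coef, m2.coef)

    def test_failed_configuration_recorded_not_fatal(self, nir_batch):
        result = fs.run_grid(
            nir_batch.spectra,
            nir_batch.concentrations,
            chain_codes=["SM + MC", "totally bogus"],
            constituents=["ssc"],
            split_spec=fs.SplitSpec(seed=1),
            settings=fs.GridSettings(refine="none"),
        )
        errors = [r for r in result.reports if r.error]
        assert len(errors) == 1 and "unknown" in errors[0].error
        assert any(r.rmsep is not None for r in result.reports)

    def test_report_csv_byte_identical_across_runs(self, tmp_path):
        def one_run(path):
            cfg = fs.GeneratorConfig(
                n_samples=30, region="VIS-NIR", seed=31, constituents=("phenols",)
            )
            batch = fs.generate_batch(cfg)
            res = fs.run_grid(
                batch.spectra, batch.concentrations, ["SM + MC", "SM + 2nd Dev + MC"],
                split_spec=fs.SplitSpec(seed=31),
                settings=fs.GridSettings(max_lv=6, n_intervals=8),
            )
            res.frame().to_csv(path, index=False)
            return path.read_bytes()

        assert one_run(tmp_path / "a.csv") == one_run(tmp_path / "b.csv")


class TestSelectBest:
    @staticmethod
    def row(rmsep, r2_pred, lvs=5, n_var=100):
        return ModelReport(
            parameter="x", region="NIR", pretreatment="SM + MC",
            effective_wavelength_range_nm="900-1700", n_sample=60,
            n_variables=n_var, lvs=lvs, r2_pred=r2_pred, rmsep=rmsep,
        )

    def test_lowest_rmsep_ties_broken_by_r2(self):
        rows = [self.row(0.05, 0.9), self.row(0.04, 0.8), self.row(0.04, 0.91)]
        assert fs.select_best(rows) is rows[2]

    def test_single_row_returned(self):
        rows = [self.row(0.1, 0.5)]
        assert fs.select_best(rows) is rows[0]

    def test_identical_rows_first_by_stable_order(self):
        rows = [self.row(0.04, 0.9), self.row(0.04, 0.9), self.row(0.04, 0.9)]
        assert fs.select_best(rows) is rows[0]

    def test_lv_and_variable_count_break_remaining_ties(self):
        rows = [self.row(0.04, 0.9, lvs=7), self.row(0.04, 0.9, lvs=3, n_var=50)]
        assert fs.select_best(rows) is rows[1]

    def test_no_prediction_rows_rejected(self):
        r = self.row(None, None)
        r.rmsep = None
        with pytest.raises(ValueError, match="prediction"):
            fs.select_best([r])


class TestPredictMap:
    def test_zero_modulation_pixels_equal_object_mean_prediction(self, fitted_map_model):
        batch, chain, model = fitted_map_model
        cube, truth = fs.generate_cube(
            batch, 5, shape=(40, 40), axes_px=(13, 9), radial_amplitude=0.0
        )
        pmap = fs.predict_map(cube, model, chain, constituent="ssc")
        objs = fs.extract_object_spectra(cube, truth.mask)
        treated = fs.apply(
            chain,
            fs.SpectrumSet(objs[0].mean_spectrum[None], cube.wavelengths, "NIR"),
        )
        obj_pred = fs.predict(model, treated.values)[0]
        fruit = pmap.values[truth.mask]
        assert np.allclose(fruit, obj_pred, atol=1e-9 * max(1, abs(obj_pred)))

    def test_per_pixel_field_recovered_on_noiseless_cube(self, fitted_map_model):
        batch, chain, model = fitted_map_model
        cube, truth = fs.generate_cube(
            batch, 2, shape=(48, 48), axes_px=(15, 11), radial_amplitude=0.15
        )
        pmap = fs.predict_map(cube, model, chain, constituent="ssc")
        true_field = truth.concentration_fields["ssc"][truth.mask]
        rmse = np.sqrt(np.mean((pmap.values[truth.mask] - true_field) ** 2))
        assert rmse <= 0.01 * np.ptp(true_field)

    def test_all_background_mask_gives_empty_map(self, fitted_map_model):
        batch, chain, model = fitted_map_model
        cube, _ = fs.generate_cube(batch, 0, shape=(30, 30), axes_px=(9, 7))
        cube.mask = np.zeros(cube.data.shape[:2], dtype=bool)
        pmap = fs.predict_map(cube, model, chain)
        assert not np.isfinite(pmap.values).any()

    def test_grid_mismatch_rejected(self, fitted_map_model):
        batch, chain, model = fitted_map_model
        grid = fs.make_wavelength_grid(400, 1000, 5)
        cube = fs.HyperCube(
            np.full((10, 10, grid.size), 0.5), grid, "VIS-NIR",
            mask=np.ones((10, 10), dtype=bool),
        )
        with pytest.raises(ValueError, match="grid"):
            fs.predict_map(cube, model, chain)

    def test_missing_mask_rejected(self, fitted_map_model):
        batch, chain, model = fitted_map_model
        cube, _ = fs.generate_cube(batch, 0)
        cube.mask = None
        with pytest.raises(ValueError, match="mask"):
            fs.predict_map(cube, model, chain)
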