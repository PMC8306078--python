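"""Study orchestration: stratified 70/30 split, pretreatment model grid,
interval/outlier refinement, best-model selection and pixel-wise maps.

`run_grid` mirrors the two-phase calibration protocol: first every
pretreatment chain is scored on the full spectrum (LOO cross-validation
with PRESS-ratio component selection, then external-set evaluation); then
the best chain per constituent is refined by backward interval elimination
and left-out outlier removal before the final external evaluation.
Everything downstream of the split sees calibration rows only.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ConcentrationTable, HyperCube, SpectrumSet
from .pls import FitMetrics, PLSModel, fit_pls, loo_cv, metrics, predict, select_lv
from .pretreatment import PretreatmentChain, apply, fit_apply, parse_chain
from .selection import make_intervals, modified_ipls, remove_outliers_refit

__all__ = [
    "SplitSpec",
    "GridSettings",
    "ModelReport",
    "GridResult",
    "PredictionMap",
    "split",
    "run_grid",
    "select_best",
    "predict_map",
    "report_frame",
]

#: CSV column order for reports (the prediction-table layout).
REPORT_COLUMNS = [
    "parameter",
    "region",
    "pretreatment",
    "effective_wavelength_range_nm",
    "n_sample",
    "n_variables",
    "lvs",
    "r2_cal",
    "rmsec",
    "r2_cv",
    "rmsecv",
    "r2_pred",
    "rmsep",
    "removed_outliers",
]


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/prediction partition rule."""

    calibration_fraction: float = 0.70
    stratify: bool = True  # stratify by maturity stage
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.calibration_fraction < 1.0):
            raise ValueError("calibration fraction must lie in (0, 1)")


def split(
    stages: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified random split into calibration/prediction indices.

    Within each stratum the calibration count rounds *up* (toward
    calibration), but always leaves at least one prediction sample.
    """
    stages = np.asarray(stages)
    strata = (
        {s: np.flatnonzero(stages == s) for s in np.unique(stages)}
        if spec.stratify
        else {0: np.arange(stages.size)}
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x511]))
    cal, pred = [], []
    for name in sorted(strata):
        idx = strata[name]
        if idx.size < 2:
            raise ValueError(
                f"stratum {name!r} has {idx.size} sample(s); need at least 2"
            )
        shuffled = rng.permutation(idx)
        n_cal = int(np.ceil(spec.calibration_fraction * idx.size))
        n_cal = min(n_cal, idx.size - 1)
        cal.append(shuffled[:n_cal])
        pred.append(shuffled[n_cal:])
    return np.sort(np.concatenate(cal)), np.sort(np.concatenate(pred))


@dataclass
class GridSettings:
    """Knobs of the calibration/refinement protocol."""

    max_lv: int = 20
    prob_threshold: float = 0.75
    n_intervals: int = 20
    outlier_alpha: float = 0.01
    outlier_max_rounds: int = 10
    outlier_floor: float = 0.8
    refine: str = "best"  # "best" | "all" | "none"


@dataclass
class ModelReport:
    """One row of the calibration/prediction report."""

    parameter: str
    region: str
    pretreatment: str
    effective_wavelength_range_nm: str
    n_sample: int
    n_variables: int
    lvs: int
    r2_cal: float | None = None
    rmsec: float | None = None
    r2_cv: float | None = None
    rmsecv: float | None = None
    r2_pred: float | None = None
    rmsep: float | None = None
    removed_outliers: str = ""
    refined: bool = False
    error: str = ""

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in REPORT_COLUMNS}


@dataclass
class GridResult:
    reports: list[ModelReport]
    models: dict = field(default_factory=dict)  # key -> (PLSModel, chain, var_index)
    split_indices: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return report_frame(self.reports)


def report_frame(reports: list[ModelReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports], columns=REPORT_COLUMNS)


def _evaluate(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xpred: np.ndarray,
    ypred: np.ndarray,
    settings: GridSettings,
    var_index: np.ndarray,
) -> tuple[PLSModel, int, FitMetrics]:
    max_lv = min(settings.max_lv, Xcal.shape[0] - 2, Xcal.shape[1])
    cv = loo_cv(Xcal, ycal, max_lv)
    k = select_lv(cv, prob_threshold=settings.prob_threshold)
    model = fit_pls(Xcal, ycal, k, var_index=var_index)
    out = FitMetrics()
    m_cal = metrics(ycal, predict(model, Xcal), "cal")
    m_cv = metrics(ycal, cv.predictions[:, k - 1], "cv")
    out.r2_cal, out.rmsec = m_cal.r2_cal, m_cal.rmsec
    out.r2_cv, out.rmsecv = m_cv.r2_cv, m_cv.rmsecv
    if ypred.size >= 2:
        m_p = metrics(ypred, predict(model, Xpred), "pred")
        out.r2_pred, out.rmsep = m_p.r2_pred, m_p.rmsep
    return model, k, out


def _full_range(grid: np.ndarray) -> str:
    return f"{grid[0]:g}-{grid[-1]:g}"


def run_grid(
    spectra: SpectrumSet,
    concentrations: ConcentrationTable,
    chain_codes: list[str],
    constituents: list[str] | None = None,
    split_spec: SplitSpec | None = None,
    settings: GridSettings | None = None,
) -> GridResult:
    """Run the pretreatment grid and (optionally) the refinement stage.

    Per-constituent sample masks come from missing values in the
    concentration table, so constituents with different assay coverage get
    different sample counts.  Individual configuration failures are logged
    on their report row instead of aborting the grid.
    """
    split_spec = split_spec or SplitSpec()
    settings = settings or GridSettings()
    constituents = constituents or concentrations.constituents
    result = GridResult(reports=[])
    grid = spectra.wavelengths

    for name in constituents:
        y_all = concentrations.values(name)
        valid = np.flatnonzero(np.isfinite(y_all))
        stages = concentrations.stages[valid]
        cal_loc, pred_loc = split(stages, split_spec)
        cal_idx, pred_idx = valid[cal_loc], valid[pred_loc]
        result.split_indices[name] = (cal_idx, pred_idx)
        ycal, ypred = y_all[cal_idx], y_all[pred_idx]
        base_reports: list[tuple[ModelReport, PretreatmentChain, np.ndarray, np.ndarray]] = []

        for code in chain_codes:
            report = ModelReport(
                parameter=name,
                region=spectra.region,
                pretreatment=code,
                effective_wavelength_range_nm=_full_range(grid),
                n_sample=cal_idx.size,
                n_variables=grid.size,
                lvs=0,
            )
            try:
                chain = parse_chain(code)
                Xcal = fit_apply(chain, spectra.select_rows(cal_idx)).values
                Xpred = apply(chain, spectra.select_rows(pred_idx)).values
                model, k, fm = _evaluate(
                    Xcal, ycal, Xpred, ypred, settings, np.arange(grid.size)
                )
                report.lvs = k
                report.r2_cal, report.rmsec = fm.r2_cal, fm.rmsec
                report.r2_cv, report.rmsecv = fm.r2_cv, fm.rmsecv
                report.r2_pred, report.rmsep = fm.r2_pred, fm.rmsep
                result.models[(name, code, False)] = (model, chain, np.arange(grid.size))
                base_reports.append((report, chain, Xcal, Xpred))
            except (ValueError, np.linalg.LinAlgError) as exc:
                report.error = str(exc)
            result.reports.append(report)

        if settings.refine == "none" or not base_reports:
            continue
        scored = [t for t in base_reports if t[0].rmsep is not None]
        if not scored:
            continue
        if settings.refine == "best":
            scored = [min(scored, key=lambda t: (t[0].rmsep, -(t[0].r2_pred or 0)))]
        for base, chain, Xcal, Xpred in scored:
            result.reports.append(
                _refine_one(
                    base, chain, Xcal, ycal, Xpred, ypred, cal_idx,
                    grid, settings, result, name,
                )
            )
    return result


def _refine_one(
    base: ModelReport,
    chain: PretreatmentChain,
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xpred: np.ndarray,
    ypred: np.ndarray,
    cal_idx: np.ndarray,
    grid: np.ndarray,
    settings: GridSettings,
    result: GridResult,
    name: str,
) -> ModelReport:
    """Interval elimination + outlier removal on one chain, then re-evaluate."""
    report = replace(base, refined=True)
    try:
        scheme = make_intervals(grid.size, min(settings.n_intervals, grid.size))
        scheme, _trace = modified_ipls(
            Xcal, ycal, scheme,
            max_lv=settings.max_lv,
            prob_threshold=settings.prob_threshold,
        )
        var_index = scheme.indices()
        Xc_kept, yc_kept, removal_log = remove_outliers_refit(
            Xcal[:, var_index], ycal,
            alpha=settings.outlier_alpha,
            max_rounds=settings.outlier_max_rounds,
            floor_fraction=settings.outlier_floor,
            max_lv=settings.max_lv,
            prob_threshold=settings.prob_threshold,
        )
        removed = removal_log["sample_index"].to_numpy()
        model, k, fm = _evaluate(
            Xc_kept, yc_kept, Xpred[:, var_index], ypred, settings, var_index
        )
        report.effective_wavelength_range_nm = scheme.as_nm_ranges(grid)
        report.n_sample = yc_kept.size
        report.n_variables = var_index.size
        report.lvs = k
        report.r2_cal, report.rmsec = fm.r2_cal, fm.rmsec
        report.r2_cv, report.rmsecv = fm.r2_cv, fm.rmsecv
        report.r2_pred, report.rmsep = fm.r2_pred, fm.rmsep
        report.removed_outliers = ";".join(str(int(cal_idx[i])) for i in removed)
        result.models[(name, base.pretreatment, True)] = (model, chain, var_index)
    except (ValueError, np.linalg.LinAlgError) as exc:
        report.error = str(exc)
    return report


def select_best(reports: list[ModelReport]) -> ModelReport:
    """Lowest RMSEP; ties broken by highest R2pred, fewest LVs, fewest
    variables, then stable input order."""
    scored = [r for r in reports if r.rmsep is not None]
    if not scored:
        raise ValueError("no report rows carry prediction metrics")
    return min(
        scored,
        key=lambda r: (
            r.rmsep,
            -(r.r2_pred if r.r2_pred is not None else -np.inf),
            r.lvs,
            r.n_variables,
        ),
    )


@dataclass
class PredictionMap:
    """Per-pixel predicted concentration raster for one constituent."""

    values: np.ndarray  # rows x cols, NaN outside the mask
    mask: np.ndarray
    constituent: str
    unit: str = ""
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("raster and mask shapes differ")
        if np.any(np.isfinite(self.values) & ~self.mask):
            raise ValueError("predictions present outside the mask")


def predict_map(
    cube: HyperCube,
    model: PLSModel,
    chain: PretreatmentChain,
    var_index: np.ndarray | None = None,
    constituent: str = "",
    unit: str = "",
) -> PredictionMap:
    """Predict a constituent at every masked pixel of a cube.

    Each pixel's spectrum runs through the *fitted* chain (stored
    calibration centering) and the model's retained variables; background
    pixels are NaN.
    """
    if cube.mask is None:
        raise ValueError("cube has no mask; segment it first (build_mask)")
    if chain.fitted_wavelengths_ is not None and not np.array_equal(
        chain.fitted_wavelengths_, cube.wavelengths
    ):
        raise ValueError("cube wavelength grid differs from the model's grid")
    var_index = model.var_index if var_index is None else np.asarray(var_index)
    raster = np.full(cube.data.shape[:2], np.nan)
    if cube.mask.any():
        pixels = cube.data[cube.mask]
        ss = SpectrumSet(pixels, cube.wavelengths, cube.region)
        treated = apply(chain, ss).values[:, var_index]
        raster[cube.mask] = predict(model, treated)
    return PredictionMap(
        values=raster,
        mask=cube.mask.copy(),
        constituent=constituent,
        unit=unit,
        model_id=f"{constituent}:{chain.code}:{model.n_lv}LV",
    )
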