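"""Synthetic fruit spectra, concentration tables and hyperspectral cubes.

The generator emulates the statistical structure a reflectance calibration
assumes: per-sample constituent concentrations with realistic population
moments across four maturity stages, noiseless absorbance built by
Beer-Lambert mixing of Gaussian constituent bands on top of a water
background and a smooth per-sample baseline, reflectance R = 10**(-A) with
additive sensor noise, and spatial cubes of elliptical fruit on a dark
background.  Ground truth (band library, noiseless absorbance, per-pixel
concentration fields) is carried along so parameter-recovery tests can
score every downstream stage.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import (
    REGIONS,
    ConcentrationTable,
    HyperCube,
    SpectrumSet,
    region_grid,
)

__all__ = [
    "ComponentBand",
    "ConstituentStats",
    "GeneratorConfig",
    "SyntheticBatch",
    "CubeTruth",
    "CONSTITUENT_STATS",
    "DEFAULT_BANDS",
    "constituents_in_region",
    "sample_concentrations",
    "mix_spectra",
    "generate_batch",
    "generate_cube",
]


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band of a constituent.

    ``molar_strength`` is the absorbance at band centre contributed by one
    concentration unit of the constituent.
    """

    constituent: str
    center: float  # nm
    width: float  # Gaussian sigma, nm
    molar_strength: float  # absorbance per concentration unit

    def __post_init__(self) -> None:
        if not (400.0 <= self.center <= 1700.0):
            raise ValueError(
                f"band centre {self.center} nm outside the sensed range 400-1700 nm"
            )
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.molar_strength <= 0:
            raise ValueError("molar strength must be positive")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        d = (np.asarray(wavelengths, float) - self.center) / self.width
        return self.molar_strength * np.exp(-0.5 * d * d)


@dataclass(frozen=True)
class ConstituentStats:
    """Population min/max/mean/sd of one constituent, in its native unit."""

    minimum: float
    maximum: float
    mean: float
    sd: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("constituent stats must satisfy min <= mean <= max")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


# Population statistics of the eight constituents of fresh goji berry that
# the generator reproduces (min, max, mean, sd in the listed units).
CONSTITUENT_STATS: dict[str, ConstituentStats] = {
    "vitamin_c": ConstituentStats(0.13, 0.65, 0.31, 0.14, "g kg-1"),
    "ascorbic_acid": ConstituentStats(0.02, 0.48, 0.20, 0.12, "g kg-1"),
    "dhaa": ConstituentStats(0.04, 0.18, 0.11, 0.04, "g kg-1"),
    "antioxidant": ConstituentStats(1.63, 3.29, 2.31, 0.41, "TE g kg-1"),
    "phenols": ConstituentStats(2.09, 3.37, 2.62, 0.32, "GA g kg-1"),
    "anthocyanin": ConstituentStats(0.67, 1.35, 1.05, 0.17, "mg cm-2"),
    "ssc": ConstituentStats(6.50, 25.90, 21.62, 3.48, "%"),
    "ta": ConstituentStats(0.11, 0.92, 0.56, 0.15, "%"),
}

#: Constituents whose concentration rises with maturity stage.
STAGE_SHIFTED = ("vitamin_c", "ssc", "ta")


def _default_band_library() -> list[ComponentBand]:
    """Gaussian bands at literature positions, one strength per constituent.

    Vitamin C bands sit at reported correlating positions (850, 1360,
    1650 nm; ascorbic acid at 930, 1000, 1580 nm); sugars at the
    starch/cellulose/sucrose positions near 905 and 1435 nm; phenolics in
    the visible (ferulic-acid reflectance peak near 450 nm); anthocyanin at
    its optical-density wavelengths 532/653 nm.  Strengths are scaled so a
    mean-level sample contributes roughly 0.25 absorbance per band.
    """
    spec: dict[str, list[tuple[float, float]]] = {
        "vitamin_c": [(850, 25), (1360, 30), (1650, 30)],
        "ascorbic_acid": [(930, 25), (1000, 25), (1580, 30)],
        "dhaa": [(1210, 30)],
        "antioxidant": [(1120, 35)],
        "phenols": [(450, 30), (760, 40)],
        "anthocyanin": [(532, 25), (653, 25)],
        "ssc": [(640, 30), (905, 25), (1435, 30)],
        "ta": [(785, 35), (1150, 40)],
    }
    bands = []
    for name, centers in spec.items():
        strength = 0.25 / CONSTITUENT_STATS[name].mean
        for center, width in centers:
            bands.append(ComponentBand(name, float(center), float(width), strength))
    return bands


DEFAULT_BANDS: tuple[ComponentBand, ...] = tuple(_default_band_library())

# Broad water absorption background: two bands near 970 and 1450 nm with a
# fixed 0.4 absorbance amplitude, present in every sample.
WATER_BANDS: tuple[tuple[float, float, float], ...] = (
    (970.0, 35.0, 0.4),
    (1450.0, 45.0, 0.4),
)


def constituents_in_region(
    region: str, bands: Sequence[ComponentBand] = DEFAULT_BANDS
) -> list[str]:
    """Constituents with at least one band centre inside the region's grid."""
    lo, hi = REGIONS[region]
    seen: list[str] = []
    for b in bands:
        if lo <= b.center <= hi and b.constituent not in seen:
            seen.append(b.constituent)
    return seen


@dataclass
class GeneratorConfig:
    """Everything that defines one synthetic acquisition campaign."""

    n_samples: int = 100
    region: str = "NIR"
    constituents: tuple[str, ...] | None = None  # None -> all with in-region bands
    constituent_stats: Mapping[str, ConstituentStats] = field(
        default_factory=lambda: dict(CONSTITUENT_STATS)
    )
    noise_sd: float = 0.005  # reflectance units
    baseline_amplitude: float = 0.02  # absorbance units
    n_stages: int = 4
    stage_step_sd: float = 1.0  # stage-to-stage mean shift, within-stage sds
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise ValueError("noise_sd and baseline_amplitude must be >= 0")
        if self.n_stages < 1:
            raise ValueError("need at least one maturity stage")
        for name, st in self.constituent_stats.items():
            if not isinstance(st, ConstituentStats):
                raise TypeError(f"stats for {name!r} must be ConstituentStats")

    def resolved_constituents(
        self, bands: Sequence[ComponentBand] = DEFAULT_BANDS
    ) -> list[str]:
        if self.constituents is not None:
            return list(self.constituents)
        return [
            c
            for c in constituents_in_region(self.region, bands)
            if c in self.constituent_stats
        ]


@dataclass
class SyntheticBatch:
    """Spectra + concentrations + ground truth for one generated campaign."""

    spectra: SpectrumSet
    concentrations: ConcentrationTable
    stages: np.ndarray
    bands: tuple[ComponentBand, ...]
    absorbance_true: np.ndarray  # noiseless absorbance, samples x bands
    mixing_matrix: np.ndarray  # bands(grid) x constituents, absorbance per unit
    background: np.ndarray  # water background absorbance on the grid
    baselines: np.ndarray  # per-sample smooth baseline absorbance
    config: GeneratorConfig

    def __post_init__(self) -> None:
        n = self.spectra.n_samples
        if not (self.concentrations.n_samples == n == self.stages.size):
            raise ValueError("spectra, concentrations and stage labels disagree on n")
        v = self.spectra.values
        if v.min() <= 0 or v.max() > 1.0:
            raise ValueError("reflectance must lie in (0, 1]")


# --------------------------------------------------------------------------
# concentration sampling

def _stage_offsets(n_stages: int) -> np.ndarray:
    """Centred stage indices, e.g. 4 stages -> (-1.5, -0.5, 0.5, 1.5)."""
    return np.arange(n_stages, dtype=float) - (n_stages - 1) / 2.0


def _mixture_moments(
    c: float, w: float, st: ConstituentStats, shifts: np.ndarray
) -> tuple[float, float]:
    """Mean and sd of an equal-weight mixture of [min,max]-truncated normals."""
    locs = st.mean + c + shifts
    a = (st.minimum - locs) / w
    b = (st.maximum - locs) / w
    m = stats.truncnorm.mean(a, b, loc=locs, scale=w)
    v = stats.truncnorm.var(a, b, loc=locs, scale=w)
    mean = float(np.mean(m))
    var = float(np.mean(v + m**2) - mean**2)
    return mean, np.sqrt(var)


def _match_moments(
    st: ConstituentStats, step_sd: float, n_stages: int
) -> tuple[float, float]:
    """Solve for (offset, within-stage sd) so the stage-shifted, truncated
    mixture reproduces the configured population mean and sd."""
    base = _stage_offsets(n_stages)

    def residual(x: np.ndarray) -> np.ndarray:
        c, logw = x
        w = np.exp(logw)
        shifts = base * step_sd * w
        m, s = _mixture_moments(c, w, st, shifts)
        return np.array([(m - st.mean) / st.sd, (s - st.sd) / st.sd])

    spread = np.sqrt(1.0 + step_sd**2 * np.var(base))
    x0 = np.array([0.0, np.log(st.sd / spread)])
    sol = optimize.least_squares(residual, x0, xtol=1e-12, ftol=1e-12)
    c, w = sol.x[0], float(np.exp(sol.x[1]))
    return c, w


def sample_concentrations(
    config: GeneratorConfig, bands: Sequence[ComponentBand] = DEFAULT_BANDS
) -> ConcentrationTable:
    """Draw a seeded concentration table with the configured moments.

    Per constituent, values come from truncated normals on [min, max]; a
    monotone maturity-stage covariate shifts the means of vitamin C, SSC
    and TA so later stages are richer, and the within-stage scale/offset
    are moment-matched so the whole-population mean and sd still hit the
    configured targets.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0]))
    n = config.n_samples
    stages = (np.arange(n) * config.n_stages) // n  # balanced blocks 0..S-1
    offsets = _stage_offsets(config.n_stages)

    cols: dict[str, np.ndarray] = {
        "sample_id": np.arange(n),
        "stage": stages,
    }
    units: dict[str, str] = {}
    for name in config.resolved_constituents(bands):
        st = config.constituent_stats[name]
        units[name] = st.unit
        if st.sd == 0:
            cols[name] = np.full(n, st.mean)
            continue
        step = config.stage_step_sd if name in STAGE_SHIFTED else 0.0
        c, w = _match_moments(st, step, config.n_stages)
        locs = st.mean + c + offsets[stages] * step * w
        a = (st.minimum - locs) / w
        b = (st.maximum - locs) / w
        vals = stats.truncnorm.rvs(a, b, loc=locs, scale=w, random_state=rng)
        cols[name] = np.clip(vals, st.minimum, st.maximum)
    return ConcentrationTable(pd.DataFrame(cols), units)


# --------------------------------------------------------------------------
# spectral forward model

def water_background(wavelengths: np.ndarray) -> np.ndarray:
    """Fixed broad water absorbance (bands near 970 and 1450 nm)."""
    w = np.asarray(wavelengths, float)
    out = np.zeros_like(w)
    for center, sigma, amp in WATER_BANDS:
        d = (w - center) / sigma
        out += amp * np.exp(-0.5 * d * d)
    return out


def mixing_matrix(
    wavelengths: np.ndarray,
    constituents: Sequence[str],
    bands: Sequence[ComponentBand],
) -> np.ndarray:
    """Absorbance-per-unit-concentration profiles, grid x constituents."""
    S = np.zeros((len(wavelengths), len(constituents)))
    for j, name in enumerate(constituents):
        for b in bands:
            if b.constituent == name:
                S[:, j] += b.profile(wavelengths)
    return S


def mix_spectra(
    concentrations: ConcentrationTable,
    bands: Sequence[ComponentBand],
    config: GeneratorConfig,
) -> SyntheticBatch:
    """Beer-Lambert forward model: concentrations -> noisy reflectance.

    Noiseless absorbance is ``A = C @ S.T + water + baseline`` with S the
    Gaussian band profiles; reflectance is ``10**(-A)`` plus additive
    Gaussian sensor noise, clipped into (0, 1].
    """
    config.validate()
    grid = region_grid(config.region)
    lo, hi = grid[0], grid[-1]
    names = concentrations.constituents
    for name in names:
        centers = [b.center for b in bands if b.constituent == name]
        if not centers:
            raise ValueError(f"constituent {name!r} has no band in the library")
        if not any(lo <= c <= hi for c in centers):
            raise ValueError(
                f"constituent {name!r} has no band inside the {config.region} grid "
                f"({lo:g}-{hi:g} nm); it would be unlearnable by construction"
            )

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5EC7]))
    n = concentrations.n_samples
    C = np.column_stack([concentrations.values(c) for c in names])
    S = mixing_matrix(grid, names, bands)
    background = water_background(grid)

    # smooth per-sample baseline drift: quadratic in normalized wavelength
    t = (grid - lo) / (hi - lo)
    coeffs = rng.normal(0.0, config.baseline_amplitude, size=(n, 3))
    baselines = coeffs @ np.vstack([np.ones_like(t), t, t * t])
    baselines -= baselines.min(initial=0.0)  # keep absorbance non-negative

    A_true = C @ S.T + background + baselines
    R = 10.0 ** (-A_true)
    if config.noise_sd > 0:
        R = R + rng.normal(0.0, config.noise_sd, size=R.shape)
    R = np.clip(R, 1e-6, 1.0)

    spectra = SpectrumSet(
        R, grid, config.region, concentrations.data["sample_id"].to_numpy()
    )
    return SyntheticBatch(
        spectra=spectra,
        concentrations=concentrations,
        stages=concentrations.stages,
        bands=tuple(bands),
        absorbance_true=A_true,
        mixing_matrix=S,
        background=background,
        baselines=baselines,
        config=config,
    )


def generate_batch(
    config: GeneratorConfig, bands: Sequence[ComponentBand] = DEFAULT_BANDS
) -> SyntheticBatch:
    """Sample concentrations and run the forward model in one seeded call."""
    table = sample_concentrations(config, bands)
    return mix_spectra(table, bands, config)


def noise_equivalent_error(batch: SyntheticBatch) -> dict[str, float]:
    """Best-case per-constituent concentration error given the sensor noise.

    Propagates the reflectance noise into absorbance at each band's mean
    reflectance and inverts the true mixing matrix (with constant/linear/
    quadratic baseline columns as nuisance parameters) in the generalised
    least-squares sense; the square roots of the diagonal of the resulting
    covariance are the error floors an ideal linear estimator could reach.
    """
    cfg = batch.config
    grid = batch.spectra.wavelengths
    names = batch.concentrations.constituents
    if cfg.noise_sd == 0:
        return {n: 0.0 for n in names}
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    D = np.column_stack([batch.mixing_matrix, np.ones_like(t), t, t * t])
    r_bar = np.maximum(batch.spectra.values.mean(axis=0), 1e-3)
    sigma_a = cfg.noise_sd / (np.log(10.0) * r_bar)  # dA = -dR/(R ln10)
    info = (D / sigma_a[:, None] ** 2).T @ D
    cov = np.linalg.inv(info)
    return {n: float(np.sqrt(cov[j, j])) for j, n in enumerate(names)}


# --------------------------------------------------------------------------
# spatial cubes

@dataclass
class CubeTruth:
    """Ground truth stored with a generated cube."""

    mask: np.ndarray
    concentration_fields: dict[str, np.ndarray]  # per-pixel nominal fields
    modulation: np.ndarray  # zero-mean radial factor over the mask


def generate_cube(
    batch: SyntheticBatch,
    sample: int,
    shape: tuple[int, int] = (64, 64),
    axes_px: tuple[float, float] = (22.0, 16.0),
    radial_amplitude: float = 0.1,
    background_level: float = 0.03,
    seed: int | None = None,
) -> tuple[HyperCube, CubeTruth]:
    """Render one sample of a batch as an elliptical fruit on dark background.

    The fruit's semi-axes follow the roughly 1.37 major/minor ratio of the
    berries being emulated.  Inside the ellipse every constituent's
    concentration is modulated by a smooth radial field whose spatial mean
    equals the sample's nominal value exactly; outside, pixels carry
    low-reflectance noise.
    """
    rows, cols = shape
    a, b = axes_px
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    if a > r0 + 0.5 or b > c0 + 0.5:
        raise ValueError(
            f"ellipse semi-axes {axes_px} exceed the {shape} frame"
        )
    cfg = batch.config
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed if seed is None else seed), 0xC1BE, sample])
    )

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2
    mask = d2 <= 1.0
    if not mask.any():
        raise ValueError("ellipse produced an empty mask")

    # zero-mean smooth radial modulation over the mask
    g = 1.0 - d2
    g = np.where(mask, g, 0.0)
    g_mean = g[mask].mean()
    h = np.where(mask, g - g_mean, 0.0)
    factor = 1.0 + radial_amplitude * h  # spatial mean over mask == 1 exactly

    names = batch.concentrations.constituents
    conc = np.array([batch.concentrations.values(n)[sample] for n in names])
    grid = batch.spectra.wavelengths
    nb = grid.size

    fields = {
        n: np.where(mask, conc[j] * factor, np.nan) for j, n in enumerate(names)
    }

    # per-pixel absorbance: scale the constituent part by the radial factor,
    # keep the sample's water background + baseline fixed across the fruit
    A_const = batch.mixing_matrix @ conc  # (bands,)
    fixed = batch.background + batch.baselines[sample]
    A = factor[..., None] * A_const[None, None, :] + fixed[None, None, :]
    R = 10.0 ** (-A)

    bg = background_level * (0.5 + rng.random((rows, cols, 1)))
    data = np.where(mask[..., None], R, bg)
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, size=(rows, cols, nb))
    data = np.clip(data, 1e-6, 1.0)

    cube = HyperCube(data, grid, cfg.region, mask=mask.copy())
    return cube, CubeTruth(mask=mask, concentration_fields=fields, modulation=h)
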