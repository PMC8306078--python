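"""Core in-memory containers shared across the pipeline.

Conventions: wavelengths are strictly increasing, in nanometres; the band
axis is always the *last* axis of any array; reflectance lives in (0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The two sensor regions and their (start, stop) wavelength ranges in nm.
REGIONS: dict[str, tuple[float, float]] = {
    "VIS-NIR": (400.0, 1000.0),
    "NIR": (900.0, 1700.0),
}

#: Native spectral sampling of both sensors, nm.
DEFAULT_STEP = 5.0


def make_wavelength_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive arithmetic wavelength grid ``start, start+step, ..., stop``.

    The (start, stop) range must be an exact multiple of ``step``; the two
    sensor grids (400-1000 nm and 900-1700 nm at 5 nm) yield 121 and 161
    variables respectively.
    """
    if stop <= start:
        raise ValueError(f"stop ({stop}) must exceed start ({start})")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    n_steps = (stop - start) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"range {start}-{stop} nm is not divisible by step {step} nm"
        )
    n = int(round(n_steps))
    return start + step * np.arange(n + 1, dtype=float)


def region_grid(region: str, step: float = DEFAULT_STEP) -> np.ndarray:
    """The sensor grid for a named region (``VIS-NIR`` or ``NIR``)."""
    try:
        lo, hi = REGIONS[region]
    except KeyError:
        raise ValueError(f"unknown region {region!r}; expected one of {list(REGIONS)}")
    return make_wavelength_grid(lo, hi, step)


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("wavelength grid must be 1-D with at least 2 points")
    if np.any(np.diff(w) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    return w


@dataclass
class SpectrumSet:
    """A samples x wavelengths reflectance (or pretreated) matrix.

    This is the X block of every calibration: ``values[i, j]`` is sample
    ``i`` at ``wavelengths[j]``.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    region: str = "NIR"
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths = _check_grid(self.wavelengths)
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"values have {self.values.shape[1]} bands but grid has "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.values.shape[0])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.size != self.values.shape[0]:
                raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def select_rows(self, idx) -> "SpectrumSet":
        return SpectrumSet(
            self.values[idx], self.wavelengths, self.region, self.sample_ids[idx]
        )

    def with_values(self, values: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(values, self.wavelengths, self.region, self.sample_ids)


@dataclass
class ConcentrationTable:
    """Per-sample constituent concentrations (the y block).

    Wraps a DataFrame with columns ``sample_id``, ``stage`` and one column
    per constituent; ``units`` maps constituent name to its unit string.
    """

    data: pd.DataFrame
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("sample_id", "stage"):
            if col not in self.data.columns:
                raise ValueError(f"concentration table must have a {col!r} column")

    @property
    def constituents(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("sample_id", "stage")]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def stages(self) -> np.ndarray:
        return self.data["stage"].to_numpy()

    def values(self, constituent: str) -> np.ndarray:
        return self.data[constituent].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, units: Mapping[str, str] | None = None) -> "ConcentrationTable":
        return cls(pd.read_csv(path), units or {})


@dataclass
class HyperCube:
    """A rows x cols x bands reflectance cube with its wavelength grid."""

    data: np.ndarray
    wavelengths: np.ndarray
    region: str = "NIR"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        self.wavelengths = _check_grid(self.wavelengths)
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid lists "
                f"{self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube reflectance must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial "
                    f"shape {self.data.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
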