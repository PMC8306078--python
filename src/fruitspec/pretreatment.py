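"""Spectral pretreatment chains with fit/apply (train/test) semantics.

Chains are written as the field's shorthand strings, e.g.
``"SM + Log + 1st Dev + MC"``:

* ``SM`` — Savitzky-Golay polynomial smoothing,
* ``Log`` — decadic absorbance transform A = -log10(R),
* ``1st Dev`` / ``2nd Dev`` — Savitzky-Golay derivative, scaled to
  per-nm / per-nm**2 units by the grid step,
* ``MC`` — mean centering; column means are learned on the calibration
  set and re-used verbatim on any later set.

Steps are applied in the written order; edge samples are handled by the
filter's polynomial edge fit so the variable count never changes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import SpectrumSet

__all__ = ["PretreatmentChain", "parse_chain", "fit_apply", "apply"]

_CANONICAL = {
    "SM": "SM",
    "LOG": "Log",
    "1ST DEV": "1stDev",
    "1STDEV": "1stDev",
    "2ND DEV": "2ndDev",
    "2NDDEV": "2ndDev",
    "MC": "MC",
}
_DERIVATIVES = {"1stDev": 1, "2ndDev": 2}


@dataclass
class PretreatmentChain:
    """An ordered pretreatment pipeline; MC state is learned by fitting."""

    steps: tuple[str, ...]
    window: int = 7
    polyorder: int = 2
    log_base: str = "10"  # "10" (decadic absorbance) or "e"
    column_means_: np.ndarray | None = field(default=None, repr=False)
    fitted_wavelengths_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.steps = tuple(self.steps)
        unknown = [s for s in self.steps if s not in _CANONICAL.values()]
        if unknown:
            raise ValueError(f"unknown pretreatment step(s) {unknown}")
        if sum(s in _DERIVATIVES for s in self.steps) > 1:
            raise ValueError("a chain may contain at most one derivative step")
        if "MC" in self.steps and self.steps[-1] != "MC":
            raise ValueError("mean centering (MC) must be the last step")
        if len(set(self.steps)) != len(self.steps):
            raise ValueError("duplicate steps in chain")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and exceed the polynomial order")
        if self.log_base not in ("10", "e"):
            raise ValueError("log_base must be '10' or 'e'")

    @property
    def code(self) -> str:
        pretty = {"1stDev": "1st Dev", "2ndDev": "2nd Dev"}
        return " + ".join(pretty.get(s, s) for s in self.steps)

    @property
    def is_fitted(self) -> bool:
        return "MC" not in self.steps or self.column_means_ is not None


def parse_chain(code: str, window: int = 7, polyorder: int = 2) -> PretreatmentChain:
    """Parse a '+'-separated chain string into a :class:`PretreatmentChain`."""
    tokens = [t.strip() for t in code.split("+")]
    if any(not t for t in tokens):
        raise ValueError(f"malformed chain code {code!r}")
    steps = []
    for t in tokens:
        key = t.upper()
        if key not in _CANONICAL:
            raise ValueError(f"unknown pretreatment token {t!r} in {code!r}")
        steps.append(_CANONICAL[key])
    return PretreatmentChain(tuple(steps), window=window, polyorder=polyorder)


def _run_steps(chain: PretreatmentChain, X: SpectrumSet, fit: bool) -> np.ndarray:
    step_nm = np.diff(X.wavelengths)
    if not np.allclose(step_nm, step_nm[0], rtol=1e-9):
        raise ValueError("pretreatment requires a uniform wavelength step")
    delta = float(step_nm[0])
    vals = np.array(X.values, dtype=float, copy=True)
    for step in chain.steps:
        if step in ("SM",) or step in _DERIVATIVES:
            if chain.window > vals.shape[1]:
                raise ValueError(
                    f"smoothing window {chain.window} exceeds the "
                    f"{vals.shape[1]} available bands"
                )
            deriv = _DERIVATIVES.get(step, 0)
            vals = savgol_filter(
                vals,
                window_length=chain.window,
                polyorder=chain.polyorder,
                deriv=deriv,
                delta=delta,
                axis=1,
                mode="interp",
            )
        elif step == "Log":
            if np.any(vals <= 0):
                raise ValueError(
                    "Log step requires strictly positive values "
                    "(apply it before any derivative)"
                )
            vals = -np.log10(vals) if chain.log_base == "10" else -np.log(vals)
        elif step == "MC":
            if fit:
                if vals.shape[0] < 2:
                    raise ValueError("mean centering needs at least 2 calibration rows")
                chain.column_means_ = vals.mean(axis=0)
            if chain.column_means_ is None:
                raise ValueError("chain with MC must be fitted before apply()")
            vals = vals - chain.column_means_
    return vals


def fit_apply(chain: PretreatmentChain, X: SpectrumSet) -> SpectrumSet:
    """Fit the chain's data-dependent state on X and return transformed X."""
    out = _run_steps(chain, X, fit=True)
    chain.fitted_wavelengths_ = np.array(X.wavelengths, copy=True)
    return X.with_values(out)


def apply(chain: PretreatmentChain, X: SpectrumSet) -> SpectrumSet:
    """Apply a fitted chain to new spectra using the stored calibration state."""
    if not chain.is_fitted:
        raise ValueError("chain must be fitted (fit_apply) before apply")
    if chain.fitted_wavelengths_ is not None and not np.array_equal(
        chain.fitted_wavelengths_, X.wavelengths
    ):
        raise ValueError("wavelength grid differs from the fitted grid")
    out = _run_steps(chain, X, fit=False)
    return X.with_values(out)
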