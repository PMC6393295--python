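"""Two-state UV melting curves and first-derivative Tm estimation.

tRNA unfolding is modelled as a two-state van't Hoff transition with a
temperature-independent enthalpy: the unfolded fraction is

    theta(T) = 1 / (1 + exp((dH_vH / R) * (1/T - 1/Tm)))     [T in K]

and the 260-nm absorbance is a theta-weighted mix of linear folded and
unfolded baselines (hyperchromicity: the unfolded baseline lies above
the folded one).  Melting experiments scan 25-95 degC; Tm is read as
the maximum of the first derivative of the melting curve, here with
moving-average smoothing, central differences and quadratic
interpolation through the peak.  Only Tm is estimated from data; the
enthalpy is a simulation input, not a fitted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "MeltCurveModel",
    "MeltingCurve",
    "TmEstimate",
    "ThermalError",
    "BoundaryPeakError",
    "GAS_CONSTANT_KJ",
    "fraction_unfolded",
    "simulate_melting_curve",
    "estimate_tm",
    "delta_tm",
]

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 8.31446261815324e-3

_KELVIN = 273.15


class ThermalError(ValueError):
    """Invalid melting-curve input."""


class BoundaryPeakError(ThermalError):
    """Derivative maximum at the scan boundary: transition truncated."""


@dataclass(frozen=True)
class MeltCurveModel:
    """Two-state unfolding model parameters.

    ``tm_c`` in degC, ``dh_vh_kj`` the van't Hoff enthalpy in kJ/mol,
    baselines as (intercept AU, slope AU/degC) evaluated at the Celsius
    temperature.  Defaults: 250 kJ/mol and flat baselines 0.25 -> 0.30
    AU, matching transcripts whose initial A260 is held at 0.2-0.3.
    """

    tm_c: float
    dh_vh_kj: float = 250.0
    folded_baseline: tuple[float, float] = (0.25, 0.0)
    unfolded_baseline: tuple[float, float] = (0.30, 0.0)

    def __post_init__(self) -> None:
        if self.dh_vh_kj <= 0:
            raise ThermalError("van't Hoff enthalpy must be positive")
        folded_at_tm = self.folded_baseline[0] + self.folded_baseline[1] * self.tm_c
        unfolded_at_tm = self.unfolded_baseline[0] + self.unfolded_baseline[1] * self.tm_c
        if unfolded_at_tm <= folded_at_tm:
            raise ThermalError(
                "unfolded baseline must lie above the folded baseline at Tm "
                "(hyperchromicity)"
            )


@dataclass(frozen=True)
class MeltingCurve:
    """Sampled absorbance vs temperature, on a uniform increasing grid."""

    temperatures: tuple[float, ...]  # degC
    absorbance: tuple[float, ...]  # AU
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if len(self.temperatures) != len(self.absorbance):
            raise ThermalError("temperature and absorbance lengths differ")
        steps = np.diff(t)
        if len(steps) == 0 or np.any(steps <= 0):
            raise ThermalError("temperatures must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ThermalError("temperature grid must be uniform")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class TmEstimate:
    """First-derivative Tm readout.

    ``method`` records the derivative variant: ``dA/d(1/T)`` (default;
    peaks exactly at the two-state midpoint) or ``dA/dT``.
    ``peak_height`` is always quoted on the temperature axis (AU/degC).
    """

    tm_c: float
    peak_height: float  # AU/degC
    method: str = "dA/d(1/T)"


def fraction_unfolded(model: MeltCurveModel, temperature_c: float | np.ndarray):
    """Unfolded fraction theta(T) of the two-state van't Hoff model."""
    t_k = np.asarray(temperature_c, dtype=float) + _KELVIN
    tm_k = model.tm_c + _KELVIN
    theta = 1.0 / (1.0 + np.exp((model.dh_vh_kj / GAS_CONSTANT_KJ) * (1.0 / t_k - 1.0 / tm_k)))
    return float(theta) if np.isscalar(temperature_c) else theta


def simulate_melting_curve(
    model: MeltCurveModel,
    t_min_c: float = 25.0,
    t_max_c: float = 95.0,
    step_c: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MeltingCurve:
    """Simulate a melting curve on a uniform temperature grid.

    ``A(T) = (1-theta) * folded(T) + theta * unfolded(T) + N(0, noise_sd)``.
    The model Tm must lie inside the scan window.
    """
    if step_c <= 0:
        raise ThermalError("step must be positive")
    if not (t_min_c < model.tm_c < t_max_c):
        raise ThermalError(
            f"Tm {model.tm_c} degC outside scan window [{t_min_c}, {t_max_c}]"
        )
    n_steps = int(round((t_max_c - t_min_c) / step_c))
    t = t_min_c + step_c * np.arange(n_steps + 1)
    theta = fraction_unfolded(model, t)
    folded = model.folded_baseline[0] + model.folded_baseline[1] * t
    unfolded = model.unfolded_baseline[0] + model.unfolded_baseline[1] * t
    a = (1.0 - theta) * folded + theta * unfolded
    if noise_sd < 0:
        raise ThermalError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + noise_sd * rng.standard_normal(len(a))
    return MeltingCurve(
        temperatures=tuple(float(x) for x in t),
        absorbance=tuple(float(x) for x in a),
        metadata={
            "tm_c": model.tm_c,
            "dh_vh_kj": model.dh_vh_kj,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def estimate_tm(
    curve: MeltingCurve, smooth_window: int = 5, method: str = "dA/d(1/T)"
) -> TmEstimate:
    """Tm from the first derivative of the melting curve.

    The absorbance is smoothed with a centred moving average
    (``smooth_window`` grid points, odd) and differentiated by central
    differences; the derivative maximum is refined by quadratic
    interpolation through the peak and its two neighbours.  A maximum
    at either end of the scan raises :class:`BoundaryPeakError`.

    With the default ``method="dA/d(1/T)"`` the peak is located on the
    reciprocal-temperature axis (the derivative is weighted by T^2 in
    kelvin), where a two-state van't Hoff transition with flat
    baselines peaks exactly at the thermodynamic midpoint; the plain
    temperature-axis derivative (``method="dA/dT"``) peaks slightly
    below it.  ``peak_height`` is always the temperature-axis
    derivative at the peak.
    """
    a = np.asarray(curve.absorbance, dtype=float)
    t = np.asarray(curve.temperatures, dtype=float)
    if len(a) < 20:
        raise ThermalError("need at least 20 grid points")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ThermalError("smooth_window must be odd and >= 1")
    if method not in ("dA/d(1/T)", "dA/dT"):
        raise ThermalError(f"unknown derivative variant {method!r}")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        a_s = np.convolve(a, kernel, mode="valid")
        t_s = t[smooth_window // 2 : len(t) - smooth_window // 2]
    else:
        a_s, t_s = a, t
    step = curve.step
    deriv_t = (a_s[2:] - a_s[:-2]) / (2.0 * step)
    t_d = t_s[1:-1]
    if method == "dA/d(1/T)":
        peak_fn = deriv_t * (t_d + _KELVIN) ** 2  # = -dA/d(1/T)
    else:
        peak_fn = deriv_t
    idx = int(np.argmax(peak_fn))
    if idx == 0 or idx == len(peak_fn) - 1:
        raise BoundaryPeakError(
            "derivative maximum at the scan boundary; transition not fully sampled"
        )
    # quadratic refinement of the peak position; the fit neighbourhood
    # scales with the smoothing window so that a wide window (chosen
    # for noisy data) also widens the parabola fit
    n_fit = max(1, smooth_window // 2)
    lo, hi = max(0, idx - n_fit), min(len(peak_fn), idx + n_fit + 1)
    x = t_d[lo:hi] - t_d[idx]
    coeffs = np.polyfit(x, peak_fn[lo:hi], 2)
    if coeffs[0] < 0:
        offset = float(np.clip(-coeffs[1] / (2.0 * coeffs[0]),
                                -n_fit * step, n_fit * step))
    else:  # degenerate neighbourhood: keep the grid argmax
        offset = 0.0
    tm = float(t_d[idx] + offset)
    return TmEstimate(tm_c=tm, peak_height=float(deriv_t[idx]), method=method)


def delta_tm(est_modified: TmEstimate, est_unmodified: TmEstimate) -> float:
    """Tm difference (modified minus unmodified), reported to 0.1 degC."""
    return round(est_modified.tm_c - est_unmodified.tm_c, 1)
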