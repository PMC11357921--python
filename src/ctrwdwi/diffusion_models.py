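"""Forward diffusion-signal models shared by the fitter and the simulator.

Two signal representations of multi-b-value DWI magnitude data:

* the CTRW (continuous-time random-walk) model
  ``S(b) = S0 * E_alpha(-(b*D)**beta)``, with anomalous diffusion
  coefficient D (mm^2/s), temporal heterogeneity exponent alpha and
  spatial heterogeneity exponent beta, both in (0, 1]; and
* the conventional mono-exponential model ``S(b) = S0 * exp(-b*ADC)``,
  whose two-point inversion from the b=0 and b=800 s/mm^2 images defines
  the ADC map.

D and ADC are stored in mm^2/s throughout; conversion to the conventional
reporting unit (1e-3 mm^2/s) happens only at the reporting boundary
(see :func:`to_reporting_units`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mittag_leffler import ml_eval

__all__ = [
    "CTRWParams",
    "ctrw_signal",
    "mono_exp_signal",
    "adc_two_point",
    "to_reporting_units",
    "from_reporting_units",
]


@dataclass(frozen=True)
class CTRWParams:
    """CTRW tissue parameters: D in mm^2/s, alpha and beta dimensionless."""

    D: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")


def ctrw_signal(params: CTRWParams, S0: float, b):
    """CTRW signal S0 * E_alpha(-(b*D)**beta) at b-value(s) b (s/mm^2).

    Equals S0 at b = 0 and decreases strictly with b.  With
    alpha = beta = 1 it reduces exactly to the mono-exponential model
    with ADC = D.
    """
    if not S0 > 0:
        raise ValueError(f"S0 must be positive, got {S0}")
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b-values must be non-negative")
    bD = b_arr * params.D
    z = np.where(bD > 0, -np.power(np.where(bD > 0, bD, 1.0), params.beta), 0.0)
    out = S0 * ml_eval(params.alpha, z)
    return float(np.asarray(out)) if np.ndim(b) == 0 else out


def mono_exp_signal(adc: float, S0: float, b):
    """Mono-exponential signal S0 * exp(-b*adc); adc in mm^2/s."""
    if not S0 > 0:
        raise ValueError(f"S0 must be positive, got {S0}")
    b_arr = np.asarray(b, dtype=float)
    out = S0 * np.exp(-b_arr * adc)
    return float(out) if np.ndim(b) == 0 else out


def adc_two_point(S0, S_b, b: float = 800.0):
    """Two-point ADC, ln(S0/S_b)/b, from the b=0 and b=b images (mm^2/s).

    The exact inverse of :func:`mono_exp_signal`.  Voxels with
    non-positive signal in either image are unusable for the logarithm and
    are flagged NaN rather than raising, so they can be excluded from ROI
    statistics downstream.  Negative ADC (S_b > S0) is returned as-is: a
    recognisable fit artifact that ROI statistics also exclude.
    """
    if not b > 0:
        raise ValueError(f"b must be positive, got {b}")
    S0_arr = np.asarray(S0, dtype=float)
    Sb_arr = np.asarray(S_b, dtype=float)
    usable = (S0_arr > 0) & (Sb_arr > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.where(usable, np.log(S0_arr / np.where(usable, Sb_arr, 1.0)) / b, np.nan)
    if np.ndim(S0) == 0 and np.ndim(S_b) == 0:
        return float(adc)
    return adc


def to_reporting_units(value):
    """mm^2/s -> 1e-3 mm^2/s (the conventional reporting unit)."""
    return np.asarray(value, dtype=float) * 1e3


def from_reporting_units(value):
    """1e-3 mm^2/s -> mm^2/s."""
    return np.asarray(value, dtype=float) * 1e-3
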