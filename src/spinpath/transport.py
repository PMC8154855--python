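"""Observable algebra of the device measurements.

Magnetoresistance as a percentage, MR = 100 (R(H) - R(0)) / R(0); the
antisymmetric two-filter MR curve produced by a chiral spin filter in series
with a ferromagnetic (Ni) filter; the field-extreme difference
dMR = MR(-Hmax) - MR(+Hmax); and the photovoltage observables
V_updown = (V_up + V_down)/2 with P = (V_up - V_down)/V_updown, plus the
AlOx-resistance normalization that turns the average photovoltage into a
current-like quantity proportional to the charge-transfer yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "SignalCurve",
    "TwoFilterParams",
    "mr_percent",
    "delta_mr",
    "two_filter_mr",
    "photovoltage_summary",
    "normalize_yield",
]


@dataclass
class SignalCurve:
    """Field- or temperature-indexed signal (V, Ohm, or %)."""

    axis_kind: str          # "field_T" or "temperature_K"
    axis: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.axis_kind not in ("field_T", "temperature_K"):
            raise ValidationError("axis_kind must be field_T or temperature_K")
        self.axis = np.asarray(self.axis, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.axis.ndim != 1 or self.axis.shape != self.signal.shape:
            raise ValidationError("axis and signal must be 1-D and equal length")
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("axis must be strictly monotone")

    def __len__(self) -> int:
        return int(self.axis.size)


@dataclass(frozen=True)
class TwoFilterParams:
    """Chiral-protein filter in series with the Ni electrode filter.

    ``protein_polarization`` is a signed fraction (sign = chirality
    handedness), ``H_sat`` the field scale on which the Ni magnetization
    saturates, ``leak_fraction`` the field-independent pinhole-leakage share
    of the current that suppresses the observed MR amplitude.
    """

    protein_polarization: float
    H_sat: float
    leak_fraction: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.protein_polarization) > 1:
            raise ValidationError("|protein_polarization| must be <= 1")
        if self.H_sat <= 0:
            raise ValidationError("H_sat must be positive")
        if not (0.0 <= self.leak_fraction <= 1.0):
            raise ValidationError("leak_fraction must be in [0, 1]")


def mr_percent(R_H: float, R_0: float):
    """MR (%) = 100 (R(H) - R(0)) / R(0)."""
    if np.any(np.asarray(R_0) <= 0):
        raise ValidationError("zero-field resistance must be positive")
    return 100.0 * (np.asarray(R_H) - R_0) / R_0


def delta_mr(curve: SignalCurve) -> float:
    """dMR = MR(-Hmax) - MR(+Hmax) at the curve's field extremes."""
    if curve.axis_kind != "field_T":
        raise ValidationError("delta_mr needs a field-indexed curve")
    h_max = np.max(np.abs(curve.axis))
    tol = 1e-9 * max(1.0, h_max)
    i_neg = np.where(np.abs(curve.axis + h_max) <= tol)[0]
    i_pos = np.where(np.abs(curve.axis - h_max) <= tol)[0]
    if i_neg.size == 0 or i_pos.size == 0:
        raise ValidationError("curve must contain both field extremes ±H_max")
    return float(curve.signal[i_neg[0]] - curve.signal[i_pos[0]])


def two_filter_mr(p: TwoFilterParams, H_grid) -> SignalCurve:
    """Antisymmetric MR(H) of the protein+Ni double filter.

    MR(H) = -100 (1 - leak) p_protein tanh(H / H_sat): the Ni filter follows
    its (hysteresis-free) magnetization tanh(H/H_sat), the chiral filter is
    field-independent, and pinhole leakage dilutes the spin-dependent share.
    """
    H = np.asarray(H_grid, dtype=float)
    mr = (
        -100.0
        * (1.0 - p.leak_fraction)
        * p.protein_polarization
        * np.tanh(H / p.H_sat)
    )
    return SignalCurve(axis_kind="field_T", axis=H, signal=mr, label="two_filter_MR")


def photovoltage_summary(V_up: float, V_down: float) -> tuple[float, float]:
    """(V_avg, P) = ((V_up + V_down)/2, (V_up - V_down)/V_avg)."""
    v_avg = 0.5 * (V_up + V_down)
    if v_avg == 0:
        raise DegenerateInputError("V_up + V_down = 0: polarization undefined")
    return v_avg, (V_up - V_down) / v_avg


def invert_photovoltage_summary(V_avg: float, P: float) -> tuple[float, float]:
    """Reconstruct (V_up, V_down) from (V_avg, P); exact inverse of the summary."""
    half = 0.5 * P * V_avg
    return V_avg + half, V_avg - half


def normalize_yield(V_avg: float, R_alox: float) -> float:
    """V_avg / R_alox — current-like, proportional to the steady-state yield."""
    if R_alox <= 0:
        raise ValidationError("AlOx resistance must be positive")
    return V_avg / R_alox
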