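"""Arrhenius activation-energy extraction from temperature-indexed signals.

A thermally activated signal y(T) = A exp(-E_act / (k_B T)) is linear in
ln(y) vs 1/(k_B T); the activation energy is minus the slope of an ordinary
(optionally weighted) least-squares fit, reported in meV.  Non-positive
signal points cannot enter the log fit; they are excluded and recorded on the
fit object (a 0% polarization floor is not an Arrhenius datum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import K_B
from .errors import InsufficientDataError, ValidationError
from .transport import SignalCurve

__all__ = ["ArrheniusFit", "fit_activation_energy", "exclude_quench_correction"]

logger = logging.getLogger(__name__)


@dataclass
class ArrheniusFit:
    """Result of an Arrhenius fit: E_act (meV), prefactor, residuals."""

    E_act: float
    prefactor: float
    residual_rms: float
    n_points: int
    covariance: np.ndarray
    excluded_points: list[int]

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("an Arrhenius fit needs >= 3 points")
        if not np.isfinite(self.E_act):
            raise ValidationError("E_act must be finite")

    def predict(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return self.prefactor * np.exp(-self.E_act / (K_B * T))


def fit_activation_energy(curve: SignalCurve, weights=None) -> ArrheniusFit:
    """Least-squares fit of ln(signal) vs 1/(k_B T); E_act = -slope, in meV."""
    if curve.axis_kind != "temperature_K":
        raise ValidationError("Arrhenius fit needs a temperature-indexed curve")
    T = curve.axis
    y = curve.signal
    usable = y > 0
    excluded = list(np.nonzero(~usable)[0])
    if excluded:
        logger.info(
            "Arrhenius fit: excluding %d non-positive signal point(s) at T=%s K",
            len(excluded), np.round(T[~usable], 3).tolist(),
        )
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} positive points; need >= 3"
        )
    x = 1.0 / (K_B * T[usable])
    ln_y = np.log(y[usable])
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[usable]
        if np.any(w <= 0):
            raise ValidationError("weights must be positive")
    coeffs, cov = np.polyfit(x, ln_y, 1, w=w, cov=True)
    slope, intercept = coeffs
    pred = np.exp(intercept + slope * x)
    rms = float(np.sqrt(np.mean((y[usable] - pred) ** 2)))
    return ArrheniusFit(
        E_act=float(-slope),
        prefactor=float(np.exp(intercept)),
        residual_rms=rms,
        n_points=int(usable.sum()),
        covariance=np.asarray(cov),
        excluded_points=excluded,
    )


def exclude_quench_correction(curve: SignalCurve) -> SignalCurve:
    """Documented identity pass-through for the phonon-quenching correction.

    The device-specific correction applied to the measured polarization data
    is not reproduced here; this hook keeps the composition point explicit
    and logs a notice (exactly once per call) so downstream records show the
    correction was skipped.
    """
    logger.info(
        "phonon-quenching correction not applied (identity transform): the "
        "device-specific procedure is outside this package's scope"
    )
    return curve
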