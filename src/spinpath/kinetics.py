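"""Steady-state master-equation model of the protein–electrode photocycle.

Four states of one adsorbed protein on the metal film:

* ``ground``            Ru(II)/Cu(II), resting
* ``excited``           Ru(II)*/Cu(II), after photoexcitation at k_exc = k_I*I
* ``charge_separated``  Ru(III)/Cu(I), after intramolecular transfer k_DA
* ``cu_reduced``        Ru(II)/Cu(I), after the electrode refills the Ru(III)
                        hole (k_refill); the Cu(I) electron returns to the
                        electrode at k_AAg, closing the cycle

A parasitic decay k_quench (energy/electron transfer of the excited donor to
the metal) competes with k_DA and suppresses the yield.  The stationary
distribution of the rate matrix gives the steady-state flux of electrons to
the electrode per protein, the model quantity proportional to the measured
photovoltage-derived yield; only cross-condition ratios of this flux are
physically meaningful here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import null_space

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "KineticRates",
    "KineticModel",
    "SteadyState",
    "build_photocycle",
    "steady_state",
    "accumulation_ratio",
    "coupling_to_rate",
]

_NULLSPACE_RCOND = 1e-10

STATE_LABELS = ("ground", "excited", "charge_separated", "cu_reduced")


@dataclass(frozen=True)
class KineticRates:
    """First-order rate constants (s^-1) of the photocycle at one temperature."""

    k_exc: float          # excitation, k_I * laser intensity
    k_DA: float           # intramolecular Ru* -> Cu transfer
    k_AAg: float          # Cu(I) -> electrode return
    k_refill: float       # electrode -> Ru(III) hole refill
    k_quench: float = 0.0 # parasitic excited-state decay
    temperature: float = 290.0

    def __post_init__(self) -> None:
        for name in ("k_exc", "k_DA", "k_AAg", "k_refill", "k_quench"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.k_exc <= 0:
            raise ValidationError("k_exc must be > 0 for a driven steady state")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")


@dataclass
class KineticModel:
    """Labelled rate matrix, column-to-row convention: Q[i, j] = rate j -> i."""

    state_labels: tuple[str, ...]
    rate_matrix: np.ndarray
    electrode_edge: tuple[str, str] | None = None  # (from_state, to_state)

    def __post_init__(self) -> None:
        q = np.asarray(self.rate_matrix, dtype=float)
        n = len(self.state_labels)
        if q.shape != (n, n):
            raise ValidationError("rate matrix shape does not match labels")
        off = q - np.diag(np.diag(q))
        if np.any(off < 0):
            raise ValidationError("off-diagonal rates must be >= 0")
        if not np.allclose(q.sum(axis=0), 0.0, atol=1e-8 * max(1.0, np.abs(q).max())):
            raise ValidationError("columns of the rate matrix must sum to zero")
        self.rate_matrix = q

    def index(self, label: str) -> int:
        return self.state_labels.index(label)


@dataclass
class SteadyState:
    """Stationary populations and the electron flux delivered to the electrode."""

    populations: np.ndarray
    state_labels: tuple[str, ...]
    flux_to_electrode: float | None

    def population(self, label: str) -> float:
        return float(self.populations[self.state_labels.index(label)])


def build_photocycle(r: KineticRates) -> KineticModel:
    """Assemble the 4-state photocycle rate matrix from one rate set."""
    q = np.zeros((4, 4))
    g, e, c, u = range(4)
    q[e, g] = r.k_exc
    if r.k_quench > 0:
        q[g, e] = r.k_quench
    q[c, e] = r.k_DA
    q[u, c] = r.k_refill
    q[g, u] = r.k_AAg
    np.fill_diagonal(q, -q.sum(axis=0))
    return KineticModel(
        state_labels=STATE_LABELS,
        rate_matrix=q,
        electrode_edge=("cu_reduced", "ground"),
    )


def steady_state(m: KineticModel) -> SteadyState:
    """Stationary distribution as the normalized null vector of the rate matrix.

    Raises :class:`DegenerateInputError` when the null space is not
    one-dimensional (reducible or degenerate model; singular-value tolerance
    1e-10).
    """
    q = m.rate_matrix
    # rcond is relative to the largest singular value
    ns = null_space(q, rcond=_NULLSPACE_RCOND)
    if ns.shape[1] != 1:
        raise DegenerateInputError(
            f"rate matrix null space has dimension {ns.shape[1]}, expected 1"
        )
    v = ns[:, 0]
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9 * np.abs(v).max()):
        raise DegenerateInputError("stationary vector has negative components")
    p = np.clip(v, 0.0, None)
    p = p / p.sum()
    flux = None
    if m.electrode_edge is not None:
        src, dst = (m.index(s) for s in m.electrode_edge)
        flux = float(q[dst, src] * p[src])
    return SteadyState(
        populations=p, state_labels=m.state_labels, flux_to_electrode=flux
    )


def electrode_flux(r: KineticRates) -> float:
    """Steady-state electron flux (s^-1 per protein) to the electrode."""
    return steady_state(build_photocycle(r)).flux_to_electrode


def accumulation_ratio(r1: KineticRates, r2: KineticRates) -> float:
    """Ratio of steady-state charge accumulation between two conditions.

    The per-protein electrode flux is proportional to the photovoltage-derived
    yield, so this ratio is directly comparable to the measured cross-
    temperature yield ratio.
    """
    f1 = electrode_flux(r1)
    f2 = electrode_flux(r2)
    if f2 == 0:
        raise DegenerateInputError("zero electrode flux in denominator condition")
    return f1 / f2


def coupling_to_rate(coupling_sq_ratio: float, r: KineticRates) -> KineticRates:
    """Scale k_DA by a squared-coupling ratio (golden-rule proportionality)."""
    if coupling_sq_ratio <= 0:
        raise ValidationError("coupling_sq_ratio must be positive")
    return replace(r, k_DA=r.k_DA * coupling_sq_ratio)
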