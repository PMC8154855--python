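"""Synthetic inputs with known ground truth.

Two generators cover every input class the analysis needs without any
external data:

* :func:`make_toy_azurin` — a hand-built donor--bridge--acceptor structure
  emulating the Ru-His83-labelled blue copper protein: a Ru donor 17 Å
  (1.7 nm) from the Cu acceptor, a Cu site with two His nitrogens, a Cys
  thiolate (the equatorial plane) and an axial Met sulfur, a meandering
  covalently bonded bridge, and an internal two-water pocket that offers a
  nearly straight water-mediated shortcut.  Snapshot ensembles add isotropic
  Gaussian jitter with sigma = sigma_ref * sqrt(T / T_ref), the classical
  equipartition scaling of harmonic positional fluctuations.  The template
  geometry is tuned so the bonded route and the water shortcut genuinely
  compete: moderate jitter occasionally promotes the shortcut, more often at
  higher temperature.

* :func:`make_arrhenius_curve` — thermally activated signal curves
  A*exp(-E_act/(k_B T)) with multiplicative Gaussian noise, for testing
  activation-energy recovery.

Noise is drawn as standard normals and then scaled by sigma(T), so two
ensembles generated with the same seed at different temperatures share their
underlying random displacements (common random numbers); paired comparisons
between temperatures are then far less noisy than independent draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import K_B
from .errors import ConfigError, ValidationError
from .structures import Atom, Ensemble, StructureSnapshot
from .transport import SignalCurve

__all__ = [
    "EnsembleSpec",
    "CurveSpec",
    "make_toy_azurin",
    "make_arrhenius_curve",
    "toy_template",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a jittered snapshot ensemble of a toy template."""

    n_snapshots: int = 100
    temperature: float = 290.0
    sigma_ref: float = 0.35     # Å per-atom jitter at T_ref
    T_ref: float = 290.0
    seed: int = 0
    topology: str = "his83"

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValidationError("n_snapshots must be >= 1")
        if self.sigma_ref < 0:
            raise ValidationError("sigma_ref must be >= 0")
        if self.temperature <= 0 or self.T_ref <= 0:
            raise ValidationError("temperatures must be positive")


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for a synthetic Arrhenius signal curve."""

    E_act: float                      # meV
    prefactor: float = 1.0
    T_grid: tuple = tuple(np.linspace(100.0, 300.0, 20))
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


# ---------------------------------------------------------------------------
# toy template
# ---------------------------------------------------------------------------

def _toy_his83_atoms() -> tuple[list[Atom], set[tuple[int, int]], dict[str, int]]:
    """Atoms, bonds and tags of the His83-like toy template.

    Geometry notes (all Å, mostly in the z=0 plane):
      * Ru at (17, 0, 0.04): donor-acceptor distance exactly 1.7 nm.
      * Cu 0.04 Å above the His/His/Cys plane, on the Met side; Cu-S(Met)
        3.50 Å.
      * The bonded bridge runs Ru -> His83 -> 18 backbone-like carbons ->
        Cys CB -> Cys SG -> Cu (22 covalent steps).  Between the bridge's
        raised arc and the Cu-side segment sit two waters on an almost
        straight Ru->Cu line; entry and exit through-space jumps (~2 Å)
        plus a water-water hydrogen bond form the shortcut route.
    """
    recs: list[tuple[str, str, str, int, tuple[float, float, float]]] = []
    # (element, atom name, residue name, residue seq, xyz)
    recs.append(("Ru", "RU", "RU", 201, (17.0, 0.0, 0.04)))
    recs.append(("C", "CE1", "HIS", 83, (15.7, 0.8, 0.0)))
    # straight segment toward the water pocket
    seg_a = [(14.8, 0.4), (13.9, -0.4), (13.0, 0.4), (12.1, -0.4)]
    # arc detouring over the pocket
    arc = [(11.5, 0.9), (11.0, 2.1), (10.1, 2.9), (8.9, 3.2), (7.7, 2.9),
           (6.8, 2.1), (6.3, 0.9)]
    # descent toward the Cys ligand, kept clear of the Cu coordination shell
    seg_b = [(5.6, -0.1), (4.8, -1.0), (4.0, -1.9), (3.2, -2.8), (2.3, -3.4),
             (1.4, -3.8), (0.5, -3.5)]
    for k, (x, y) in enumerate(seg_a + arc + seg_b):
        recs.append(("C", "CA", "GLY", 84 + k, (x, y, 0.0)))
    recs.append(("C", "CB", "CYS", 112, (-0.35, -2.95, 0.0)))
    recs.append(("S", "SG", "CYS", 112, (-1.10, -1.90, 0.0)))
    recs.append(("Cu", "CU", "CU", 130, (0.0, 0.0, 0.04)))
    recs.append(("N", "ND1", "HIS", 46, (2.03, 0.0, 0.0)))
    recs.append(("N", "ND1", "HIS", 117, (-1.02, 1.76, 0.0)))
    recs.append(("S", "SD", "MET", 121, (0.0, 0.0, 3.54)))
    # water shortcut under the arc
    recs.append(("O", "O", "HOH", 301, (10.05, -0.15, 0.0)))
    recs.append(("O", "O", "HOH", 302, (7.45, -0.25, 0.0)))

    atoms = [
        Atom(atom_id=i + 1, element=el, name=nm, residue_name=rn,
             residue_seq=rs, coords=np.array(xyz))
        for i, (el, nm, rn, rs, xyz) in enumerate(recs)
    ]
    by_key = {(a.residue_name, a.residue_seq, a.name): a.atom_id for a in atoms}

    def aid(rn, rs, nm):
        return by_key[(rn, rs, nm)]

    chain_ids = [aid("RU", 201, "RU"), aid("HIS", 83, "CE1")]
    chain_ids += [aid("GLY", 84 + k, "CA") for k in range(len(seg_a + arc + seg_b))]
    chain_ids += [aid("CYS", 112, "CB"), aid("CYS", 112, "SG"),
                  aid("CU", 130, "CU")]
    bonds = {(min(i, j), max(i, j)) for i, j in zip(chain_ids[:-1], chain_ids[1:])}
    # Cu coordination bonds
    cu = aid("CU", 130, "CU")
    for partner in (aid("HIS", 46, "ND1"), aid("HIS", 117, "ND1"),
                    aid("MET", 121, "SD")):
        bonds.add((min(cu, partner), max(cu, partner)))

    tags = {
        "donor": aid("RU", 201, "RU"),
        "acceptor": cu,
        "his_N1": aid("HIS", 46, "ND1"),
        "his_N2": aid("HIS", 117, "ND1"),
        "cys_S": aid("CYS", 112, "SG"),
        "met_S": aid("MET", 121, "SD"),
    }
    return atoms, bonds, tags


_TOPOLOGIES = {"his83": _toy_his83_atoms}


def toy_template(topology: str = "his83", temperature: float = 290.0
                 ) -> StructureSnapshot:
    """The unjittered template snapshot for a named topology."""
    if topology not in _TOPOLOGIES:
        raise ConfigError(
            f"unknown topology {topology!r}; available: {sorted(_TOPOLOGIES)}"
        )
    atoms, bonds, tags = _TOPOLOGIES[topology]()
    return StructureSnapshot(
        atoms=atoms, covalent_bonds=bonds, site_tags=tags,
        temperature=temperature, model_index=0,
    )


def make_toy_azurin(spec: EnsembleSpec) -> Ensemble:
    """Generate a jittered snapshot ensemble from the toy template.

    Per-atom isotropic Gaussian jitter of sigma = sigma_ref * sqrt(T/T_ref);
    bit-identical output under a fixed seed, and seed-matched ensembles at
    different temperatures share scaled displacements.
    """
    template = toy_template(spec.topology, spec.temperature)
    coords0 = template.coords_array()
    sigma = spec.sigma_ref * np.sqrt(spec.temperature / spec.T_ref)
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.n_snapshots, *coords0.shape))
    snapshots = [
        template.with_coords(coords0 + sigma * noise[i], model_index=i)
        for i in range(spec.n_snapshots)
    ]
    return Ensemble(snapshots=snapshots, temperature=spec.temperature)


def make_arrhenius_curve(spec: CurveSpec) -> SignalCurve:
    """Thermally activated curve A*exp(-E/(k_B T)) with multiplicative noise."""
    T = np.asarray(spec.T_grid, dtype=float)
    if T.size == 0:
        raise ConfigError("empty temperature grid")
    signal = spec.prefactor * np.exp(-spec.E_act / (K_B * T))
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal * (1.0 + spec.noise_cv * rng.standard_normal(T.shape))
    return SignalCurve(
        axis_kind="temperature_K", axis=T, signal=signal,
        label=f"arrhenius_E{spec.E_act:g}meV",
    )
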