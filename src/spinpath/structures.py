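"""Structure ensembles and Cu-site geometric observables.

A multi-model PDB file stands in for an MD trajectory: each ``MODEL`` block is
one conformational snapshot of a donor--bridge--acceptor system (a Ru-labelled
blue copper protein).  Snapshots carry covalent-bond topology (from ``CONECT``
records when present, else a distance heuristic) and a set of tagged sites:
the Ru donor, the Cu acceptor, the two His imidazole nitrogens and the Cys
thiolate sulfur that define the Cu equatorial ligand plane, and the Met
sulfur on the axial side.

Internal length unit is Å; distances are reported in nm only at the public
reporting boundary, matching the conventions of the measurements being
modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import ANGSTROM_PER_NM
from .errors import FormatError, GeometryError, TaggingError, ValidationError

__all__ = [
    "Atom",
    "StructureSnapshot",
    "Ensemble",
    "read_ensemble",
    "write_ensemble",
    "infer_covalent_bonds",
    "donor_acceptor_distance",
    "cu_equatorial_displacement",
    "cu_met_distance",
]

#: site roles understood by the geometry operations
SITE_ROLES = ("donor", "acceptor", "his_N1", "his_N2", "cys_S", "met_S")

# bond-inference cutoffs (Å): heavy-heavy and any-pair-involving-hydrogen
HEAVY_BOND_CUTOFF = 1.9
HYDROGEN_BOND_CUTOFF = 1.2


@dataclass
class Atom:
    """One atom of a snapshot.

    coords are Cartesian Å.  ``atom_id`` is the PDB serial and must be unique
    within a snapshot.
    """

    atom_id: int
    element: str
    name: str
    residue_name: str
    residue_seq: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValidationError(f"atom {self.atom_id}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.atom_id}: non-finite coordinates")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class StructureSnapshot:
    """One conformation: atoms, covalent topology, and tagged sites."""

    atoms: list[Atom]
    covalent_bonds: set[tuple[int, int]]
    site_tags: dict[str, int] = field(default_factory=dict)
    temperature: float = 290.0
    model_index: int = 0

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate atom_id within snapshot")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        known = set(ids)
        self.covalent_bonds = {
            (min(i, j), max(i, j)) for i, j in self.covalent_bonds
        }
        for i, j in self.covalent_bonds:
            if i == j:
                raise ValidationError(f"self-bond on atom {i}")
            if i not in known or j not in known:
                raise ValidationError(f"bond ({i},{j}) references unknown atom")
        for role, aid in self.site_tags.items():
            if aid not in known:
                raise TaggingError(
                    f"site tag {role!r} references unknown atom id {aid}"
                )
        self._by_id = {a.atom_id: a for a in self.atoms}

    def atom(self, atom_id: int) -> Atom:
        return self._by_id[atom_id]

    def tagged(self, role: str) -> Atom:
        """Return the atom tagged with ``role``; raise TaggingError if absent."""
        if role not in self.site_tags:
            raise TaggingError(f"snapshot has no {role!r} tag")
        return self._by_id[self.site_tags[role]]

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def with_coords(self, coords: np.ndarray, model_index: int | None = None,
                    temperature: float | None = None) -> "StructureSnapshot":
        """Copy of this snapshot with replaced coordinates (same topology/tags)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValidationError("coords array shape mismatch")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return StructureSnapshot(
            atoms=atoms,
            covalent_bonds=set(self.covalent_bonds),
            site_tags=dict(self.site_tags),
            temperature=self.temperature if temperature is None else temperature,
            model_index=self.model_index if model_index is None else model_index,
        )


@dataclass
class Ensemble:
    """Ordered collection of snapshots sharing atom naming and count."""

    snapshots: list[StructureSnapshot]
    temperature: float = 290.0

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise ValidationError("ensemble must contain at least one snapshot")
        n0 = len(self.snapshots[0].atoms)
        tags0 = self.snapshots[0].site_tags
        for s in self.snapshots[1:]:
            if len(s.atoms) != n0:
                raise ValidationError("snapshots differ in atom count")
            if s.site_tags != tags0:
                raise ValidationError("snapshots differ in site tags")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)


# ---------------------------------------------------------------------------
# bond inference
# ---------------------------------------------------------------------------

def infer_covalent_bonds(atoms: Sequence[Atom]) -> set[tuple[int, int]]:
    """Distance-rule bonding: heavy pairs within 1.9 Å, H pairs within 1.2 Å.

    Used only when the file carries no CONECT records; a real force-field
    topology is out of scope.
    """
    xyz = np.array([a.coords for a in atoms])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=HEAVY_BOND_CUTOFF)
    bonds: set[tuple[int, int]] = set()
    for i, j in pairs:
        ai, aj = atoms[i], atoms[j]
        cutoff = (
            HYDROGEN_BOND_CUTOFF
            if (ai.is_hydrogen or aj.is_hydrogen)
            else HEAVY_BOND_CUTOFF
        )
        if np.linalg.norm(ai.coords - aj.coords) <= cutoff:
            bonds.add((min(ai.atom_id, aj.atom_id), max(ai.atom_id, aj.atom_id)))
    return bonds


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _scan_conect(path: Path) -> set[tuple[int, int]]:
    """Collect CONECT serial pairs from a PDB file (Bio.PDB discards them)."""
    bonds: set[tuple[int, int]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("CONECT"):
                continue
            fields = line[6:].split()
            if len(fields) < 2:
                continue
            try:
                serials = [int(f) for f in fields]
            except ValueError:
                raise FormatError(f"malformed CONECT record: {line.rstrip()}")
            base = serials[0]
            for other in serials[1:]:
                bonds.add((min(base, other), max(base, other)))
    return bonds


def _resolve_tag(atoms: Sequence[Atom], role: str, spec: Mapping) -> int:
    seq = spec.get("residue_seq")
    name = spec.get("atom")
    resname = spec.get("residue_name")
    for a in atoms:
        if seq is not None and a.residue_seq != int(seq):
            continue
        if name is not None and a.name.strip() != str(name).strip():
            continue
        if resname is not None and a.residue_name.strip() != str(resname).strip():
            continue
        return a.atom_id
    raise TaggingError(
        f"cannot resolve site tag {role!r} (spec {dict(spec)!r}): no matching atom"
    )


def read_ensemble(path, tag_spec: Mapping[str, Mapping] | None = None,
                  temperature: float = 290.0) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    One snapshot per MODEL block; a file with no MODEL records yields a
    single snapshot.  Covalent bonds come from CONECT records when present,
    otherwise from the distance rule of :func:`infer_covalent_bonds`.
    ``tag_spec`` maps role -> ``{"residue_seq": int, "atom": str[,
    "residue_name": str]}``.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("ens", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise FormatError(f"failed to parse PDB {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no models found")

    conect = _scan_conect(path)
    snapshots: list[StructureSnapshot] = []
    for m_idx, model in enumerate(models):
        atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                for at in residue:
                    element = (at.element or at.get_name()[0]).strip()
                    # normalize case: PDB columns carry "RU", we use "Ru"
                    element = element[:1].upper() + element[1:].lower()
                    atoms.append(
                        Atom(
                            atom_id=int(at.get_serial_number()),
                            element=element,
                            name=at.get_name(),
                            residue_name=residue.get_resname().strip(),
                            residue_seq=int(residue.get_id()[1]),
                            coords=np.asarray(at.get_coord(), dtype=float),
                        )
                    )
        if not atoms:
            raise FormatError(f"{path}: model {m_idx} contains no atoms")
        bonds = set(conect) if conect else infer_covalent_bonds(atoms)
        tags = {}
        if tag_spec:
            for role, spec in tag_spec.items():
                tags[role] = _resolve_tag(atoms, role, spec)
        snapshots.append(
            StructureSnapshot(
                atoms=atoms,
                covalent_bonds=bonds,
                site_tags=tags,
                temperature=temperature,
                model_index=m_idx,
            )
        )
    return Ensemble(snapshots=snapshots, temperature=temperature)


_HETERO_RESIDUES = {"HOH", "WAT", "RU", "CU", "RUC"}


def _format_atom_line(a: Atom) -> str:
    record = "HETATM" if a.residue_name in _HETERO_RESIDUES else "ATOM  "
    name = a.name
    # PDB convention: 1-char element names start at column 14
    if len(name) < 4 and len(a.element) < 2:
        name = f" {name:<3s}"
    else:
        name = f"{name:<4s}"
    x, y, z = a.coords
    return (
        f"{record}{a.atom_id:>5d} {name} {a.residue_name:<3s} A"
        f"{a.residue_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {a.element:>2s}"
    )


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB with CONECT records."""
    path = Path(path)
    lines: list[str] = []
    for s in ensemble:
        lines.append(f"MODEL     {s.model_index + 1:>4d}")
        for a in s.atoms:
            lines.append(_format_atom_line(a))
        lines.append("ENDMDL")
    # topology is shared; write the first snapshot's bonds once
    neighbors: dict[int, list[int]] = {}
    for i, j in sorted(ensemble.snapshots[0].covalent_bonds):
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    for serial in sorted(neighbors):
        partners = sorted(neighbors[serial])
        for k in range(0, len(partners), 4):
            chunk = partners[k : k + 4]
            lines.append(
                "CONECT" + f"{serial:>5d}" + "".join(f"{p:>5d}" for p in chunk)
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# geometric observables
# ---------------------------------------------------------------------------

def donor_acceptor_distance(s: StructureSnapshot) -> float:
    """Donor(Ru)–acceptor(Cu) metal-to-metal distance in nm."""
    d = s.tagged("donor").coords
    a = s.tagged("acceptor").coords
    return float(np.linalg.norm(d - a)) / ANGSTROM_PER_NM


def cu_met_distance(s: StructureSnapshot) -> float:
    """Cu–S(Met) axial coordination distance in nm."""
    cu = s.tagged("acceptor").coords
    sm = s.tagged("met_S").coords
    return float(np.linalg.norm(cu - sm)) / ANGSTROM_PER_NM


def cu_equatorial_displacement(s: StructureSnapshot) -> float:
    """Signed perpendicular displacement (Å) of Cu from its equatorial plane.

    The plane passes through the two His coordinating nitrogens and the Cys
    thiolate sulfur (exactly those three atoms); the sign is positive toward
    the Met sulfur side.
    """
    p1 = s.tagged("his_N1").coords
    p2 = s.tagged("his_N2").coords
    p3 = s.tagged("cys_S").coords
    cu = s.tagged("acceptor").coords
    ms = s.tagged("met_S").coords
    normal = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(normal)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1e-30)
    if norm < 1e-9 * scale**2:
        raise GeometryError("his_N1, his_N2 and cys_S are (nearly) collinear")
    normal = normal / norm
    if np.dot(normal, ms - p1) < 0:
        normal = -normal
    return float(np.dot(cu - p1, normal))
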