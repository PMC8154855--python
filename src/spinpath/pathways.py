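"""Tunneling-pathway analysis.

Implements the semi-empirical pathway picture of protein electron tunneling:
the donor--acceptor coupling mediated by a chain of bonded and non-bonded
contacts is proportional to a product of per-step decay factors

* covalent bond:      eps_C (default 0.6)
* hydrogen bond:      eps_C^2 * exp(-beta_hb * (R - r0_hb))
* through-space jump: prefactor * eps_C * exp(-beta_ts * (R - r0_ts))

The strongest pathway maximizes the product of its edge decays, which is the
shortest path under edge weights -ln(eps).  Ensemble statistics (occurrence
census over snapshots, mean-square decay products and their ratio between two
temperatures) quantify how conformational sampling redistributes the
tunneling routes.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, NoPathError, ValidationError
from .structures import Ensemble, StructureSnapshot

__all__ = [
    "PathwayParams",
    "Pathway",
    "PathwayCensus",
    "build_coupling_graph",
    "strongest_pathway",
    "census",
    "coupling_ratio",
]

#: elements that may donate/accept hydrogen bonds
_HB_ELEMENTS = {"N", "O", "S"}

_REL_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PathwayParams:
    """Decay parameters of the pathway model.

    Defaults are the canonical values used throughout the pathway-coupling
    literature; the measurements this package models were analysed with the
    same functional forms.  All are config-overridable.
    """

    eps_covalent: float = 0.6
    beta_hb: float = 1.7          # Å^-1
    r0_hb: float = 2.8            # Å
    beta_ts: float = 1.7          # Å^-1
    r0_ts: float = 1.4            # Å
    prefactor_ts: float = 0.5
    hb_max_dist: float = 3.5      # Å, heavy-atom donor-acceptor cutoff
    hb_min_angle: float = 120.0   # degrees, donor-H-acceptor, when H present
    ts_cutoff: float = 6.0        # Å

    def __post_init__(self) -> None:
        if not (0.0 < self.eps_covalent <= 1.0):
            raise ValidationError("eps_covalent must be in (0, 1]")
        for name in ("beta_hb", "beta_ts", "r0_hb", "r0_ts",
                     "hb_max_dist", "ts_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.prefactor_ts <= 0:
            raise ValidationError("prefactor_ts must be positive")

    def eps_hbond(self, r: float) -> float:
        return min(
            1.0, self.eps_covalent**2 * math.exp(-self.beta_hb * (r - self.r0_hb))
        )

    def eps_through_space(self, r: float) -> float:
        return min(
            1.0,
            self.prefactor_ts
            * self.eps_covalent
            * math.exp(-self.beta_ts * (r - self.r0_ts)),
        )


@dataclass
class Pathway:
    """A donor→acceptor route with its decay product and residue signature."""

    atom_sequence: list[int]
    edge_kinds: list[str]
    epsilon_total: float
    residue_signature: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon_total <= 1.0):
            raise ValidationError("epsilon_total must be in (0, 1]")


@dataclass
class PathwayCensus:
    """Occurrence statistics of strongest pathways over an ensemble."""

    counts: dict[tuple[tuple[str, int], ...], int]
    fractions: dict[tuple[tuple[str, int], ...], float]
    strongest: list[Pathway | None]       # per snapshot; None if disconnected
    n_snapshots: int
    n_disconnected: int
    mean_square_decay: float

    def top_fraction(self, k: int) -> float:
        """Cumulative fraction of the k most frequent signatures."""
        return float(sum(sorted(self.fractions.values(), reverse=True)[:k]))


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_coupling_graph(s: StructureSnapshot, p: PathwayParams | None = None
                         ) -> nx.Graph:
    """Build the weighted tunneling graph of one snapshot.

    Nodes are atom ids.  Edge attribute ``epsilon`` holds the per-step decay,
    ``kind`` one of covalent/hbond/through_space.  Edge-kind precedence is
    covalent > hbond > through_space when a pair qualifies for several.
    Hydrogens carry covalent edges but are excluded from through-space jumps
    to bound the graph size.
    """
    p = p or PathwayParams()
    if not s.atoms:
        raise ValidationError("empty snapshot")
    g = nx.Graph()
    for a in s.atoms:
        g.add_node(a.atom_id, residue_name=a.residue_name,
                   residue_seq=a.residue_seq, element=a.element)

    for i, j in s.covalent_bonds:
        g.add_edge(i, j, kind="covalent", epsilon=min(1.0, p.eps_covalent))

    heavy = [a for a in s.atoms if not a.is_hydrogen]
    xyz = np.array([a.coords for a in heavy])
    tree = cKDTree(xyz)
    # hydrogens attached to each heavy atom, for the angle criterion
    h_neighbors: dict[int, list[int]] = {}
    for i, j in s.covalent_bonds:
        ai, aj = s.atom(i), s.atom(j)
        if ai.is_hydrogen and not aj.is_hydrogen:
            h_neighbors.setdefault(aj.atom_id, []).append(ai.atom_id)
        elif aj.is_hydrogen and not ai.is_hydrogen:
            h_neighbors.setdefault(ai.atom_id, []).append(aj.atom_id)

    for ii, jj in tree.query_pairs(r=p.ts_cutoff):
        ai, aj = heavy[ii], heavy[jj]
        u, v = ai.atom_id, aj.atom_id
        if g.has_edge(u, v):       # covalent wins
            continue
        r = float(np.linalg.norm(ai.coords - aj.coords))
        if (
            r <= p.hb_max_dist
            and ai.element.upper() in _HB_ELEMENTS
            and aj.element.upper() in _HB_ELEMENTS
            and _hbond_angle_ok(s, ai, aj, h_neighbors, p.hb_min_angle)
        ):
            g.add_edge(u, v, kind="hbond", epsilon=p.eps_hbond(r))
        else:
            g.add_edge(u, v, kind="through_space", epsilon=p.eps_through_space(r))
    return g


def _hbond_angle_ok(s: StructureSnapshot, ai, aj, h_neighbors, min_angle: float
                    ) -> bool:
    """Donor–H–acceptor angle check; distance-only when neither atom has H."""
    candidates = []
    for donor, acceptor in ((ai, aj), (aj, ai)):
        for hid in h_neighbors.get(donor.atom_id, ()):
            h = s.atom(hid).coords
            v1 = donor.coords - h
            v2 = acceptor.coords - h
            cosang = np.dot(v1, v2) / (
                np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-30
            )
            candidates.append(math.degrees(math.acos(np.clip(cosang, -1, 1))))
    if not candidates:
        return True
    return max(candidates) >= min_angle


# ---------------------------------------------------------------------------
# strongest (max-product) pathway
# ---------------------------------------------------------------------------

def strongest_pathway(g: nx.Graph, donor: int, acceptor: int) -> Pathway:
    """Max-product donor→acceptor path: Dijkstra on -ln(epsilon).

    Deterministic tie-break for path costs equal within 1e-12 relative:
    fewer edges wins, then the lexicographically smallest atom-id sequence.
    """
    for node, label in ((donor, "donor"), (acceptor, "acceptor")):
        if node not in g:
            raise NoPathError(f"{label} atom {node} not in graph")
    # best[n] = (cost, n_edges, path_tuple)
    best: dict[int, tuple[float, int, tuple[int, ...]]] = {
        donor: (0.0, 0, (donor,))
    }
    done: set[int] = set()
    heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, (donor,))]
    while heap:
        cost, nedges, path = heapq.heappop(heap)
        node = path[-1]
        if node in done or best.get(node, (math.inf,))[0] < cost - _tol(cost):
            continue
        done.add(node)
        if node == acceptor:
            break
        for nbr, attrs in g[node].items():
            if nbr in path:
                continue
            eps = attrs["epsilon"]
            if eps <= 0:
                continue
            new = (cost - math.log(eps), nedges + 1, path + (nbr,))
            cur = best.get(nbr)
            if cur is None or _better(new, cur):
                best[nbr] = new
                heapq.heappush(heap, new)
    if acceptor not in done:
        raise NoPathError(f"no path between donor {donor} and acceptor {acceptor}")
    cost, nedges, path = best[acceptor]
    return _path_to_pathway(g, list(path))


def _tol(cost: float) -> float:
    return _REL_TIE_TOL * max(1.0, abs(cost))


def _better(new, cur) -> bool:
    if new[0] < cur[0] - _tol(cur[0]):
        return True
    if new[0] > cur[0] + _tol(cur[0]):
        return False
    return (new[1], new[2]) < (cur[1], cur[2])


def _path_to_pathway(g: nx.Graph, path: list[int]) -> Pathway:
    kinds, eps_total = [], 1.0
    for u, v in zip(path[:-1], path[1:]):
        kinds.append(g.edges[u, v]["kind"])
        eps_total *= g.edges[u, v]["epsilon"]
    sig: list[tuple[str, int]] = []
    for n in path:
        entry = (g.nodes[n]["residue_name"], g.nodes[n]["residue_seq"])
        if not sig or sig[-1] != entry:
            sig.append(entry)
    return Pathway(
        atom_sequence=path,
        edge_kinds=kinds,
        epsilon_total=eps_total,
        residue_signature=tuple(sig),
    )


# ---------------------------------------------------------------------------
# ensemble census
# ---------------------------------------------------------------------------

def census(e: Ensemble, p: PathwayParams | None = None,
           donor: str | int = "donor", acceptor: str | int = "acceptor"
           ) -> PathwayCensus:
    """Strongest pathway per snapshot plus the occurrence census.

    ``donor``/``acceptor`` may be site-tag roles (resolved per snapshot) or
    literal atom ids.  Snapshots with a disconnected donor/acceptor pair are
    counted in ``n_disconnected`` and excluded from fractions and the
    mean-square decay, never silently dropped.
    """
    p = p or PathwayParams()
    if len(e) == 0:
        raise ValidationError("empty ensemble")
    strongest: list[Pathway | None] = []
    for s in e:
        d = s.site_tags[donor] if isinstance(donor, str) else donor
        a = s.site_tags[acceptor] if isinstance(acceptor, str) else acceptor
        g = build_coupling_graph(s, p)
        try:
            strongest.append(strongest_pathway(g, d, a))
        except NoPathError:
            strongest.append(None)
    connected = [pw for pw in strongest if pw is not None]
    if not connected:
        raise DegenerateInputError("donor/acceptor disconnected in every snapshot")
    counts: dict[tuple, int] = {}
    for pw in connected:
        counts[pw.residue_signature] = counts.get(pw.residue_signature, 0) + 1
    n_conn = len(connected)
    fractions = {sig: c / n_conn for sig, c in counts.items()}
    msd = float(np.mean([pw.epsilon_total**2 for pw in connected]))
    return PathwayCensus(
        counts=counts,
        fractions=fractions,
        strongest=strongest,
        n_snapshots=len(e),
        n_disconnected=len(e) - n_conn,
        mean_square_decay=msd,
    )


def coupling_ratio(c1: PathwayCensus, c2: PathwayCensus) -> float:
    """Ratio of mean-square pathway decay products, <eps^2>_1 / <eps^2>_2.

    In the golden-rule picture the nonadiabatic rate is proportional to the
    squared coupling, so this ratio estimates the rate ratio between the two
    sampled conditions (e.g. 290 K vs 250 K).
    """
    if c2.mean_square_decay == 0:
        raise DegenerateInputError("denominator census has zero mean-square decay")
    return c1.mean_square_decay / c2.mean_square_decay
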