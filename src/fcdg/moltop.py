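"""Molecular constitution, stereogenic elements, and holonomic distance bounds.

The distance-geometry description of a molecule starts from its constitution
(the bonding graph) plus a single reference 3D geometry of *arbitrary*
configuration.  Only constitution-derived quantities enter the bounds matrix:
bond lengths (1,2), geminal distances (1,3), torsion-range distances (1,4) and
van-der-Waals excluded volume for everything further apart.  The input
configuration is deliberately ignored everywhere except for scalar distances
that are configuration-independent, so structure generation is unbiased with
respect to diastereomers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem

__all__ = [
    "MolecularGraph",
    "StereoElement",
    "BoundsMatrix",
    "InconsistentBoundsError",
    "build_graph",
    "stereo_analysis",
    "enumerate_stereo_elements",
    "free_elements",
    "n_assignments",
    "build_bounds",
    "smooth_bounds",
]

# Bondi-style van der Waals radii (Å); conservative default for anything else.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
VDW_DEFAULT = 1.60
NONBONDED_VDW_SCALE = 0.8


class InconsistentBoundsError(ValueError):
    """Lower bound exceeds upper bound for some atom pair after smoothing."""

    def __init__(self, i: int, j: int, lower: float, upper: float):
        self.pair = (i, j)
        super().__init__(
            f"inconsistent distance bounds for atom pair ({i + 1}, {j + 1}) "
            f"[1-based]: lower {lower:.4f} Å > upper {upper:.4f} Å"
        )


@dataclass(frozen=True)
class MolecularGraph:
    """Constitution + hybridization + one reference geometry.

    Atom indices are 0-based internally; every user-facing surface (TSV files,
    CLI, error messages) uses 1-based indices.
    """

    symbols: tuple[str, ...]
    hybridizations: tuple[str, ...]          # "sp2" | "sp3" | "other"
    bonds: frozenset[frozenset[int]]
    reference_coords: np.ndarray             # (n_atoms, 3) in Å

    def __post_init__(self):
        coords = np.asarray(self.reference_coords, dtype=float)
        object.__setattr__(self, "reference_coords", coords)
        n = len(self.symbols)
        if coords.shape != (n, 3):
            raise ValueError("reference_coords must be (n_atoms, 3)")
        for b in self.bonds:
            for i in b:
                if not 0 <= i < n:
                    raise ValueError(f"bond index {i} out of range")
        if n and not nx.is_connected(self.to_networkx()):
            raise ValueError("molecular graph is disconnected")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(tuple(b) for b in self.bonds)
        return g

    def neighbors(self, i: int) -> list[int]:
        return sorted(j for b in self.bonds if i in b for j in b if j != i)


@dataclass(frozen=True)
class StereoElement:
    """One binary stereochemical degree of freedom (or an sp2 planarity lock).

    ``neighbor_indices`` is the ordered 4-tuple of atoms whose signed volume
    (vector triple product about the last atom) encodes the element's state.
    """

    kind: str  # "stereocenter" | "prochiral-methylene" | "prochiral-gem-dimethyl" | "sp2-planar"
    center_index: int
    neighbor_indices: tuple[int, int, int, int]
    fixed: bool = False

    def label(self) -> str:
        return f"{self.kind}@{self.center_index + 1}"


@dataclass
class BoundsMatrix:
    """Symmetric per-pair lower/upper distance bounds in Å (zero diagonal)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 2:
            raise ValueError("lower/upper must be square matrices of equal shape")

    @property
    def n_atoms(self) -> int:
        return self.lower.shape[0]

    def copy(self) -> "BoundsMatrix":
        return BoundsMatrix(self.lower.copy(), self.upper.copy())

    def validate(self) -> None:
        n = self.n_atoms
        off = ~np.eye(n, dtype=bool)
        bad = (self.lower > self.upper + 1e-9) & off
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InconsistentBoundsError(int(i), int(j), self.lower[i, j], self.upper[i, j])


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(mol_block: str) -> MolecularGraph:
    """Parse an MDL MOL/SDF (V2000) block into a :class:`MolecularGraph`.

    Explicit hydrogens are mandatory: holonomic bounds and prochiral tracking
    need every proton as a graph node.
    """
    mol = Chem.MolFromMolBlock(mol_block, removeHs=False, sanitize=True)
    if mol is None:
        raise ValueError("unparseable MOL/SDF block")
    if mol.GetNumConformers() == 0:
        raise ValueError("MOL block carries no 3D coordinates")
    if any(a.GetNumImplicitHs() + a.GetNumExplicitHs() > 0 for a in mol.GetAtoms()):
        raise ValueError("MOL block must contain explicit hydrogens only")

    symbols = tuple(a.GetSymbol() for a in mol.GetAtoms())
    hybrid = []
    for a in mol.GetAtoms():
        orders = [b.GetBondType() for b in a.GetBonds()]
        n_double = sum(o == Chem.BondType.DOUBLE for o in orders)
        aromatic = any(o == Chem.BondType.AROMATIC for o in orders)
        triple = any(o == Chem.BondType.TRIPLE for o in orders)
        if triple or n_double >= 2:
            hybrid.append("other")
        elif aromatic or n_double == 1:
            hybrid.append("sp2")
        else:
            hybrid.append("sp3")
    bonds = frozenset(
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in mol.GetBonds()
    )
    coords = mol.GetConformer().GetPositions()
    return MolecularGraph(symbols, tuple(hybrid), bonds, np.asarray(coords, float))


# ---------------------------------------------------------------------------
# stereogenic element enumeration (constitution only)
# ---------------------------------------------------------------------------

def _branch_signature(graph: MolecularGraph, center: int, start: int) -> tuple:
    """Canonical signature of the branch entered from ``center`` via ``start``.

    BFS away from the center; two substituents are constitutionally equivalent
    iff their signatures match.  Coordinates never enter, so enumeration is
    mirror-invariant by construction.
    """
    adj = {i: graph.neighbors(i) for i in range(graph.n_atoms)}
    seen = {center, start}
    frontier = [start]
    layers = []
    while frontier:
        layers.append(tuple(sorted(
            (graph.symbols[a], graph.hybridizations[a], len(adj[a])) for a in frontier
        )))
        nxt = []
        for a in frontier:
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    nxt.append(b)
        frontier = nxt
    return tuple(layers)


def stereo_analysis(graph: MolecularGraph):
    """Constitutional stereo analysis: stereocenters and prochiral groups.

    Returns ``(stereocenters, prochiral)`` where ``stereocenters`` is a list
    of ``(center, neighbor_4tuple)`` and ``prochiral`` maps a center index to
    ``(kind, volume_quad, exchangeable_pair)``.
    """
    stereocenters = []
    prochiral: dict[int, tuple[str, tuple, list[int]]] = {}
    for c in range(graph.n_atoms):
        if graph.hybridizations[c] != "sp3":
            continue
        nbrs = graph.neighbors(c)
        if len(nbrs) != 4:
            continue
        sigs = [_branch_signature(graph, c, n) for n in nbrs]
        distinct = len(set(sigs))
        if distinct == 4:
            stereocenters.append((c, tuple(nbrs)))
        elif distinct == 3:
            # one equivalent pair: prochiral if the pair is H/H or CH3/CH3
            pair = [n for n in nbrs if sigs.count(_branch_signature(graph, c, n)) == 2]
            if len(pair) != 2:
                continue
            a, b = sorted(pair)
            others = sorted(n for n in nbrs if n not in pair)
            if graph.symbols[a] == "H":
                kind = "prochiral-methylene"
            elif graph.symbols[a] == "C" and all(
                graph.symbols[x] == "H" for x in graph.neighbors(a) if x != c
            ):
                kind = "prochiral-gem-dimethyl"
            else:
                continue
            # signed volume of (other1, other2, first exchangeable, center)
            prochiral[c] = (kind, (others[0], others[1], a, c), [a, b])
    return stereocenters, prochiral


def enumerate_stereo_elements(
    graph: MolecularGraph,
    tracked_prochiral: Iterable[int] = (),
    fixed_centers: Iterable[int] | None = None,
) -> list[StereoElement]:
    """Enumerate stereocenters, tracked prochiral groups, and sp2 planarity locks.

    Parameters
    ----------
    tracked_prochiral:
        Center atom indices (0-based) of CH2 / gem-dimethyl groups whose
        diastereotopic assignment should be tracked as a binary element.
        Untracked groups do not multiply the assignment space.
    fixed_centers:
        Stereocenters locked by chiral-volume restraints to the reference
        configuration (the enantiomer-breaking reference; correlated centers
        may be listed together).  Defaults to the lowest-index stereocenter.

    Elements are returned sorted by center atom index; the free (non-fixed,
    non-sp2) elements in this order define the configuration-key positions.
    """
    elements: list[StereoElement] = []
    tracked = set(tracked_prochiral)
    stereocenters, prochiral = stereo_analysis(graph)

    if fixed_centers is None:
        fixed_set = {stereocenters[0][0]} if stereocenters else set()
    else:
        fixed_set = set(fixed_centers)
        known = {c for c, _ in stereocenters}
        unknown = fixed_set - known
        if unknown:
            raise ValueError(
                f"fixed_centers {sorted(i + 1 for i in unknown)} (1-based) are not stereocenters"
            )

    for c, nbrs in stereocenters:
        elements.append(StereoElement("stereocenter", c, nbrs, fixed=c in fixed_set))
    for c in sorted(tracked):
        if c not in prochiral:
            raise ValueError(
                f"atom {c + 1} (1-based) is not a prochiral CH2 or gem-dimethyl center"
            )
        kind, quad, _ = prochiral[c]
        elements.append(StereoElement(kind, c, quad, fixed=False))
    for c in range(graph.n_atoms):
        if graph.hybridizations[c] == "sp2":
            nbrs = graph.neighbors(c)
            if len(nbrs) == 3:
                elements.append(
                    StereoElement("sp2-planar", c, (nbrs[0], nbrs[1], nbrs[2], c), fixed=True)
                )
    elements.sort(key=lambda e: (e.center_index, e.kind))
    return elements


def free_elements(elements: Sequence[StereoElement]) -> list[StereoElement]:
    """The binary assignment degrees of freedom (non-fixed, non-planar)."""
    return [e for e in elements if not e.fixed and e.kind != "sp2-planar"]


def n_assignments(elements: Sequence[StereoElement]) -> int:
    """Number of configurational assignment keys, 2**M for M free elements."""
    return 2 ** len(free_elements(elements))


# ---------------------------------------------------------------------------
# holonomic bounds
# ---------------------------------------------------------------------------

def _torsion_distance_range(r_ij, r_jk, r_kl, theta_ijk, theta_jkl):
    """Min/max distance of a 1,4 pair over the free torsion about j-k.

    Closed form from the internal coordinates of the i-j-k-l fragment:
    syn (0°) gives the minimum, anti (180°) the maximum.
    """
    def d(phi):
        # place j at origin, k on x-axis
        j = np.zeros(3)
        k = np.array([r_jk, 0.0, 0.0])
        # i positioned in the xy-plane so that angle i-j-k = theta_ijk
        i = np.array([r_ij * np.cos(theta_ijk), r_ij * np.sin(theta_ijk), 0.0])
        l = k + np.array([
            -r_kl * np.cos(theta_jkl),
            r_kl * np.sin(theta_jkl) * np.cos(phi),
            r_kl * np.sin(theta_jkl) * np.sin(phi),
        ])
        return float(np.linalg.norm(i - l))

    return d(0.0), d(np.pi)


def build_bounds(graph: MolecularGraph, bond_tolerance: float = 0.01) -> BoundsMatrix:
    """Holonomic distance bounds from constitution + reference geometry.

    Bonds are bounded at the reference length ±``bond_tolerance`` (default
    ±1%), geminal 1,3 distances at ±2%, ring-constrained 1,4 pairs at ±5%,
    open-chain 1,4 pairs span the syn..anti torsion range, and all remaining
    pairs get a van-der-Waals lower bound and a path-length upper bound.
    """
    if bond_tolerance < 0:
        raise ValueError("bond_tolerance must be >= 0")
    n = graph.n_atoms
    coords = graph.reference_coords
    dref = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)

    g = graph.to_networkx()
    for (u, v) in g.edges:
        g.edges[u, v]["length"] = dref[u, v]
    topo = dict(nx.all_pairs_shortest_path_length(g))
    path_len = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    rings = [set(r) for r in nx.cycle_basis(g)]

    vdw = np.array([VDW_RADII.get(s, VDW_DEFAULT) for s in graph.symbols])
    lower = np.zeros((n, n))
    upper = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t = topo[i][j]
            d = dref[i, j]
            if t == 1:
                lo, up = d * (1 - bond_tolerance), d * (1 + bond_tolerance)
            elif t == 2:
                lo, up = d * 0.98, d * 1.02
            elif t == 3:
                if any(i in r and j in r for r in rings):
                    lo, up = d * 0.95, d * 1.05
                else:
                    path = nx.shortest_path(g, i, j)
                    _, jj, kk, _ = path
                    rij, rjk, rkl = dref[i, jj], dref[jj, kk], dref[kk, j]
                    th1 = _angle(coords[i], coords[jj], coords[kk])
                    th2 = _angle(coords[jj], coords[kk], coords[j])
                    lo, up = _torsion_distance_range(rij, rjk, rkl, th1, th2)
                    lo, up = lo * 0.98, up * 1.02
            else:
                lo = NONBONDED_VDW_SCALE * (vdw[i] + vdw[j])
                up = path_len[i][j]
                # never exclude the reference geometry itself
                lo = min(lo, 0.98 * d)
                up = max(up, 1.02 * d)
            lower[i, j] = lower[j, i] = min(lo, up)
            upper[i, j] = upper[j, i] = max(lo, up)
    return BoundsMatrix(lower, upper)


def _angle(a, b, c) -> float:
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosv, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# triangle smoothing
# ---------------------------------------------------------------------------

def smooth_bounds(bounds: BoundsMatrix, max_sweeps: int = 10) -> BoundsMatrix:
    """Triangle-smooth uppers and inverse-triangle-tighten lowers.

    Uppers are contracted to all-pairs shortest paths (Floyd–Warshall); lowers
    are raised via lower[i,j] >= lower[i,k] - upper[k,j].  Idempotent and
    monotone: uppers never increase past their input, lowers never decrease.
    """
    out = bounds.copy()
    U, L = out.upper, out.lower
    n = out.n_atoms
    np.fill_diagonal(U, 0.0)
    np.fill_diagonal(L, 0.0)
    for _ in range(max_sweeps):
        changed = False
        for k in range(n):
            via = U[:, k, None] + U[None, k, :]
            mask = via < U
            if mask.any():
                U[mask] = via[mask]
                changed = True
        for k in range(n):
            via1 = L[:, k, None] - U[None, k, :]
            via2 = L[None, k, :] - U[:, k, None]
            cand = np.maximum(via1, via2)
            mask = cand > L
            if mask.any():
                L[mask] = cand[mask]
                changed = True
        if not changed:
            break
    np.fill_diagonal(U, 0.0)
    np.fill_diagonal(L, 0.0)
    out.validate()
    return out
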