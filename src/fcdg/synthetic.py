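"""Self-contained synthetic test systems: molecules, tensors, restraint sets.

Two hand-picked templates emulate the two analyte classes the method targets:

* ``rigid``  — a rigid bicyclic monoterpene alcohol (2,6,6-trimethyl-
  bicyclo[3.1.1]heptan-3-ol, C10H18O, 29 atoms).  Two free stereocenters
  (ring positions 2 and 3), the correlated bridgehead pair fixed as the
  enantiomer-breaking reference, and three tracked diastereotopic groups (two
  ring methylenes and the gem-dimethyl bridge): 5 binary elements, 32
  assignment keys.  11 one-bond CH RDCs per alignment medium (4 methines,
  4 individually assigned methylene protons, 3 methyls).
* ``flexible`` — an open-chain diol (C13H28O2, 43 atoms) with 4 stereocenters
  (one fixed as reference: 8 diastereomers) and the 13-coupling RDC pattern
  of a flexible natural product: 4 methines, 5 methylenes used as unassigned
  sums of two C-H couplings, 4 methyls, plus sparse NOE distances.

Restraints are back-calculated exactly from a chosen ground-truth geometry
(plus optional Gaussian noise), from alignment tensors that are drawn at
random, so every fixture carries a zero-energy witness: at zero noise the
ground-truth structure satisfies every restraint exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDistGeom

from . import dynamics
from .embed import embed_4d
from .energy import (AlignmentTensor, ChiralRestraint, NOERestraint,
                     RDCRestraint, RestraintSet, _restraint_row,
                     chiral_volume, dmax)
from .moltop import (MolecularGraph, StereoElement, build_bounds, build_graph,
                     free_elements, smooth_bounds, stereo_analysis)

__all__ = [
    "SyntheticSpec", "SyntheticFixture", "make_fixture", "random_tensor",
    "synth_rdc", "synth_noe", "TEMPLATES",
]

TEMPLATES = {
    "rigid": {
        "smiles": "CC1C(O)CC2CC1C2(C)C",
        "methylene_mode": "individual",
        "free_centers": 2,
    },
    "flexible": {
        "smiles": "CCC(C)CC(O)CC(C)CC(O)CC",
        "methylene_mode": "sum",
        "free_centers": 3,
    },
}


@dataclass(frozen=True)
class SyntheticSpec:
    template: str = "rigid"
    media: int = 3
    rdc_sigma: float = 0.0         # Hz
    noe_sigma: float = 0.0         # Å
    ground_truth_key: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template '{self.template}'")
        if not 1 <= self.media <= 4:
            raise ValueError("media count must be in 1..4")
        if self.rdc_sigma < 0 or self.noe_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass
class SyntheticFixture:
    graph: MolecularGraph
    elements: list[StereoElement]
    truth_key: str
    tracked: tuple[int, ...]
    fixed_centers: tuple[int, ...]
    spec: SyntheticSpec


def _embed_template(smiles: str, seed: int) -> str:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = int(seed % (2 ** 31 - 1)) + 1
    if rdDistGeom.EmbedMolecule(mol, params) != 0:
        raise RuntimeError("template embedding failed")
    return Chem.MolToMolBlock(mol)


def _reference_chiral_restraints(graph, elements, k_chir=2.0):
    """Chiral restraints pinning fixed elements (and sp2 planes) to the reference."""
    out = []
    for e in elements:
        if e.kind == "sp2-planar":
            out.append(ChiralRestraint(e, 0.0, k_chir))
        elif e.fixed:
            v, _ = chiral_volume(graph.reference_coords, e)
            out.append(ChiralRestraint(e, v, k_chir))
    return out


def _branch_atoms(graph, center, start):
    """Atoms of the substituent branch entered from ``center`` via ``start``."""
    seen = {center, start}
    stack = [start]
    while stack:
        a = stack.pop()
        for nb in graph.neighbors(a):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    seen.discard(center)
    return sorted(seen)


def _flip_element(graph, coords, element):
    """Invert one stereo element by swapping two exchangeable substituent branches.

    For prochiral groups the exchangeable pair is defined by the element; for
    stereocenters the two smallest branches are swapped.  The swap translates
    each branch rigidly onto the other root, leaving small bond distortions
    for the subsequent holonomic minimization to repair.
    """
    x = np.array(coords, float)
    c = element.center_index
    if element.kind == "stereocenter":
        nbrs = list(element.neighbor_indices)
        branches = {n: _branch_atoms(graph, c, n) for n in nbrs}
        a, b = sorted(nbrs, key=lambda n: len(branches[n]))[:2]
    else:
        # exchangeable pair: the two substituents of identical constitution
        quad = element.neighbor_indices
        a = quad[2]
        sibs = [n for n in graph.neighbors(c)
                if n != a and graph.symbols[n] == graph.symbols[a]
                and n not in quad[:2]]
        b = sibs[0]
        branches = {a: _branch_atoms(graph, c, a), b: _branch_atoms(graph, c, b)}
    shift_ab = x[b] - x[a]
    xa = x[branches[a]] + shift_ab
    xb = x[branches[b]] - shift_ab
    x[branches[a]] = xa
    x[branches[b]] = xb
    return x


def _realize_key(graph, elements, key, k_chir=2.0):
    """Produce a geometry realizing a requested configuration key.

    Swaps exchangeable substituent branches of every element whose sign
    disagrees with the request, then repairs the geometry by minimizing the
    holonomic pseudo-energy with all elements pinned to their target signs.
    """
    from .stereo import classify

    free = free_elements(elements)
    if len(key) != len(free):
        raise ValueError(f"key length {len(key)} != {len(free)} free elements")
    bounds = smooth_bounds(build_bounds(graph))
    current = classify(graph.reference_coords, elements)
    x = np.array(graph.reference_coords, float)
    # key signs are parity-canonicalized by the fixed reference element's sign
    fixed_refs = [e for e in elements if e.fixed and e.kind != "sp2-planar"]
    parity = 1.0
    if fixed_refs:
        v_ref, _ = chiral_volume(graph.reference_coords, fixed_refs[0])
        parity = 1.0 if v_ref > 0 else -1.0
    restraints = RestraintSet(
        chiral=list(_reference_chiral_restraints(graph, elements, k_chir)))
    for e, want, have in zip(free, key, current):
        v, _ = chiral_volume(graph.reference_coords, e)
        target = parity * (abs(v) if want == "+" else -abs(v))
        restraints.chiral.append(ChiralRestraint(e, target, 10 * k_chir))
        if want != have:
            x = _flip_element(graph, x, e)
    x = dynamics._descend(x, bounds, restraints, graph.symbols, tol=1e-8, max_iter=3000)
    base = RestraintSet(
        chiral=list(_reference_chiral_restraints(graph, elements, k_chir)))
    x = dynamics._descend(x, bounds, base, graph.symbols, tol=1e-8, max_iter=1500)
    if classify(x, elements) != key:
        raise RuntimeError(f"could not realize configuration key {key}")
    return x


def make_fixture(spec: SyntheticSpec) -> SyntheticFixture:
    """Build the template molecule and a ground-truth geometry for the spec."""
    from .stereo import classify

    tmpl = TEMPLATES[spec.template]
    graph = build_graph(_embed_template(tmpl["smiles"], spec.seed))
    stereocenters, prochiral = stereo_analysis(graph)
    centers = [c for c, _ in stereocenters]
    if spec.template == "rigid":
        # the correlated bridgehead pair is the fixed reference; ring
        # methylenes + gem-dimethyl are tracked
        ring4 = _smallest_ring(graph)
        fixed = tuple(sorted(c for c in centers if c in ring4))
        tracked = tuple(sorted(prochiral))
    else:
        fixed = (centers[0],)
        tracked = ()
    from .moltop import enumerate_stereo_elements
    elements = enumerate_stereo_elements(graph, tracked_prochiral=tracked,
                                         fixed_centers=fixed)
    key = classify(graph.reference_coords, elements)
    if spec.ground_truth_key is not None and spec.ground_truth_key != key:
        coords = _realize_key(graph, elements, spec.ground_truth_key)
        graph = replace(graph, reference_coords=coords)
        key = classify(graph.reference_coords, elements)
        if key != spec.ground_truth_key:
            raise RuntimeError("failed to realize the requested ground-truth key")
    return SyntheticFixture(graph=graph, elements=elements, truth_key=key,
                            tracked=tracked, fixed_centers=fixed, spec=spec)


def _smallest_ring(graph: MolecularGraph) -> set[int]:
    import networkx as nx
    rings = nx.cycle_basis(graph.to_networkx())
    return set(min(rings, key=len))


# ---------------------------------------------------------------------------
# restraint synthesis
# ---------------------------------------------------------------------------

def random_tensor(rng: np.random.Generator, medium: str = "medium_1") -> AlignmentTensor:
    """Random symmetric traceless Saupe tensor of realistic magnitude.

    The principal order parameter is drawn so that back-calculated one-bond
    CH couplings fall within a ±30 Hz window (|S| ~ 1e-3, weak alignment).
    """
    a = rng.normal(size=(3, 3))
    m = 0.5 * (a + a.T)
    m -= np.eye(3) * np.trace(m) / 3.0
    zeta = rng.uniform(6e-4, 1.2e-3)
    m *= zeta / np.max(np.abs(np.linalg.eigvalsh(m)))
    return AlignmentTensor.from_matrix(m, medium=medium)


def ch_rdc_template(graph: MolecularGraph, medium: str,
                    methylene_mode: str = "individual",
                    k: float = 1.0) -> list[RDCRestraint]:
    """One-bond CH RDC restraint skeletons (d_exp unset) for all CHn groups."""
    rows: list[RDCRestraint] = []
    for c in range(graph.n_atoms):
        if graph.symbols[c] != "C":
            continue
        hs = [n for n in graph.neighbors(c) if graph.symbols[n] == "H"]
        heavies = [n for n in graph.neighbors(c) if graph.symbols[n] != "H"]
        if len(hs) == 1:
            rows.append(RDCRestraint(((c, hs[0]),), 0.0, medium, "single", k))
        elif len(hs) == 2:
            if methylene_mode == "sum":
                rows.append(RDCRestraint(((c, hs[0]), (c, hs[1])), 0.0, medium,
                                         "methylene-sum", k))
            else:
                for h in hs:
                    rows.append(RDCRestraint(((c, h),), 0.0, medium, "single", k))
        elif len(hs) == 3 and len(heavies) == 1:
            rows.append(RDCRestraint(((c, heavies[0]),), 0.0, medium, "methyl", k,
                                     h_atoms=tuple(hs)))
    return rows


def synth_rdc(
    coords: np.ndarray,
    symbols,
    tensor: AlignmentTensor,
    rows: list[RDCRestraint],
    sigma: float,
    rng: np.random.Generator,
) -> list[RDCRestraint]:
    """Back-calculate couplings from a geometry + tensor, add Gaussian noise."""
    coords3 = np.asarray(coords, float)[:, :3]
    out = []
    for r in rows:
        d = float(_restraint_row(coords3, symbols, r) @ tensor.s)
        if sigma > 0:
            d += rng.normal(0.0, sigma)
        out.append(replace(r, d_exp=d, medium=tensor.medium))
    return out


def synth_noe(
    coords: np.ndarray,
    pairs: list[tuple[tuple[int, ...], tuple[int, ...]]],
    sigma: float,
    rng: np.random.Generator,
    k: float = 100.0,
) -> list[NOERestraint]:
    """NOE restraints at the r^-6-averaged effective distances (+ noise)."""
    from .energy import _group_distance

    coords = np.asarray(coords, float)[:, :3]
    out = []
    for gi, gj in pairs:
        deff, _, _ = _group_distance(coords, gi, gj)
        d = deff + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        out.append(NOERestraint(tuple(gi), tuple(gj), max(d, 1.5), k))
    return out


def default_noe_pairs(
    graph: MolecularGraph,
    coords: np.ndarray | None = None,
    max_distance: float = 4.5,
    min_bond_separation: int = 3,
    max_pairs: int = 16,
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Sparse assigned NOE contacts from the reference geometry.

    Methyl protons form one r^-6-averaged group (rotation makes them
    indistinguishable); methine and methylene protons enter individually, as
    stereospecifically assigned contacts — it is precisely these assigned
    NOEs that discriminate diastereotopic arrangements.  Pairs are kept when
    the carriers are >= ``min_bond_separation`` bonds apart and the effective
    distance is below ``max_distance`` Å (closest contacts first).
    """
    import networkx as nx

    from .energy import _group_distance

    coords = graph.reference_coords if coords is None else np.asarray(coords, float)
    groups = []
    for c in range(graph.n_atoms):
        if graph.symbols[c] == "H":
            continue
        hs = tuple(n for n in graph.neighbors(c) if graph.symbols[n] == "H")
        if len(hs) == 3:
            groups.append((c, hs))
        else:
            groups.extend((c, (h,)) for h in hs)
    topo = dict(nx.all_pairs_shortest_path_length(graph.to_networkx()))
    cands = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            ca, ha = groups[a]
            cb, hb = groups[b]
            if topo[ca][cb] < min_bond_separation:
                continue
            deff, _, _ = _group_distance(coords, ha, hb)
            if deff <= max_distance:
                cands.append((deff, ha, hb))
    cands.sort(key=lambda t: t[0])
    return [(ha, hb) for _, ha, hb in cands[:max_pairs]]


def make_restraints(
    fixture: SyntheticFixture,
    rng: np.random.Generator,
    k_rdc: float = 1.0,
    k_noe: float = 100.0,
    k_chir: float = 2.0,
    k_dist: float = 2.0,
    with_noe: bool | None = None,
) -> tuple[RestraintSet, list[AlignmentTensor]]:
    """Full restraint set for a fixture: holonomic chiral locks + synthetic NMR data.

    One random alignment tensor per medium; NOEs default to on for the
    flexible template (sparse-NOE study style) and off for the rigid one.
    """
    spec = fixture.spec
    graph = fixture.graph
    tmpl = TEMPLATES[spec.template]
    chiral = _reference_chiral_restraints(graph, fixture.elements, k_chir)
    rs = RestraintSet(chiral=list(chiral), k_dist=k_dist)
    tensors = []
    if k_rdc > 0:
        for m in range(spec.media):
            tensor = random_tensor(rng, medium=f"medium_{m + 1}")
            tensors.append(tensor)
            rows = ch_rdc_template(graph, tensor.medium, tmpl["methylene_mode"], k_rdc)
            rs.rdc.extend(synth_rdc(graph.reference_coords, graph.symbols,
                                    tensor, rows, spec.rdc_sigma, rng))
    if with_noe is None:
        with_noe = spec.template == "flexible"
    if with_noe and k_noe > 0:
        pairs = default_noe_pairs(graph)
        rs.noe.extend(synth_noe(graph.reference_coords, pairs, spec.noe_sigma,
                                rng, k_noe))
    return rs, tensors


def holonomic_restraints(fixture: SyntheticFixture, k_chir: float = 2.0,
                         k_dist: float = 2.0) -> RestraintSet:
    """Restraint set with no NMR data: bounds + chiral locks only (prior sampling)."""
    return RestraintSet(
        chiral=list(_reference_chiral_restraints(fixture.graph, fixture.elements, k_chir)),
        k_dist=k_dist,
    )
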