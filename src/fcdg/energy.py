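"""Dimensionless pseudo-energy terms and analytic Cartesian gradients.

The total penalty  E_total = E_dist + E_chir + E_NOE + E_RDC  measures how
badly a candidate geometry violates the holonomic distance bounds, chiral
volume targets, NOE distances and residual dipolar couplings.  All terms are
dimensionless and non-negative, vanish exactly at satisfaction, and their
negative Cartesian gradients serve as the forces of the distance-bounds-driven
dynamics.  Alignment (Saupe) tensors are re-fitted to the instantaneous
geometry by linear least squares before every RDC evaluation, so the returned
structures always satisfy the least-squares stationarity condition
dE_RDC/dS = 0 of the tensor fit.

Functional forms
----------------
* E_dist: flat-bottomed quadratic, (1/2) K_dist (d - nearest bound)^2 outside
  the [lower, upper] window, zero inside.
* E_chir: (1/2) K_chir (V - V_target)^2 on signed vector triple products.
* E_NOE:  (1/2) K_NOE ln^2(d_exp / d_calc), the log-normal potential; its
  stiffness at d_exp equals K_NOE / d_exp^2, i.e. softer for longer distances
  than a harmonic of equal force constant.
* E_RDC:  (1/2) K_RDC (D_exp - D_calc)^2 per coupling, summed over media.

In the 4D phase, bounds and NOE distances use the full 4-dimensional metric,
while chiral volumes and RDCs are evaluated on the first three coordinates
(their gradients have zero 4th component) — this is what lets configurations
invert barrier-free through the extra dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .moltop import BoundsMatrix, StereoElement

__all__ = [
    "ChiralRestraint", "NOERestraint", "RDCRestraint", "RestraintSet",
    "AlignmentTensor", "EnergyReport", "InsufficientRDCError",
    "e_dist", "chiral_volume", "e_chir", "e_noe",
    "fit_tensor_svd", "e_rdc", "chi2", "q_factor", "e_total", "dmax",
]

# gyromagnetic ratios, rad s^-1 T^-1 (1H, 13C, 15N, 19F, 31P)
GYROMAGNETIC = {
    "H": 2.6752218744e8,
    "C": 6.728284e7,
    "N": -2.7116e7,
    "F": 2.518148e8,
    "P": 1.08394e8,
}
# D_max(r) = -(mu0/4pi) * gamma_i gamma_j * hbar / (2 pi r^3), r in Angstrom -> Hz
_DMAX_COEF = -(1.0e-7 * 1.054571817e-34) / (2.0 * np.pi * 1.0e-30)


def dmax(symbol_i: str, symbol_j: str, r_angstrom) -> float:
    """Static dipolar coupling prefactor (Hz) at internuclear distance r (Å)."""
    gi = GYROMAGNETIC[symbol_i]
    gj = GYROMAGNETIC[symbol_j]
    return _DMAX_COEF * gi * gj / np.asarray(r_angstrom, float) ** 3


class InsufficientRDCError(ValueError):
    def __init__(self, medium: str, n: int):
        self.medium = medium
        super().__init__(
            f"medium '{medium}' has only {n} RDC restraints; >=5 independent "
            f"couplings are required for a Saupe tensor fit"
        )


@dataclass(frozen=True)
class ChiralRestraint:
    element: StereoElement
    target: float              # signed volume, Å^3 (0 for sp2 planarity)
    k: float = 2.0             # Å^-6


@dataclass(frozen=True)
class NOERestraint:
    group_i: tuple[int, ...]
    group_j: tuple[int, ...]
    d_exp: float               # Å
    k: float = 100.0           # dimensionless (log-normal potential)


@dataclass(frozen=True)
class RDCRestraint:
    """One residual dipolar coupling (possibly a sum or a methyl average).

    ``pairs`` holds (i, j) atom index pairs defining internuclear vectors:
    one pair for class "single", the two C-H pairs for "methylene-sum", and
    the (methyl-C, attached-heavy-atom) axis pair for "methyl".  For methyls,
    ``h_atoms`` are the three protons whose mean C-H distance scales D_max,
    and the back-calculated coupling is -1/3 of the axis coupling
    (fast-rotation average).
    """

    pairs: tuple[tuple[int, int], ...]
    d_exp: float               # Hz
    medium: str
    klass: str = "single"      # "single" | "methylene-sum" | "methyl"
    k: float = 1.0             # Hz^-2
    h_atoms: tuple[int, ...] = ()


@dataclass
class RestraintSet:
    chiral: list[ChiralRestraint] = field(default_factory=list)
    noe: list[NOERestraint] = field(default_factory=list)
    rdc: list[RDCRestraint] = field(default_factory=list)
    k_dist: float = 2.0        # Å^-2, holonomic bound violations

    @property
    def media(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rdc:
            seen.setdefault(r.medium, None)
        return list(seen)

    def rdc_by_medium(self, medium: str) -> list[RDCRestraint]:
        return [r for r in self.rdc if r.medium == medium]


@dataclass
class AlignmentTensor:
    """Symmetric traceless Saupe order matrix, parameterized by
    s = (Sxx, Syy, Sxy, Sxz, Syz) with Szz = -Sxx - Syy."""

    s: np.ndarray
    medium: str = ""

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (5,):
            raise ValueError("Saupe parameter vector must have 5 components")

    @property
    def matrix(self) -> np.ndarray:
        sxx, syy, sxy, sxz, syz = self.s
        return np.array([
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ])

    @classmethod
    def from_matrix(cls, m: np.ndarray, medium: str = "") -> "AlignmentTensor":
        m = np.asarray(m, float)
        if not np.allclose(m, m.T, atol=1e-10) or abs(np.trace(m)) > 1e-10:
            raise ValueError("Saupe matrix must be symmetric and traceless")
        return cls(np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]]), medium)


@dataclass
class EnergyReport:
    edist: float
    echir: float
    enoe: float
    erdc_by_medium: dict[str, float]
    gradient: np.ndarray
    tensors: dict[str, AlignmentTensor]

    @property
    def erdc(self) -> float:
        return float(sum(self.erdc_by_medium.values()))

    @property
    def etotal(self) -> float:
        return self.edist + self.echir + self.enoe + self.erdc


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------

def _pairwise(coords: np.ndarray):
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    return diff, d


def e_dist(coords: np.ndarray, bounds: BoundsMatrix, k_dist: float = 2.0):
    """Flat-bottomed quadratic on bound violations; returns (energy, gradient)."""
    coords = np.asarray(coords, float)
    diff, d = _pairwise(coords)
    n = coords.shape[0]
    off = ~np.eye(n, dtype=bool)
    dsafe = np.where(off, d, 1.0)
    over = np.clip(d - bounds.upper, 0.0, None)
    under = np.clip(bounds.lower - d, 0.0, None)
    over[~off] = under[~off] = 0.0
    energy = 0.25 * k_dist * float(np.sum(over ** 2 + under ** 2))  # half of full-matrix sum
    dEdd = k_dist * (over - under)
    grad = np.einsum("ij,ijk->ik", dEdd / dsafe, diff)
    return energy, grad


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # manual cross product along the last axis (np.cross is slow on small arrays)
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def chiral_volume(coords: np.ndarray, element: StereoElement):
    """Signed volume V = (r1-r4)·[(r2-r4)×(r3-r4)] and its gradient.

    Always evaluated on the first three coordinate components.
    """
    i1, i2, i3, i4 = element.neighbor_indices
    r = np.asarray(coords, float)[:, :3]
    a, b, c = r[i1] - r[i4], r[i2] - r[i4], r[i3] - r[i4]
    g1 = _cross(b, c)
    v = float(a @ g1)
    g2 = _cross(c, a)
    g3 = _cross(a, b)
    g4 = -(g1 + g2 + g3)
    return v, {i1: g1, i2: g2, i3: g3, i4: g4}


def e_chir(coords: np.ndarray, chiral: list[ChiralRestraint]):
    """(1/2) K_chir (V - V_target)^2 summed over chiral-volume restraints."""
    coords = np.asarray(coords, float)
    grad = np.zeros_like(coords)
    if not chiral:
        return 0.0, grad
    quads = np.array([r.element.neighbor_indices for r in chiral])
    targets = np.array([r.target for r in chiral])
    ks = np.array([r.k for r in chiral])
    r3 = coords[:, :3]
    p4 = r3[quads[:, 3]]
    a = r3[quads[:, 0]] - p4
    b = r3[quads[:, 1]] - p4
    c = r3[quads[:, 2]] - p4
    g1 = _cross(b, c)
    v = np.einsum("mi,mi->m", a, g1)
    dev = v - targets
    energy = 0.5 * float(np.sum(ks * dev * dev))
    coef = (ks * dev)[:, None]
    g2 = _cross(c, a)
    g3 = _cross(a, b)
    np.add.at(grad[:, :3], quads[:, 0], coef * g1)
    np.add.at(grad[:, :3], quads[:, 1], coef * g2)
    np.add.at(grad[:, :3], quads[:, 2], coef * g3)
    np.add.at(grad[:, :3], quads[:, 3], -coef * (g1 + g2 + g3))
    return energy, grad


def _group_distance(coords: np.ndarray, gi, gj):
    """r^-6-averaged effective distance between two proton groups."""
    ri = coords[list(gi)]
    rj = coords[list(gj)]
    diff = ri[:, None, :] - rj[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(d <= 1e-9):
        raise ValueError("coincident atoms in NOE restraint (d_calc = 0)")
    m = np.mean(d ** -6.0)
    deff = m ** (-1.0 / 6.0)
    return deff, diff, d


def e_noe(coords: np.ndarray, noe: list[NOERestraint]):
    """Log-normal NOE potential (1/2) K ln^2(d_exp/d_calc) with r^-6 group averaging."""
    coords = np.asarray(coords, float)
    grad = np.zeros_like(coords)
    energy = 0.0
    for res in noe:
        deff, diff, d = _group_distance(coords, res.group_i, res.group_j)
        if deff <= 0 or np.any(d <= 1e-9):
            raise ValueError("coincident atoms in NOE restraint (d_calc = 0)")
        lr = np.log(res.d_exp / deff)
        energy += 0.5 * res.k * lr * lr
        dE_ddeff = -res.k * lr / deff
        npairs = d.size
        # d(deff)/d(d_ab) = deff^7 * d_ab^-7 / n_pairs
        coef = dE_ddeff * (deff ** 7) * d ** -7.0 / npairs
        unit = diff / d[..., None]
        for a_idx, a in enumerate(res.group_i):
            grad[a] += np.einsum("j,jk->k", coef[a_idx], unit[a_idx])
        for b_idx, b in enumerate(res.group_j):
            grad[b] -= np.einsum("i,ik->k", coef[:, b_idx], unit[:, b_idx])
    return energy, grad


# ---------------------------------------------------------------------------
# RDC: design rows, SVD fit, energy
# ---------------------------------------------------------------------------

def _basis_rows(u: np.ndarray) -> np.ndarray:
    """(m, 5) Saupe design basis for (m, 3) unit vectors."""
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    return np.stack([
        ux * ux - uz * uz,
        uy * uy - uz * uz,
        2 * ux * uy,
        2 * ux * uz,
        2 * uy * uz,
    ], axis=1)


class _MediumWorkspace:
    """Precompiled index arrays for one medium's restraints (static per run)."""

    def __init__(self, symbols, rdcs: list[RDCRestraint]):
        self.rdcs = rdcs
        self.n_res = len(rdcs)
        self.d_exp = np.array([r.d_exp for r in rdcs])
        self.k = np.array([r.k for r in rdcs])
        # vector sub-pairs of single / methylene-sum restraints
        pi, pj, owner, gamma = [], [], [], []
        mi_c, mi_h, mi_owner = [], [], []   # methyls: axis pairs + protons
        for t, r in enumerate(rdcs):
            if r.klass == "methyl":
                (c, heavy), = r.pairs
                mi_c.append((c, heavy))
                mi_h.append(r.h_atoms)
                mi_owner.append(t)
            else:
                for (i, j) in r.pairs:
                    pi.append(i)
                    pj.append(j)
                    owner.append(t)
                    gamma.append(GYROMAGNETIC[symbols[i]] * GYROMAGNETIC[symbols[j]])
        self.pi = np.array(pi, dtype=int)
        self.pj = np.array(pj, dtype=int)
        self.owner = np.array(owner, dtype=int)
        self.gamma = np.array(gamma)
        self.me_pairs = np.array(mi_c, dtype=int).reshape(-1, 2)
        self.me_h = np.array(mi_h, dtype=int).reshape(-1, 3) if mi_h else np.zeros((0, 3), int)
        self.me_owner = np.array(mi_owner, dtype=int)
        self.me_gamma = np.array(
            [GYROMAGNETIC[symbols[c]] * GYROMAGNETIC["H"] for c, _ in mi_c]
        ) if mi_c else np.zeros(0)

    def design(self, coords3: np.ndarray):
        """Design matrix A with D_calc = A @ s, plus cached geometry."""
        A = np.zeros((self.n_res, 5))
        geo = {}
        if len(self.pi):
            v = coords3[self.pj] - coords3[self.pi]
            r = np.linalg.norm(v, axis=1)
            # floor guards against transient atom overlap during hot dynamics
            r = np.maximum(r, 0.5)
            u = v / r[:, None]
            dm = _DMAX_COEF * self.gamma / r ** 3
            rows = dm[:, None] * _basis_rows(u)
            np.add.at(A, self.owner, rows)
            geo["pair"] = (u, r, dm)
        if len(self.me_pairs):
            c, hv = self.me_pairs[:, 0], self.me_pairs[:, 1]
            v = coords3[hv] - coords3[c]
            r_ax = np.maximum(np.linalg.norm(v, axis=1), 0.5)
            u = v / r_ax[:, None]
            w = coords3[self.me_h] - coords3[c][:, None, :]   # (m, 3H, 3)
            rh = np.maximum(np.linalg.norm(w, axis=2), 0.5)
            rbar = rh.mean(axis=1)
            dm = _DMAX_COEF * self.me_gamma / rbar ** 3
            A[self.me_owner] += (-1.0 / 3.0) * dm[:, None] * _basis_rows(u)
            geo["methyl"] = (u, r_ax, dm, rbar, w, rh)
        return A, geo

    def gradient(self, coords3, S, resid, geo):
        """-dE/dD accumulation: grad of (1/2) Σ k (D_exp - D_calc)^2, S fixed."""
        grad = np.zeros_like(coords3)
        pref_res = -self.k * resid                       # dE/dD_calc per restraint
        if "pair" in geo:
            u, r, dm = geo["pair"]
            q = np.einsum("mi,ij,mj->m", u, S, u)
            Su = u @ S.T
            dD_dv = (dm / r)[:, None] * (2.0 * Su - 5.0 * q[:, None] * u)
            g = pref_res[self.owner][:, None] * dD_dv
            np.add.at(grad, self.pj, g)
            np.add.at(grad, self.pi, -g)
        if "methyl" in geo:
            u, r_ax, dm, rbar, w, rh = geo["methyl"]
            c, hv = self.me_pairs[:, 0], self.me_pairs[:, 1]
            q = np.einsum("mi,ij,mj->m", u, S, u)
            Su = u @ S.T
            pref = pref_res[self.me_owner]
            dD_dv = (-(1.0 / 3.0) * dm / r_ax)[:, None] * 2.0 * (Su - q[:, None] * u)
            g = pref[:, None] * dD_dv
            np.add.at(grad, hv, g)
            np.add.at(grad, c, -g)
            # distance dependence through the mean C-H length
            dD_drbar = q * dm / rbar
            uw = w / rh[..., None]
            gh = (pref * dD_drbar / 3.0)[:, None, None] * uw
            np.add.at(grad, self.me_h.ravel(), gh.reshape(-1, 3))
            np.add.at(grad, c, -gh.sum(axis=1))
        return grad


# small identity-keyed cache: restraint lists are static during a run
_WS_CACHE: list = []


def _workspaces(symbols, rdcs: list[RDCRestraint]) -> dict[str, _MediumWorkspace]:
    for lst, syms, ws in _WS_CACHE:
        if lst is rdcs and syms is symbols:
            return ws
    media: dict[str, list[RDCRestraint]] = {}
    for r in rdcs:
        media.setdefault(r.medium, []).append(r)
    ws = {m: _MediumWorkspace(symbols, rows) for m, rows in media.items()}
    _WS_CACHE.insert(0, (rdcs, symbols, ws))
    del _WS_CACHE[4:]
    return ws


def _restraint_row(coords3: np.ndarray, symbols, res: RDCRestraint) -> np.ndarray:
    """Design-matrix row: D_calc(res) = row · s for Saupe parameters s."""
    ws = _MediumWorkspace(symbols, [res])
    A, _ = ws.design(np.asarray(coords3, float)[:, :3])
    return A[0]


def fit_tensor_svd(coords, symbols, rdcs: list[RDCRestraint], medium: str = ""):
    """Least-squares Saupe tensor from >=5 couplings of one medium.

    Returns (AlignmentTensor, back-calculated couplings).  A rank-deficient
    design matrix yields the minimum-norm solution with a warning.
    """
    if len(rdcs) < 5:
        raise InsufficientRDCError(medium or (rdcs[0].medium if rdcs else "?"), len(rdcs))
    coords3 = np.asarray(coords, float)[:, :3]
    A, _ = _MediumWorkspace(symbols, rdcs).design(coords3)
    b = np.array([r.d_exp for r in rdcs])
    s, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 5:
        warnings.warn(
            f"rank-deficient RDC design matrix (rank {rank}) for medium "
            f"'{medium}'; returning the minimum-norm tensor", RuntimeWarning,
        )
    tensor = AlignmentTensor(s, medium=medium)
    return tensor, A @ s


def e_rdc(coords, symbols, rdcs: list[RDCRestraint]):
    """RDC pseudo-energy over all media with per-call tensor refits.

    The coordinate gradient holds each Saupe tensor at its per-call optimum;
    the implicit dS/dr term vanishes because the fit satisfies dE_RDC/dS = 0
    (envelope condition).  Returns (energies, gradient, tensors, dcalc_by_medium).
    """
    coords = np.asarray(coords, float)
    coords3 = np.ascontiguousarray(coords[:, :3])
    grad = np.zeros_like(coords)
    tensors: dict[str, AlignmentTensor] = {}
    energies: dict[str, float] = {}
    dcalc_all: dict[str, np.ndarray] = {}
    for medium, ws in _workspaces(symbols, rdcs).items():
        if np.all(ws.k == 0.0):
            energies[medium] = 0.0
            continue
        if ws.n_res < 5:
            raise InsufficientRDCError(medium, ws.n_res)
        A, geo = ws.design(coords3)
        # normal equations: cheap and exact for the well-conditioned 5-parameter fit
        ata = A.T @ A
        try:
            s = np.linalg.solve(ata, A.T @ ws.d_exp)
        except np.linalg.LinAlgError:
            s = None
        if s is None or not np.all(np.isfinite(s)):
            s, _, rank, _ = np.linalg.lstsq(A, ws.d_exp, rcond=None)
            if rank < 5:
                warnings.warn(
                    f"rank-deficient RDC design matrix (rank {rank}) for medium "
                    f"'{medium}'; using the minimum-norm tensor", RuntimeWarning,
                )
        tensor = AlignmentTensor(s, medium=medium)
        tensors[medium] = tensor
        dcalc = A @ s
        dcalc_all[medium] = dcalc
        resid = ws.d_exp - dcalc
        energies[medium] = float(0.5 * np.sum(ws.k * resid ** 2))
        grad[:, :3] += ws.gradient(coords3, tensor.matrix, resid, geo)
    return energies, grad, tensors, dcalc_all


# ---------------------------------------------------------------------------
# fit statistics and totals
# ---------------------------------------------------------------------------

def chi2(x_exp, x_calc, weights=None) -> float:
    """Weighted sum of squared deviations, chi^2 = sum w_i (X_exp - X_calc)^2."""
    x_exp = np.asarray(x_exp, float)
    x_calc = np.asarray(x_calc, float)
    if x_exp.shape != x_calc.shape:
        raise ValueError("chi2: length mismatch between experimental and calculated values")
    w = np.ones_like(x_exp) if weights is None else np.asarray(weights, float)
    if w.shape != x_exp.shape:
        raise ValueError("chi2: weights length mismatch")
    return float(np.sum(w * (x_exp - x_calc) ** 2))


def q_factor(d_exp, d_calc, weights=None, root: bool = False) -> float:
    """Normalized RDC residual sum_w(ΔD)^2 / sum_w(D_exp)^2.

    ``root=True`` applies the conventional square root; the plain ratio is the
    default.
    """
    d_exp = np.asarray(d_exp, float)
    d_calc = np.asarray(d_calc, float)
    w = np.ones_like(d_exp) if weights is None else np.asarray(weights, float)
    denom = float(np.sum(w * d_exp ** 2))
    if denom <= 0:
        raise ValueError("q_factor undefined: all experimental couplings are zero")
    q = float(np.sum(w * (d_exp - d_calc) ** 2)) / denom
    return float(np.sqrt(q)) if root else q


class CompiledSystem:
    """Bounds + restraints packed into flat arrays for the JIT-compiled kernel.

    Evaluates the identical mathematics as :func:`e_total` (the two paths are
    cross-checked in the tests); used by the dynamics inner loops where Python
    overhead would dominate.  Treat the underlying restraint set as immutable
    while a compiled system is in use.
    """

    def __init__(self, bounds: BoundsMatrix, restraints: RestraintSet, symbols):
        from ._kernels import _etotal_grad
        self._kernel = _etotal_grad
        self.bounds = bounds
        self.restraints = restraints
        self.symbols = symbols
        self.lower = np.ascontiguousarray(bounds.lower)
        self.upper = np.ascontiguousarray(bounds.upper)
        self.k_dist = float(restraints.k_dist)
        ch = restraints.chiral
        self.chir_quads = np.array(
            [c.element.neighbor_indices for c in ch], dtype=np.int64
        ).reshape(-1, 4)
        self.chir_targets = np.array([c.target for c in ch], dtype=float)
        self.chir_ks = np.array([c.k for c in ch], dtype=float)
        pi, pj, owner = [], [], []
        for t, r in enumerate(restraints.noe):
            for a in r.group_i:
                for b in r.group_j:
                    pi.append(a)
                    pj.append(b)
                    owner.append(t)
        self.noe_pi = np.array(pi, dtype=np.int64)
        self.noe_pj = np.array(pj, dtype=np.int64)
        self.noe_owner = np.array(owner, dtype=np.int64)
        self.noe_npairs = np.array(
            [len(r.group_i) * len(r.group_j) for r in restraints.noe], dtype=float
        )
        self.noe_dexp = np.array([r.d_exp for r in restraints.noe], dtype=float)
        self.noe_k = np.array([r.k for r in restraints.noe], dtype=float)
        self.media = restraints.media
        med_index = {m: i for i, m in enumerate(self.media)}
        vp_i, vp_j, vp_g, vp_o = [], [], [], []
        me_c, me_hv, me_g, me_o, me_h = [], [], [], [], []
        rdcs = restraints.rdc
        for t, r in enumerate(rdcs):
            if r.klass == "methyl":
                (c, hv), = r.pairs
                me_c.append(c)
                me_hv.append(hv)
                me_g.append(GYROMAGNETIC[symbols[c]] * GYROMAGNETIC["H"])
                me_o.append(t)
                me_h.append(r.h_atoms)
            else:
                for (i, j) in r.pairs:
                    vp_i.append(i)
                    vp_j.append(j)
                    vp_g.append(GYROMAGNETIC[symbols[i]] * GYROMAGNETIC[symbols[j]])
                    vp_o.append(t)
        self.vp_i = np.array(vp_i, dtype=np.int64)
        self.vp_j = np.array(vp_j, dtype=np.int64)
        self.vp_gamma = np.array(vp_g, dtype=float)
        self.vp_owner = np.array(vp_o, dtype=np.int64)
        self.me_c = np.array(me_c, dtype=np.int64)
        self.me_hv = np.array(me_hv, dtype=np.int64)
        self.me_gamma = np.array(me_g, dtype=float)
        self.me_owner = np.array(me_o, dtype=np.int64)
        self.me_h = np.array(me_h, dtype=np.int64).reshape(-1, 3)
        self.rdc_dexp = np.array([r.d_exp for r in rdcs], dtype=float)
        self.rdc_k = np.array([r.k for r in rdcs], dtype=float)
        self.rdc_med = np.array([med_index[r.medium] for r in rdcs], dtype=np.int64)
        for m in self.media:
            rows = [r for r in rdcs if r.medium == m]
            if any(r.k > 0 for r in rows) and len(rows) < 5:
                raise InsufficientRDCError(m, len(rows))

    def energy_grad(self, coords):
        """(E_total, gradient) — the hot-loop entry point."""
        e, g, _, _ = self._evaluate(coords)
        return float(e[:3].sum() + e[3:].sum()), g

    def _evaluate(self, coords):
        coords = np.ascontiguousarray(coords, dtype=float)
        return self._kernel(
            coords, self.lower, self.upper, self.k_dist,
            self.chir_quads, self.chir_targets, self.chir_ks,
            self.noe_pi, self.noe_pj, self.noe_owner,
            self.noe_npairs, self.noe_dexp, self.noe_k,
            self.vp_i, self.vp_j, self.vp_gamma, self.vp_owner,
            self.me_c, self.me_hv, self.me_gamma, self.me_owner, self.me_h,
            self.rdc_dexp, self.rdc_k, self.rdc_med,
            len(self.media), _DMAX_COEF,
        )

    def report(self, coords) -> EnergyReport:
        """Full per-term report (same content as :func:`e_total`)."""
        e, g, tensors, _ = self._evaluate(coords)
        erdc = {m: float(e[3 + i]) for i, m in enumerate(self.media) if
                np.any((self.rdc_med == i) & (self.rdc_k > 0))}
        tdict = {m: AlignmentTensor(tensors[i], medium=m)
                 for i, m in enumerate(self.media) if m in erdc}
        return EnergyReport(edist=float(e[0]), echir=float(e[1]),
                            enoe=float(e[2]), erdc_by_medium=erdc,
                            gradient=g, tensors=tdict)


def e_total(coords, bounds: BoundsMatrix, restraints: RestraintSet, symbols=None) -> EnergyReport:
    """Full pseudo-energy report with additive gradient.

    ``coords`` may be (n, 3) or (n, 4); in 4D, bounds and NOEs use the full
    metric while chiral volumes and RDCs see only the 3D projection.
    """
    coords = np.asarray(coords, float)
    ed, gd = e_dist(coords, bounds, restraints.k_dist)
    ec, gc = e_chir(coords, restraints.chiral)
    en, gn = e_noe(coords, restraints.noe)
    if restraints.rdc:
        if symbols is None:
            raise ValueError("RDC evaluation requires atom symbols")
        er_by_medium, gr, tensors, _ = e_rdc(coords, symbols, restraints.rdc)
    else:
        er_by_medium, gr, tensors = {}, np.zeros_like(coords), {}
    return EnergyReport(
        edist=ed, echir=ec, enoe=en, erdc_by_medium=er_by_medium,
        gradient=gd + gc + gn + gr, tensors=tensors,
    )
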