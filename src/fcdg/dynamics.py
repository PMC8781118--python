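"""Distance-bounds-driven dynamics: annealing, dimension reduction, minimization.

The automated protocol per replicate is

    metrize -> embed in 4D -> 4D simulated annealing -> 4D minimization
    -> 4th-axis compression & reduction to 3D -> 3D annealing -> minimization

with the negative pseudo-energy gradients acting as forces on unit-mass atoms.
Temperatures are dimensionless kinetic scales (β = 1 convention); a per-step
velocity-rescaling thermostat tracks the target, which ramps linearly to zero
during the cooling phase.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embed import EmbeddedStructure, MetrizationError, embed_4d, metrize
from .energy import CompiledSystem, EnergyReport, RestraintSet, e_total

# identity-keyed cache of compiled systems (bounds/restraints are static per run)
_SYS_CACHE: list = []


def _system(bounds, restraints, symbols) -> CompiledSystem:
    for b_, r_, s_, sys_ in _SYS_CACHE:
        if b_ is bounds and r_ is restraints and s_ is symbols:
            return sys_
    sys_ = CompiledSystem(bounds, restraints, symbols)
    _SYS_CACHE.insert(0, (bounds, restraints, symbols, sys_))
    del _SYS_CACHE[6:]
    return sys_
from .moltop import BoundsMatrix, MolecularGraph, StereoElement, smooth_bounds

__all__ = [
    "AnnealSchedule", "StructureRecord", "anneal", "reduce_to_3d",
    "minimize", "run_ensemble",
]

# the printed schedule label is in fs; unit masses + dimensionless energies fix
# no physical time scale, so an internal conversion maps tau=5 fs -> dt=0.05
DT_PER_FS = 0.01


@dataclass(frozen=True)
class AnnealSchedule:
    """Annealing schedule: ``hot_steps`` at ``t_hot``, then ``cool_steps``
    cooling linearly to zero, with time step ``time_step`` (fs label)."""

    time_step: float = 5.0
    hot_steps: int = 5000
    cool_steps: int = 5000
    t_hot: float = 1.0

    def __post_init__(self):
        if self.time_step <= 0 or self.hot_steps <= 0 or self.cool_steps <= 0:
            raise ValueError("schedule requires positive step counts and time step")

    @property
    def dt(self) -> float:
        return self.time_step * DT_PER_FS


@dataclass
class StructureRecord:
    coords: np.ndarray                 # (n_atoms, 3) Å
    energy: EnergyReport
    configuration: str | None = None   # filled by stereo.classify
    replicate: int = 0
    seed: int = 0
    converged: bool = True


def _kinetic_rescale(vel: np.ndarray, t_target: float) -> np.ndarray:
    """Rescale velocities so the kinetic energy per degree of freedom is
    t_target/2 (unit masses, k_B = 1)."""
    ke = 0.5 * float(np.sum(vel * vel))
    dof = vel.size
    if t_target <= 0:
        return np.zeros_like(vel)
    if ke <= 1e-300:
        return vel
    lam = np.sqrt(0.5 * dof * t_target / ke)
    return vel * lam


def anneal(
    start: np.ndarray,
    bounds: BoundsMatrix,
    restraints: RestraintSet,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
    symbols=None,
    extra_force=None,
    max_restarts: int = 3,
    f_cap: float = 50.0,
) -> np.ndarray:
    """Velocity-Verlet simulated annealing with per-step velocity rescaling.

    ``extra_force(coords) -> (energy, gradient)`` can inject an auxiliary
    potential (used by the 4th-axis compression).  Per-atom forces are capped
    at ``f_cap`` (restraint gradients can be enormous for freshly embedded
    structures; capping keeps the integration stable while preserving the
    force direction).  A non-finite energy (exploding step) restarts the
    trajectory with a halved time step.
    """

    def _cap(g):
        if f_cap is None:
            return g
        norms = np.sqrt(np.sum(g * g, axis=1, keepdims=True))
        scale = np.minimum(1.0, f_cap / np.maximum(norms, 1e-12))
        return g * scale

    sys_ = _system(bounds, restraints, symbols)
    x0 = np.array(start, dtype=float)
    dt = schedule.dt
    v0 = rng.normal(size=x0.shape)
    for attempt in range(max_restarts + 1):
        x = x0.copy()
        v = _kinetic_rescale(v0.copy(), schedule.t_hot)
        e, g = sys_.energy_grad(x)
        if extra_force is not None:
            _, ge = extra_force(x)
            g = g + ge
        g = _cap(g)
        ok = True
        total = schedule.hot_steps + schedule.cool_steps
        for step in range(total):
            if step < schedule.hot_steps:
                t_target = schedule.t_hot
            else:
                frac = (step - schedule.hot_steps + 1) / schedule.cool_steps
                t_target = schedule.t_hot * max(0.0, 1.0 - frac)
            v -= 0.5 * dt * g
            x += dt * v
            e, g = sys_.energy_grad(x)
            if extra_force is not None:
                _, ge = extra_force(x)
                g = g + ge
            g = _cap(g)
            if not np.isfinite(e) or not np.all(np.isfinite(g)):
                ok = False
                break
            v -= 0.5 * dt * g
            v = _kinetic_rescale(v, t_target)
        if ok:
            return x
        dt *= 0.5
    raise RuntimeError("annealing diverged despite time-step halving")


def reduce_to_3d(
    coords4: np.ndarray,
    bounds: BoundsMatrix,
    restraints: RestraintSet,
    symbols=None,
    compression_steps: int = 500,
    w_tol: float = 1e-3,
) -> np.ndarray:
    """Compress the 4th coordinate with a growing quadratic penalty, then drop it.

    The penalty (1/2) k_w sum w^2 is ramped geometrically while the structure
    relaxes against all restraints, so 3D distances distort by no more than the
    residual 4th-axis norm (<= ``w_tol`` per atom) before truncation.
    """
    x = np.array(coords4, dtype=float)
    if x.shape[1] != 4:
        raise ValueError("reduce_to_3d expects 4D coordinates")
    if np.max(np.abs(x[:, 3])) <= w_tol:
        return x[:, :3].copy()
    n_stages = 12
    steps_per_stage = max(1, compression_steps // n_stages)
    for k_w in np.geomspace(1.0, 1e8, n_stages):
        def penalty(c, k_w=k_w):
            g = np.zeros_like(c)
            g[:, 3] = k_w * c[:, 3]
            return 0.5 * k_w * float(np.sum(c[:, 3] ** 2)), g
        x = _descend(x, bounds, restraints, symbols, extra=penalty,
                     max_iter=steps_per_stage, tol=1e-8)
        if np.max(np.abs(x[:, 3])) <= w_tol:
            break
    x[:, 3] = np.clip(x[:, 3], -w_tol, w_tol)
    return x[:, :3].copy()


def _descend(x, bounds, restraints, symbols, extra=None, tol=1e-6, max_iter=500):
    """Monotone descent on E_total: limited-memory BFGS with a line search that
    enforces energy decrease across accepted steps."""
    import scipy.optimize

    x = np.array(x, dtype=float)
    shape = x.shape

    sys_ = _system(bounds, restraints, symbols)

    def fg(flat):
        c = flat.reshape(shape)
        e, g = sys_.energy_grad(c)
        if extra is not None:
            ee, ge = extra(c)
            e, g = e + ee, g + ge
        return e, g.ravel()

    res = scipy.optimize.minimize(
        fg, x.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-18, "gtol": tol, "maxls": 40},
    )
    return res.x.reshape(shape)


def minimize(
    coords: np.ndarray,
    bounds: BoundsMatrix,
    restraints: RestraintSet,
    symbols=None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> StructureRecord:
    """Gradient-descent optimization of E_total to gradient norm <= ``tol``.

    Energy is monotone non-increasing across accepted steps.  Hitting the
    iteration cap returns the best structure found with ``converged=False``.
    """
    x = _descend(np.array(coords, float), bounds, restraints, symbols,
                 tol=tol, max_iter=max_iter)
    rep = e_total(x, bounds, restraints, symbols)
    converged = float(np.linalg.norm(rep.gradient)) <= max(tol, 1e-6) * 10
    return StructureRecord(coords=x, energy=rep, converged=converged)


def run_ensemble(
    graph: MolecularGraph,
    bounds: BoundsMatrix,
    restraints: RestraintSet,
    n_structures: int,
    schedule: AnnealSchedule,
    seed: int,
    elements: list[StereoElement] | None = None,
    compression_steps: int = 500,
    min_tol: float = 1e-6,
    sort_by_energy: bool = False,
    quench_cycles: int = 2,
) -> list[StructureRecord]:
    """Produce ``n_structures`` independent fc-rDG/DDD replicates.

    Each replicate runs metrize -> 4D embed -> 4D anneal -> 4D minimize ->
    reduce -> 3D anneal -> minimize, concluded by ``quench_cycles`` short
    low-temperature anneal/minimize rounds that keep the best structure found
    (deeper relaxation of each replicate into its configurational family's
    energy floor).  Every replicate derives its own seed from the master seed.
    Failed replicates (metrization dead ends, diverged dynamics, ambiguous
    stereo classification) are redrawn with fresh sub-seeds.
    """
    from .stereo import AmbiguousClassificationError, classify

    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    symbols = graph.symbols
    smoothed = smooth_bounds(bounds)
    records: list[StructureRecord] = []
    ss = np.random.SeedSequence(seed)
    draws = 0
    failures = 0
    while len(records) < n_structures:
        child = ss.spawn(1)[0]
        draws += 1
        if draws > 20 * n_structures:
            raise RuntimeError("too many failed replicates; check restraints")
        rng = np.random.default_rng(child)
        try:
            dmat = metrize(smoothed, rng)
            x4 = embed_4d(dmat).coords
            x4 = anneal(x4, smoothed, restraints, schedule, rng, symbols)
            x4 = _descend(x4, smoothed, restraints, symbols, tol=min_tol, max_iter=500)
            x3 = reduce_to_3d(x4, smoothed, restraints, symbols,
                              compression_steps=compression_steps)
            x3 = anneal(x3, smoothed, restraints, schedule, rng, symbols)
            x3 = _descend(x3, smoothed, restraints, symbols, tol=min_tol,
                          max_iter=2000)
            if quench_cycles > 0:
                sys_ = _system(smoothed, restraints, symbols)
                e_best, _ = sys_.energy_grad(x3)
                qsched = AnnealSchedule(
                    schedule.time_step,
                    max(20, schedule.hot_steps // 5),
                    max(40, schedule.cool_steps // 5),
                    0.25 * schedule.t_hot,
                )
                for _ in range(quench_cycles):
                    xq = anneal(x3, smoothed, restraints, qsched, rng, symbols)
                    xq = _descend(xq, smoothed, restraints, symbols,
                                  tol=min_tol, max_iter=2000)
                    e_q, _ = sys_.energy_grad(xq)
                    if e_q < e_best:
                        x3, e_best = xq, e_q
            rec = minimize(x3, smoothed, restraints, symbols, tol=min_tol)
        except (MetrizationError, RuntimeError):
            failures += 1
            continue
        rec.replicate = len(records)
        rec.seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        if elements is not None:
            try:
                rec.configuration = classify(rec.coords, elements)
            except AmbiguousClassificationError:
                failures += 1
                continue
        records.append(rec)
    if failures:
        import warnings

        warnings.warn(f"{failures} replicate(s) failed and were redrawn",
                      RuntimeWarning)
    if sort_by_energy:
        records.sort(key=lambda r: r.energy.etotal)
    return records


def energy_steps(records: list[StructureRecord]) -> np.ndarray:
    """ΔE_N = E_N - E_(N-1) over the energy-sorted ensemble (rank-plot steps)."""
    e = np.sort([r.energy.etotal for r in records])
    return np.diff(e)
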