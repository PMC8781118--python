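"""Bayesian inference over fc-rDG pseudo-energies.

A canonical rDG ensemble assigns each sampled structure θ the Boltzmann
likelihood exp(-E_total(θ)) (β = 1).  With the uniform sampling prior
P(θ) = 1/N_DG, the posterior probability that the analyte's configuration is
Θ — the *diastereomeric differentiability* dd(Θ) — is the Boltzmann-weighted
share of the ensemble in family Θ:

    dd(Θ) = P(Θ|D) = Σ_{θ∈Θ} exp(-E_total(θ)) / Z,   Z = Σ_all exp(-E_total).

Three equivalent views of the same posterior are provided: direct Boltzmann
summation, Metropolis Monte-Carlo resampling of the ensemble (which also
yields uncertainties from independent chains), and the stationary distribution
of the Metropolis transition matrix contracted over configurational families.
AIC weights and posterior odds/Bayes factors cover the model-comparison view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .dynamics import StructureRecord
from .stereo import ConfigurationFamily

__all__ = [
    "EnsembleSummary", "TransitionMatrix", "boltzmann_dd", "aic",
    "aic_weight_ratio", "posterior_odds", "metropolis_dd",
    "metropolis_from_energies", "build_transition_matrix", "contract",
    "stationary",
]


@dataclass
class EnsembleSummary:
    dd: dict[str, float]
    z: float
    counts: dict[str, int]
    uncertainty: dict[str, float] = field(default_factory=dict)
    n_dg: int = 0


@dataclass
class TransitionMatrix:
    p: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, float)
        rows = self.p.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("transition matrix must be right-stochastic (rows sum to 1)")


def _energies_keys(records: list[StructureRecord]):
    if not records:
        raise ValueError("empty ensemble")
    e = np.array([r.energy.etotal for r in records])
    keys = [r.configuration for r in records]
    if any(k is None for k in keys):
        raise ValueError("ensemble contains unclassified records")
    return e, keys


def _boltzmann_weights(e: np.ndarray) -> np.ndarray:
    # shift by the ensemble minimum before exponentiation; exact in all ratios
    return np.exp(-(e - e.min()))


def boltzmann_dd(
    records: list[StructureRecord],
    all_keys: list[str] | None = None,
) -> EnsembleSummary:
    """Posterior assignment probabilities dd(Θ) by direct Boltzmann summation.

    ``all_keys`` may list keys never sampled; these get dd = 0 with a warning.
    """
    e, keys = _energies_keys(records)
    w = _boltzmann_weights(e)
    z = float(w.sum())
    dd: dict[str, float] = {}
    counts: dict[str, int] = {}
    for wi, k in zip(w, keys):
        dd[k] = dd.get(k, 0.0) + wi
        counts[k] = counts.get(k, 0) + 1
    for k in dd:
        dd[k] /= z
    if all_keys is not None:
        missing = [k for k in all_keys if k not in dd]
        if missing:
            warnings.warn(
                f"{len(missing)} configuration keys were never sampled; their "
                f"posterior probability is reported as 0", RuntimeWarning,
            )
        for k in missing:
            dd[k] = 0.0
            counts.setdefault(k, 0)
    return EnsembleSummary(dd=dd, z=z, counts=counts, n_dg=len(records))


def aic(x_exp, x_calc, sigmas, k: int) -> float:
    """Akaike information criterion 2k + Σ (X_exp - X_calc)^2 / σ^2."""
    x_exp = np.asarray(x_exp, float)
    x_calc = np.asarray(x_calc, float)
    s = np.broadcast_to(np.asarray(sigmas, float), x_exp.shape)
    if np.any(s <= 0):
        raise ValueError("sigmas must be positive")
    return float(2 * k + np.sum((x_exp - x_calc) ** 2 / s ** 2))


def aic_weight_ratio(aic_a: float, aic_b: float) -> float:
    """Relative AIC weight P_A/P_B = exp(-(AIC_A - AIC_B)/2)."""
    return float(np.exp(-0.5 * (aic_a - aic_b)))


def posterior_odds(prior_odds: float, bayes_factor: float) -> float:
    """Posterior odds O(Θ|D) = prior odds × Bayes factor."""
    if prior_odds <= 0 or bayes_factor <= 0:
        raise ValueError("odds and Bayes factors must be positive")
    return prior_odds * bayes_factor


def metropolis_dd(
    records: list[StructureRecord],
    n_chains: int = 10_000,
    chain_length: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Metropolis Monte-Carlo resampling of the rDG ensemble.

    Chains pick structures uniformly at random; a move θ_(n-1) -> θ_n is
    accepted if ΔE <= 0 or if a uniform r in [0, 1) is less than exp(-ΔE),
    otherwise the previous state is retained.  Occupancy frequencies per key,
    averaged over chains, estimate dd; the across-chain standard deviation of
    the mean is the uncertainty.  Returns (mean dd, std) per key.
    """
    e, keys = _energies_keys(records)
    rng = np.random.default_rng() if rng is None else rng
    return metropolis_from_energies(e, keys, n_chains, rng, chain_length)


def metropolis_from_energies(
    e: np.ndarray,
    keys: list[str],
    n_chains: int,
    rng: np.random.Generator,
    chain_length: int | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Metropolis occupancy estimate from raw (energy, key) pairs."""
    e = np.asarray(e, float)
    n = len(e)
    if n == 0:
        raise ValueError("empty ensemble")
    if chain_length is None:
        chain_length = n
    if chain_length < n:
        warnings.warn(
            "chain_length shorter than the ensemble size; occupancy estimates "
            "may be poorly converged", RuntimeWarning,
        )
    uniq = sorted(set(keys))
    key_idx = np.array([uniq.index(k) for k in keys])
    occ = np.zeros((n_chains, len(uniq)))
    state = rng.integers(0, n, size=n_chains)
    for _ in range(chain_length):
        prop = rng.integers(0, n, size=n_chains)
        de = e[prop] - e[state]
        accept = (de <= 0) | (rng.random(n_chains) < np.exp(-np.clip(de, 0, 700)))
        state = np.where(accept, prop, state)
        np.add.at(occ, (np.arange(n_chains), key_idx[state]), 1.0)
    occ /= chain_length
    mean = occ.mean(axis=0)
    std = occ.std(axis=0, ddof=1) / np.sqrt(n_chains)
    return (
        {k: float(m) for k, m in zip(uniq, mean)},
        {k: float(s) for k, s in zip(uniq, std)},
    )


def build_transition_matrix(records: list[StructureRecord]) -> TransitionMatrix:
    """Metropolis transition matrix over the sampled structures.

    Uniform proposal over the ensemble with acceptance min(1, exp(-ΔE));
    rejected probability mass stays on the diagonal.  Detailed balance against
    the Boltzmann weights makes the stationary vector proportional to
    exp(-E_total).
    """
    e, _ = _energies_keys(records)
    n = len(records)
    de = e[None, :] - e[:, None]
    acc = np.minimum(1.0, np.exp(-np.clip(de, 0.0, 700.0)))
    p = acc / n
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(p, 1.0 - p.sum(axis=1))
    return TransitionMatrix(p)


def contract(
    tm: TransitionMatrix,
    families: dict[str, ConfigurationFamily],
    energies: np.ndarray,
) -> TransitionMatrix:
    """Contract a structure-level transition matrix onto configurational families.

    Rows of member structures are combined with their Boltzmann weights
    (re-normalized within each family) and member columns are summed, which
    preserves the stationary distribution at the family level.
    """
    keys = list(families)
    w = _boltzmann_weights(np.asarray(energies, float))
    m = len(keys)
    p_small = np.zeros((m, m))
    for a, ka in enumerate(keys):
        idx_a = families[ka].members
        wa = w[idx_a]
        wa = wa / wa.sum()
        for b, kb in enumerate(keys):
            idx_b = families[kb].members
            p_small[a, b] = float(wa @ tm.p[np.ix_(idx_a, idx_b)].sum(axis=1))
    p_small /= p_small.sum(axis=1, keepdims=True)
    return TransitionMatrix(p_small, labels=keys)


def stationary(tm: TransitionMatrix, tol: float = 1e-9) -> np.ndarray:
    """Stationary row vector π with π P = π, normalized to Σπ = 1.

    For reducible chains the eigenvalue 1 is degenerate; a warning is issued
    and one valid stationary vector is returned.
    """
    p = tm.p
    evals, evecs = scipy.linalg.eig(p.T)
    close = np.isclose(evals, 1.0, atol=1e-8)
    if not close.any():
        raise ValueError("no eigenvalue 1: input is not a stochastic matrix")
    if close.sum() > 1:
        warnings.warn(
            "transition matrix is reducible; the stationary distribution is "
            "not unique", RuntimeWarning,
        )
    vec = np.real(evecs[:, np.argmax(close)])
    vec = np.abs(vec)
    pi = vec / vec.sum()
    if np.linalg.norm(pi @ p - pi) > max(tol, 1e-9) * 10:
        warnings.warn("stationary vector residual exceeds tolerance", RuntimeWarning)
    return pi
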