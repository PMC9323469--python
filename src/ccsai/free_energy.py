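"""Free energy estimation from alchemical trajectories.

Frame selection, the K x N reduced-potential matrix, a multistate Bennett
acceptance ratio (MBAR) solver with asymptotic uncertainties, a two-state
BAR bisection solver, overlap diagnostics, and thermodynamic-cycle
assembly of relative free energy differences.

Internally free energies are dimensionless (units of kB*T, anchored at
``f_0 = 0``); conversion to kcal/mol happens only at reporting, using the
sampling temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .molecular_model import ValidationError
from .sampling import KB, NonbondedOptions, Trajectory, potential_energy

__all__ = [
    "ReducedPotentialMatrix",
    "FreeEnergyResult",
    "CycleResult",
    "ConvergenceError",
    "select_frames",
    "reduced_potentials",
    "reduced_potentials_from_frames",
    "solve_mbar",
    "solve_bar",
    "overlap_matrix",
    "ddg_from_cycle",
    "propagate_error",
    "free_energy_report",
]

OVERLAP_WARN_THRESHOLD = 0.03


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


@dataclass
class ReducedPotentialMatrix:
    """Dimensionless reduced potentials u_kn = U(x_n; lambda_k)/(kB T)."""

    u: np.ndarray            # (K, N)
    counts: np.ndarray       # (K,) frames contributed by each state
    temperature: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.u.ndim != 2:
            raise ValidationError("u must be a K x N matrix")
        if len(self.counts) != self.u.shape[0]:
            raise ValidationError("counts length must equal K")
        if int(self.counts.sum()) != self.u.shape[1]:
            raise ValidationError("sum of counts must equal N")
        if not np.all(np.isfinite(self.u)):
            raise ValidationError("reduced potentials contain non-finite entries")

    @property
    def n_states(self) -> int:
        return self.u.shape[0]


@dataclass
class FreeEnergyResult:
    """Dimensionless per-state free energies, anchored at f_0 = 0."""

    f_k: np.ndarray
    uncertainties: np.ndarray    # (K, K) SE of f_j - f_i; zero diagonal
    converged: bool
    iterations: int
    temperature: float

    def delta_f(self, i: int = 0, j: int = -1) -> float:
        return float(self.f_k[j] - self.f_k[i])

    def delta_f_error(self, i: int = 0, j: int = -1) -> float:
        return float(self.uncertainties[i, j])

    def delta_g_kcal(self, i: int = 0, j: int = -1) -> float:
        return self.delta_f(i, j) * KB * self.temperature

    def delta_g_error_kcal(self, i: int = 0, j: int = -1) -> float:
        return self.delta_f_error(i, j) * KB * self.temperature


@dataclass(frozen=True)
class CycleResult:
    """Relative free energy difference assembled from a thermodynamic cycle."""

    ddg: float               # kcal/mol
    sd: float                # kcal/mol
    legs: dict               # {"vac_a": (dg, sd), ...}


def select_frames(n_total: int, discard_fraction: float = 0.25,
                  stride: int = 3) -> np.ndarray:
    """Equilibration/subsampling rule: drop the first
    ``floor(discard_fraction * n_total)`` frames, then keep every
    ``stride``-th of the remainder starting from its first frame."""
    if not (0.0 <= discard_fraction < 1.0):
        raise ValidationError("discard_fraction must be in [0, 1)")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    start = int(math.floor(discard_fraction * n_total))
    idx = np.arange(start, n_total, stride)
    if idx.size == 0:
        raise ValidationError(
            f"empty frame selection (n_total={n_total}, "
            f"discard={discard_fraction}, stride={stride})"
        )
    return idx


def reduced_potentials(trajectories: Sequence[Trajectory],
                       states: Sequence,
                       opts: NonbondedOptions,
                       temperature: float) -> ReducedPotentialMatrix:
    """Evaluate every frame of every trajectory under all K parameter sets."""
    if len(trajectories) != len(states):
        raise ValidationError(
            f"{len(trajectories)} trajectories for {len(states)} states")
    counts = [t.n_frames for t in trajectories]
    frames = np.concatenate([t.frames for t in trajectories], axis=0)
    return reduced_potentials_from_frames(frames, counts, states, opts,
                                          temperature)


def reduced_potentials_from_frames(frames: np.ndarray, counts,
                                   states: Sequence,
                                   opts: NonbondedOptions,
                                   temperature: float) -> ReducedPotentialMatrix:
    """Merged-trajectory evaluation mode: one concatenated frame array
    evaluated under all states.  Identical to per-trajectory evaluation."""
    beta = 1.0 / (KB * temperature)
    frames = np.asarray(frames, dtype=float)
    counts = np.asarray(counts, dtype=int)
    if frames.shape[0] != int(counts.sum()):
        raise ValidationError("frame count does not match counts")
    u = np.empty((len(states), frames.shape[0]), dtype=float)
    for k, state in enumerate(states):
        system = getattr(state, "system", state)
        if frames.shape[1] != system.n_atoms:
            raise ValidationError(
                f"frames carry {frames.shape[1]} atoms but state {k} "
                f"({system.label!r}) has {system.n_atoms}"
            )
        for n in range(frames.shape[0]):
            u[k, n] = beta * potential_energy(state, frames[n], opts)
    return ReducedPotentialMatrix(u=u, counts=counts, temperature=temperature)


# ---------------------------------------------------------------------------
# MBAR


def _mbar_weights(u: np.ndarray, f: np.ndarray, counts: np.ndarray):
    """log W_nk with sum_n W_nk = 1 and sum_k N_k W_nk = 1 at the solution."""
    log_n = np.log(counts)
    # log D_n = logsumexp_k (log N_k + f_k - u_kn)
    log_d = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
    return f[:, None] - u - log_d[None, :]


def solve_mbar(m: ReducedPotentialMatrix, tolerance: float = 1e-8,
               max_iterations: int = 10000) -> FreeEnergyResult:
    """Solve the MBAR self-consistent equations.

    Self-consistent iteration with an adaptive switch to Newton-Raphson
    steps on the gradient once the iterate is close; raises
    :class:`ConvergenceError` carrying the residual if ``max_iterations``
    is exhausted.  Uncertainties come from the asymptotic covariance of the
    estimator (SVD form, uncorrelated-sample approximation).
    """
    u = m.u
    counts = m.counts.astype(float)
    if np.any(counts <= 0):
        raise ValidationError("every state must contribute frames (N_k > 0)")
    K, N = u.shape
    f = np.zeros(K)
    log_n = np.log(counts)

    def scf_update(f):
        log_d = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_d[None, :], axis=1)
        return f_new - f_new[0]

    def gradient_and_hessian(f):
        log_w = _mbar_weights(u, f, m.counts)
        w = np.exp(log_w)                      # (K, N)
        col = w.sum(axis=1)                    # sum_n W_nk
        g = counts * (col - 1.0)
        h = -np.outer(counts, counts) * (w @ w.T)
        h[np.diag_indices(K)] += counts * col
        return g, h

    converged = False
    iteration = 0
    residual = math.inf
    newton = False
    while iteration < max_iterations:
        iteration += 1
        if newton:
            g, h = gradient_and_hessian(f)
            try:
                delta = np.linalg.solve(h[1:, 1:], -g[1:])
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(h[1:, 1:], -g[1:], rcond=None)[0]
            f_new = f.copy()
            f_new[1:] += delta
            f_new -= f_new[0]
            if not np.all(np.isfinite(f_new)):
                newton = False
                continue
        else:
            f_new = scf_update(f)
        prev_residual = residual
        residual = float(np.max(np.abs(f_new - f)))
        scale = 1.0 + float(np.max(np.abs(f_new)))
        f = f_new
        if residual < tolerance * scale:
            converged = True
            break
        if newton and residual >= prev_residual:
            # Newton step stopped helping (oscillation near the fixed
            # point); fall back to the contraction mapping
            newton = False
        elif not newton and residual < 1e-2 * scale:
            newton = True
    if not converged:
        raise ConvergenceError(
            f"MBAR failed to converge in {max_iterations} iterations", residual)

    # asymptotic covariance: Theta = V S (I - S V^T diag(N) V S)^+ S V^T
    w = np.exp(_mbar_weights(u, f, m.counts))
    wtw = w @ w.T
    evals, vecs = np.linalg.eigh(wtw)
    keep = evals > 1e-12 * evals.max()
    s = np.sqrt(evals[keep])
    v = vecs[:, keep]
    inner = np.eye(len(s)) - (s[:, None] * v.T) @ np.diag(counts) @ (v * s)
    theta = (v * s) @ np.linalg.pinv(inner, rcond=1e-10, hermitian=True) @ (s[:, None] * v.T)
    d = np.diag(theta)
    var = d[:, None] + d[None, :] - 2.0 * theta
    uncertainties = np.sqrt(np.clip(var, 0.0, None))
    np.fill_diagonal(uncertainties, 0.0)

    return FreeEnergyResult(f_k=f, uncertainties=uncertainties,
                            converged=True, iterations=iteration,
                            temperature=m.temperature)


def solve_bar(w_forward: np.ndarray, w_reverse: np.ndarray,
              tolerance: float = 1e-12, max_iterations: int = 10000) -> float:
    """Two-state Bennett acceptance ratio by bisection.

    ``w_forward``: u_1(x) - u_0(x) for frames drawn from state 0;
    ``w_reverse``: u_0(x) - u_1(x) for frames drawn from state 1.
    Returns the dimensionless free energy difference f_1 - f_0.
    """
    w_f = np.asarray(w_forward, dtype=float)
    w_r = np.asarray(w_reverse, dtype=float)
    n_f, n_r = len(w_f), len(w_r)
    if n_f == 0 or n_r == 0:
        raise ValidationError("both directions need at least one sample")
    log_ratio = math.log(n_f / n_r)

    def implicit(df):
        # sum of Fermi functions: zero at the BAR solution
        lhs = logsumexp(-np.logaddexp(0.0, log_ratio + w_f - df))
        rhs = logsumexp(-np.logaddexp(0.0, -log_ratio + w_r + df))
        return lhs - rhs

    lo = float(min(np.min(w_f), -np.max(w_r))) - 50.0
    hi = float(max(np.max(w_f), -np.min(w_r))) + 50.0
    f_lo, f_hi = implicit(lo), implicit(hi)
    if f_lo * f_hi > 0:
        raise ConvergenceError("BAR bisection failed to bracket the root",
                               min(abs(f_lo), abs(f_hi)))
    for _ in range(max_iterations):
        mid = 0.5 * (lo + hi)
        f_mid = implicit(mid)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < tolerance:
            break
    return 0.5 * (lo + hi)


def overlap_matrix(m: ReducedPotentialMatrix,
                   result: FreeEnergyResult,
                   warn_threshold: float = OVERLAP_WARN_THRESHOLD) -> np.ndarray:
    """Row-stochastic K x K configuration-space overlap matrix.

    Warns (never fails) when a nearest-neighbour entry falls below the
    threshold — low overlap between adjacent alchemical states signals an
    unreliable free energy estimate.
    """
    if not result.converged:
        raise ValidationError("overlap_matrix needs a converged result")
    w = np.exp(_mbar_weights(m.u, result.f_k, m.counts))
    o = (w @ w.T) * m.counts[None, :]
    for k in range(m.n_states - 1):
        if o[k, k + 1] < warn_threshold:
            warnings.warn(
                f"overlap between states {k} and {k + 1} is "
                f"{o[k, k + 1]:.4f} (< {warn_threshold})",
                RuntimeWarning, stacklevel=2)
    return o


# ---------------------------------------------------------------------------
# thermodynamic cycle


def propagate_error(sds: Sequence[float]) -> float:
    """Gaussian error propagation: square root of the sum of squares."""
    sds = [float(s) for s in sds]
    for s in sds:
        if s < 0:
            raise ValidationError(f"negative standard deviation {s}")
    return math.sqrt(math.fsum(s * s for s in sds))


def ddg_from_cycle(dg_vac_a, dg_solv_a, dg_vac_b, dg_solv_b) -> CycleResult:
    """Relative solvation free energy difference from the four cycle legs.

    Each argument is ``(dg, sd)`` in kcal/mol for the leg mutating the
    physical end-state into the common core in the named environment.  The
    convention is

        ddG(A -> B) = (dG_vac,B - dG_solv,B) - (dG_vac,A - dG_solv,A)

    which is antisymmetric under exchange of A and B; the standard
    deviation follows by Gaussian propagation.
    """
    legs = {
        "vac_a": tuple(map(float, dg_vac_a)),
        "solv_a": tuple(map(float, dg_solv_a)),
        "vac_b": tuple(map(float, dg_vac_b)),
        "solv_b": tuple(map(float, dg_solv_b)),
    }
    ddg = ((legs["vac_b"][0] - legs["solv_b"][0])
           - (legs["vac_a"][0] - legs["solv_a"][0]))
    sd = propagate_error([v[1] for v in legs.values()])
    return CycleResult(ddg=ddg, sd=sd, legs=legs)


def free_energy_report(result: FreeEnergyResult) -> "pandas.DataFrame":
    """Per-state table (state, f_k in kB*T, SE, accumulated kcal/mol)."""
    import pandas as pd

    k = np.arange(len(result.f_k))
    return pd.DataFrame({
        "state": k,
        "f_k": result.f_k,
        "se_f_k": result.uncertainties[0, :],
        "dg_kcal_mol": result.f_k * KB * result.temperature,
        "se_dg_kcal_mol": result.uncertainties[0, :] * KB * result.temperature,
    })
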