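"""Energy minimization and molecular dynamics.

Minimizers: steepest descent, Polak-Ribiere+ conjugate gradient, and L-BFGS,
all with backtracking Armijo line search, an RMS-gradient stopping criterion,
and a movable-atom mask (frozen atoms never move but always contribute to the
energy).  Dynamics: velocity-Verlet with Maxwell-Boltzmann initial velocities
and an optional Berendsen thermostat.  QuickOptimizer alternates short heated
dynamics with minimization and keeps the best conformation seen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .forcefield import AmberForceField
from .model import MolecularSystem

log = logging.getLogger(__name__)

__all__ = [
    "minimize_function",
    "sd_direction",
    "cg_direction",
    "make_lbfgs_direction",
    "MinimizerOptions",
    "MinimizerResult",
    "MDOptions",
    "MDResult",
    "minimize_steepest_descent",
    "minimize_conjugate_gradient",
    "minimize_lbfgs",
    "run_md",
    "quick_optimize",
    "compute_temperature",
    "KB",
    "MD_ACC",
]

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041
#: (kcal/mol/A) / amu  ->  A/fs^2
MD_ACC = 4.184e-4


@dataclass
class MinimizerOptions:
    max_iterations: int = 1000
    grad_tolerance: float = 0.1          # RMS gradient, kcal/mol/A
    energy_output_frequency: int = 10
    armijo_c1: float = 1e-4
    backtrack_factor: float = 0.5
    initial_step: float = 1.0            # A along the unit direction
    max_backtracks: int = 30
    lbfgs_memory: int = 5
    line_search: str = "armijo"          # or "exact" (exact on quadratics)

    def __post_init__(self):
        if self.max_iterations < 0 or self.grad_tolerance <= 0:
            raise ValueError("minimizer options must be positive")
        if self.energy_output_frequency < 1:
            raise ValueError("energy output frequency must be >= 1")


@dataclass
class MinimizerResult:
    final_energy: float
    iterations: int
    converged: bool
    energy_trace: list[tuple[int, float, float]] = field(default_factory=list)
    final_rms_gradient: float = float("nan")
    reason: str = ""


@dataclass
class MDOptions:
    timestep: float = 1.0    # fs
    steps: int = 100
    temperature: float = 300.0
    thermostat: str = "none"          # or "berendsen"
    tau: float = 0.1                  # ps, Berendsen coupling time
    seed: int = 0
    sample_frequency: int = 10

    def __post_init__(self):
        if self.timestep <= 0 or self.temperature < 0:
            raise ValueError("bad MD options")
        if self.thermostat not in ("none", "berendsen"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")


@dataclass
class MDResult:
    steps: int
    energies: list[tuple[int, float, float, float]] = field(default_factory=list)
    # (step, potential, kinetic, temperature)
    final_velocities: Optional[np.ndarray] = None


def _rms(g: np.ndarray) -> float:
    return float(np.sqrt(np.mean(g * g))) if g.size else 0.0


class _Objective:
    """Energy/gradient over the movable subspace of a force field."""

    def __init__(self, ff: AmberForceField, movable: Optional[np.ndarray] = None):
        self.ff = ff
        self.coords = np.array([a.position for a in ff.lists.atoms])
        mask = ff.movable_mask() if movable is None else np.asarray(movable, bool)
        self.movable = mask
        self.idx = np.nonzero(mask)[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[self.idx].ravel().copy()

    def set_x(self, x: np.ndarray):
        self.coords[self.idx] = x.reshape(-1, 3)

    def energy(self, x: np.ndarray) -> float:
        c = self.coords.copy()
        c[self.idx] = x.reshape(-1, 3)
        return self.ff.energy(c).total

    def gradient(self, x: np.ndarray) -> np.ndarray:
        c = self.coords.copy()
        c[self.idx] = x.reshape(-1, 3)
        return self.ff.gradient(c)[self.idx].ravel()

    def write_back(self):
        for atom, row in zip(self.ff.lists.atoms, self.coords):
            atom.position = row.copy()


def _line_search(energy_fn, gradient_fn, x, e0, g, d, opts: MinimizerOptions):
    """Returns (alpha, new_e) or (None, e0) on failure."""
    slope = float(np.dot(g, d))
    if slope >= 0:
        return None, e0
    dn = float(np.linalg.norm(d))
    if dn == 0:
        return None, e0
    if opts.line_search == "exact":
        # exact for quadratics: alpha = -g.d / d.H.d with H.d from a gradient
        # difference (the gradient of a quadratic is linear, so this is exact)
        eps = 1e-3 / dn
        hd = (gradient_fn(x + eps * d) - g) / eps
        curv = float(np.dot(d, hd))
        if curv > 0:
            alpha = -slope / curv
            e = energy_fn(x + alpha * d)
            if e <= e0:
                return alpha, e
        # fall through to backtracking on non-quadratic surprises
    alpha = opts.initial_step / dn
    for _ in range(opts.max_backtracks):
        e = energy_fn(x + alpha * d)
        if e <= e0 + opts.armijo_c1 * alpha * slope:
            return alpha, e
        alpha *= opts.backtrack_factor
    return None, e0


def minimize_function(energy_fn, gradient_fn, x0: np.ndarray,
                      direction_fn, opts: MinimizerOptions) -> tuple[np.ndarray, MinimizerResult]:
    """Low-level minimizer loop over a plain objective.

    *direction_fn(g, state)* returns the search direction; state carries the
    (s, y, g_prev, d_prev) history between iterations.
    """
    x = np.asarray(x0, dtype=float).copy()
    e = energy_fn(x)
    g = gradient_fn(x)
    trace = [(0, e, _rms(g))]
    result = MinimizerResult(e, 0, False, trace, _rms(g))
    state: dict = {}
    for it in range(1, opts.max_iterations + 1):
        rms = _rms(g)
        if rms <= opts.grad_tolerance:
            result.converged = True
            result.reason = "gradient tolerance reached"
            break
        d = direction_fn(g, state)
        alpha, e_new = _line_search(energy_fn, gradient_fn, x, e, g, d, opts)
        if alpha is None and state.get("dirty"):
            # restart from steepest descent once before giving up
            state.clear()
            d = -g
            alpha, e_new = _line_search(energy_fn, gradient_fn, x, e, g, d, opts)
        if alpha is None:
            result.reason = "line search failed"
            result.iterations = it - 1
            break
        x_new = x + alpha * d
        g_new = gradient_fn(x_new)
        state["s"] = x_new - x
        state["y"] = g_new - g
        state["g_prev"] = g
        state["d_prev"] = d
        x, e, g = x_new, e_new, g_new
        result.iterations = it
        if it % opts.energy_output_frequency == 0:
            trace.append((it, e, _rms(g)))
            log.info("iter %d E= %.6f kcal/mol RMSgrad= %.6f", it, e, _rms(g))
    else:
        result.reason = "iteration limit"
    rms = _rms(g)
    if rms <= opts.grad_tolerance:
        result.converged = True
        result.reason = result.reason or "gradient tolerance reached"
    if trace[-1][0] != result.iterations:
        trace.append((result.iterations, e, rms))
    result.final_energy = e
    result.final_rms_gradient = rms
    return x, result


def _minimize(system: MolecularSystem, ff: AmberForceField,
              opts: MinimizerOptions, direction_fn) -> MinimizerResult:
    obj = _Objective(ff)
    if not obj.idx.size:
        raise ValueError("no movable atoms")
    x, result = minimize_function(obj.energy, obj.gradient, obj.x,
                                  direction_fn, opts)
    obj.set_x(x)
    obj.write_back()
    return result


def sd_direction(g, state):
    """Steepest-descent direction."""
    return -g


def cg_direction(g, state):
    """Polak-Ribiere+ direction with restart every 3N steps / on non-descent."""
    n = g.size
    count = state.get("count", 0)
    d_prev = state.get("d_prev")
    g_prev = state.get("g_prev")
    if d_prev is None or count >= 3 * n:
        state["count"] = 1
        state["dirty"] = False
        return -g
    beta = max(0.0, float(np.dot(g, g - g_prev) / np.dot(g_prev, g_prev)))
    d = -g + beta * d_prev
    if np.dot(d, g) >= 0:  # not a descent direction: restart
        state["count"] = 1
        return -g
    state["count"] = count + 1
    state["dirty"] = True
    return d


def make_lbfgs_direction(memory: int = 5):
    """L-BFGS two-loop-recursion direction with the given memory."""

    def direction(g, state):
        pairs = state.setdefault("pairs", [])
        s, y = state.get("s"), state.get("y")
        if s is not None:
            sy = float(np.dot(s, y))
            if sy > 1e-10:  # curvature condition; skip degenerate pairs
                pairs.append((s, y, 1.0 / sy))
                if len(pairs) > memory:
                    pairs.pop(0)
            state["s"] = None
        q = g.copy()
        alphas = []
        for s_i, y_i, rho_i in reversed(pairs):
            a_i = rho_i * float(np.dot(s_i, q))
            alphas.append(a_i)
            q -= a_i * y_i
        if pairs:
            s_l, y_l, _ = pairs[-1]
            gamma = float(np.dot(s_l, y_l) / np.dot(y_l, y_l))
            q *= gamma
        for (s_i, y_i, rho_i), a_i in zip(pairs, reversed(alphas)):
            b_i = rho_i * float(np.dot(y_i, q))
            q += (a_i - b_i) * s_i
        d = -q
        if np.dot(d, g) >= 0:
            state["pairs"] = []
            return -g
        state["dirty"] = bool(pairs)
        return d

    return direction


def minimize_steepest_descent(system: MolecularSystem, ff: AmberForceField,
                              opts: Optional[MinimizerOptions] = None) -> MinimizerResult:
    """x <- x - alpha g with backtracking Armijo line search."""
    return _minimize(system, ff, opts or MinimizerOptions(), sd_direction)


def minimize_conjugate_gradient(system: MolecularSystem, ff: AmberForceField,
                                opts: Optional[MinimizerOptions] = None) -> MinimizerResult:
    """Polak-Ribiere+ conjugate gradient with periodic restarts."""
    return _minimize(system, ff, opts or MinimizerOptions(), cg_direction)


def minimize_lbfgs(system: MolecularSystem, ff: AmberForceField,
                   opts: Optional[MinimizerOptions] = None) -> MinimizerResult:
    """Limited-memory BFGS (two-loop recursion, memory m)."""
    opts = opts or MinimizerOptions()
    return _minimize(system, ff, opts, make_lbfgs_direction(opts.lbfgs_memory))


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """(N, 3) velocities in A/fs drawn at *temperature* K."""
    sigma = np.sqrt(KB * temperature * MD_ACC / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def compute_temperature(masses: np.ndarray, velocities: np.ndarray,
                        movable: Optional[np.ndarray] = None) -> float:
    """T = 2 KE / (3 N_movable k_B); velocities in A/fs, masses in amu."""
    if movable is not None:
        masses = masses[movable]
        velocities = velocities[movable]
    n = len(masses)
    if n == 0:
        raise ValueError("no movable atoms with mass")
    ke = kinetic_energy(masses, velocities)
    return 2.0 * ke / (3.0 * n * KB)


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """KE in kcal/mol from velocities in A/fs."""
    return float(0.5 * np.sum(masses[:, None] * velocities ** 2) / MD_ACC)


def run_md(system: MolecularSystem, ff: AmberForceField,
           opts: Optional[MDOptions] = None,
           velocities: Optional[np.ndarray] = None) -> MDResult:
    """Velocity-Verlet integration of the movable atoms.

    Initial velocities are Maxwell-Boltzmann at ``opts.temperature`` from
    ``opts.seed`` unless given explicitly.  With the Berendsen thermostat,
    velocities are rescaled toward the target temperature each step.
    """
    opts = opts or MDOptions()
    obj = _Objective(ff)
    masses = ff.masses()
    movable = obj.movable
    idx = obj.idx
    if not idx.size:
        raise ValueError("no movable atoms")
    rng = np.random.default_rng(opts.seed)
    if velocities is None:
        velocities = np.zeros((len(masses), 3))
        velocities[idx] = maxwell_boltzmann_velocities(masses[idx],
                                                       opts.temperature, rng)
    v = velocities.astype(float).copy()
    coords = obj.coords
    dt = opts.timestep
    grad = ff.gradient(coords)
    acc = np.zeros_like(coords)
    acc[idx] = -grad[idx] * MD_ACC / masses[idx, None]
    result = MDResult(opts.steps)

    def sample(step):
        pot = ff.energy(coords).total
        ke = kinetic_energy(masses[idx], v[idx])
        t = 2.0 * ke / (3.0 * len(idx) * KB)
        result.energies.append((step, pot, ke, t))
        return pot

    sample(0)
    for step in range(1, opts.steps + 1):
        v[idx] += 0.5 * dt * acc[idx]
        coords[idx] += dt * v[idx]
        grad = ff.gradient(coords)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"nonfinite forces at MD step {step}")
        acc[idx] = -grad[idx] * MD_ACC / masses[idx, None]
        v[idx] += 0.5 * dt * acc[idx]
        if opts.thermostat == "berendsen" and opts.temperature > 0:
            t_now = compute_temperature(masses, v, movable)
            if t_now > 0:
                lam = math.sqrt(1.0 + dt / (opts.tau * 1000.0)
                                * (opts.temperature / t_now - 1.0))
                v[idx] *= lam
        if step % opts.sample_frequency == 0 or step == opts.steps:
            pot = sample(step)
            if not math.isfinite(pot):
                raise FloatingPointError(f"nonfinite energy at MD step {step}")
    obj.write_back()
    result.final_velocities = v
    return result


def quick_optimize(system: MolecularSystem, ff: AmberForceField,
                   rounds: int = 5, seed: int = 0,
                   min_opts: Optional[MinimizerOptions] = None) -> MinimizerResult:
    """Randomized MD/minimizer alternation keeping the best conformation.

    Each round: Maxwell-Boltzmann velocities at 300 K (seeded), 100 steps of
    1 fs dynamics, then conjugate-gradient minimization.  The lowest-energy
    conformation over all rounds (including the initial minimization) wins.
    """
    min_opts = min_opts or MinimizerOptions()
    best_result = minimize_conjugate_gradient(system, ff, min_opts)
    best_coords = np.array([a.position for a in ff.lists.atoms])
    rng = np.random.default_rng(seed)
    for _ in range(rounds):
        md_opts = MDOptions(timestep=1.0, steps=100, temperature=300.0,
                            seed=int(rng.integers(0, 2 ** 31)))
        run_md(system, ff, md_opts)
        res = minimize_conjugate_gradient(system, ff, min_opts)
        if res.final_energy < best_result.final_energy:
            best_result = res
            best_coords = np.array([a.position for a in ff.lists.atoms])
        else:
            for atom, row in zip(ff.lists.atoms, best_coords):
                atom.position = row.copy()
    for atom, row in zip(ff.lists.atoms, best_coords):
        atom.position = row.copy()
    return best_result
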