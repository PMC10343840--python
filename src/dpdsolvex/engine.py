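"""DPD equations of motion: force evaluation and time integration.

The total force on bead *i* is the pairwise sum of a soft conservative
repulsion ``a_ij (1 - r/r_cut) r_hat``, a dissipative drag
``-gamma w_D(r) (r_hat . v_ij) r_hat`` and a stochastic impulse
``sigma w_R(r) xi r_hat / sqrt(dt)``, all truncated at ``r_cut``, plus the
harmonic spring force ``C_S r_ij`` between bonded beads.  The standard
weight functions ``w_R = 1 - r/r_cut`` and ``w_D = w_R^2`` satisfy the
fluctuation-dissipation relation with ``sigma^2 = 2 gamma kT``, so the pair
thermostat holds the system at kT = 1.

Time integration uses the modified velocity-Verlet scheme with velocity
prediction factor ``lambda`` (default 0.65): velocities entering the
dissipative force of the new step are predicted as ``v + lambda dt f``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .model import InteractionModel
from .state import SystemState, minimum_image


@dataclass
class ForceBreakdown:
    """Per-bead force components, mainly for diagnostics and testing."""

    conservative: np.ndarray
    dissipative: np.ndarray
    random: np.ndarray
    spring: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.conservative + self.dissipative + self.random + self.spring


@dataclass
class EngineInfo:
    """Side quantities of one force evaluation."""

    virial_pair: float
    virial_spring: float
    n_overlap: int


def conservative_force(r_vec: np.ndarray, a_ij: float,
                       r_cut: float = 1.0) -> np.ndarray:
    """Soft repulsion ``a_ij (1 - r/r_cut) r_hat`` for one minimum-image
    displacement; zero at and beyond the cutoff, zero at exact overlap."""
    r = float(np.linalg.norm(r_vec))
    if r >= r_cut or r < 1e-12:
        return np.zeros(3)
    return a_ij * (1.0 - r / r_cut) * (np.asarray(r_vec) / r)


def dissipative_random_forces(r_vec: np.ndarray, v_rel: np.ndarray,
                              gamma: float, sigma: float, dt: float,
                              xi: float, r_cut: float = 1.0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise thermostat forces for one pair; ``xi`` is the standard-normal
    variate of the pair for this step."""
    r = float(np.linalg.norm(r_vec))
    if r >= r_cut or r < 1e-12:
        return np.zeros(3), np.zeros(3)
    e = np.asarray(r_vec) / r
    w_r = 1.0 - r / r_cut
    f_d = -gamma * w_r * w_r * float(e @ np.asarray(v_rel)) * e
    f_r = sigma * w_r * xi / np.sqrt(dt) * e
    return f_d, f_r


def spring_force(r_vec: np.ndarray, c_spring: float) -> np.ndarray:
    """Harmonic spring with zero equilibrium length: ``C_S r_vec`` pulls the
    bead toward its bonded partner at displacement ``r_vec``."""
    return c_spring * np.asarray(r_vec, dtype=float)


def _sorted_pairs(positions: np.ndarray, box: float, r_cut: float,
                  brute_force: bool) -> tuple[np.ndarray, np.ndarray]:
    if brute_force:
        return _kernels.brute_pairs(positions, box, r_cut)
    return _kernels.cell_pairs(positions, box, r_cut)  # sorted internally


def compute_forces(state: SystemState, model: InteractionModel, seed: int,
                   counter: int | None = None, velocities: np.ndarray | None = None,
                   brute_force: bool = False) -> tuple[np.ndarray, EngineInfo]:
    """Evaluate the full force array at the current positions.

    ``counter`` indexes the stochastic-force stream (defaults to the state's
    step counter); ``velocities`` may override the stored ones (the modified
    velocity-Verlet scheme feeds predicted velocities to the drag term).
    """
    if counter is None:
        counter = state.step
    vel = state.velocities if velocities is None else velocities
    pi, pj = _sorted_pairs(state.positions, state.box_edge, model.r_cut,
                           brute_force)
    forces = np.zeros_like(state.positions)
    virial_c, n_overlap = _kernels.accumulate_pair_forces(
        state.positions, vel, state.species, model.a_matrix,
        model.gamma, model.sigma, model.dt, state.box_edge, model.r_cut,
        np.uint64(seed), counter, pi, pj, forces)
    virial_s = 0.0
    if state.bonds.size:
        virial_s = _kernels.accumulate_spring_forces(
            state.positions, state.bonds, model.spring_constant,
            state.box_edge, forces)
    state.overlap_count += int(n_overlap)
    return forces, EngineInfo(float(virial_c), float(virial_s), int(n_overlap))


def force_breakdown(state: SystemState, model: InteractionModel, seed: int,
                    counter: int | None = None,
                    brute_force: bool = True) -> ForceBreakdown:
    """Separate conservative / dissipative / random / spring force arrays."""
    if counter is None:
        counter = state.step
    pi, pj = _sorted_pairs(state.positions, state.box_edge, model.r_cut,
                           brute_force)
    f_c = np.zeros_like(state.positions)
    f_d = np.zeros_like(state.positions)
    f_r = np.zeros_like(state.positions)
    f_s = np.zeros_like(state.positions)
    _kernels.pair_force_components(
        state.positions, state.velocities, state.species, model.a_matrix,
        model.gamma, model.sigma, model.dt, state.box_edge, model.r_cut,
        np.uint64(seed), counter, pi, pj, f_c, f_d, f_r)
    if state.bonds.size:
        _kernels.accumulate_spring_forces(
            state.positions, state.bonds, model.spring_constant,
            state.box_edge, f_s)
    return ForceBreakdown(f_c, f_d, f_r, f_s)


def _ensure_forces(state: SystemState, model: InteractionModel,
                   seed: int) -> None:
    if state.forces is None:
        state.forces, _ = compute_forces(state, model, seed,
                                         counter=state.step)


def step(state: SystemState, model: InteractionModel, seed: int,
         brute_force: bool = False) -> SystemState:
    """Advance one time step in place (modified velocity-Verlet).

    The stochastic stream of the new force evaluation is indexed by the new
    step number, so a restart from a checkpoint (which stores the cached
    forces) continues the identical trajectory.
    """
    _ensure_forces(state, model, seed)
    dt = model.dt
    f_old = state.forces
    v_old = state.velocities
    v_pred = v_old + model.lambda_vv * dt * f_old
    state.positions += dt * v_old + 0.5 * dt * dt * f_old
    if not np.isfinite(state.positions).all():
        raise FloatingPointError(
            f"non-finite coordinates at step {state.step + 1}")
    state.wrap()
    f_new, _ = compute_forces(state, model, seed, counter=state.step + 1,
                              velocities=v_pred, brute_force=brute_force)
    state.velocities = v_old + 0.5 * dt * (f_old + f_new)
    state.forces = f_new
    state.step += 1
    if not np.isfinite(state.velocities).all():
        raise FloatingPointError(
            f"non-finite velocities at step {state.step}")
    return state


Observer = tuple[int, Callable[[SystemState], None]]


def run(state: SystemState, model: InteractionModel, n_steps: int, seed: int,
        observers: Sequence[Observer] = ()) -> SystemState:
    """Apply ``step`` ``n_steps`` times, invoking each observer at its stride.

    Observers are ``(stride, callable)`` pairs called on entry and whenever
    the absolute step counter is a stride multiple.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    for _, obs in observers:
        obs(state)
    for _ in range(n_steps):
        step(state, model, seed)
        for stride, obs in observers:
            if state.step % stride == 0:
                obs(state)
    return state


def measure_pressure(state: SystemState, model: InteractionModel,
                     seed: int) -> float:
    """Instantaneous virial pressure, P = rho kT_kin + virial / (3 V).

    Only the conservative and spring contributions enter the virial; the
    thermostat pair forces average to zero.
    """
    _, info = compute_forces(state, model, seed, counter=state.step)
    volume = state.box_edge ** 3
    rho = state.n_beads / volume
    ideal = rho * state.kinetic_temperature()
    return ideal + (info.virial_pair + info.virial_spring) / (3.0 * volume)


def unwrap_bond_vectors(state: SystemState) -> np.ndarray:
    """Minimum-image displacement vectors of all bonds, one row per bond."""
    disp = (state.positions[state.bonds[:, 1]] -
            state.positions[state.bonds[:, 0]])
    return minimum_image(disp, state.box_edge)
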