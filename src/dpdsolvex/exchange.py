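"""Dialysis-mimicking solvent exchange: staged relabelling of cosolvent (G)
beads to water (W) beads.

Each exchange round relabels at most ``n_G_sup`` G beads (by default 1.25 %
of the total solvent beads) chosen uniformly among the *eligible* G beads —
those farther than the eligibility distance from every copolymer bead, i.e.
outside the aggregates.  If the eligible count ``n_G_out`` does not exceed
twice the quota, only ``floor(0.5 n_G_out)`` beads are exchanged.  After each
round the system equilibrates for ``t_eq`` steps; the protocol terminates
once fewer than ``termination_threshold`` G beads remain, at which point the
trace cosolvent is relabelled in one final sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import engine
from .model import InteractionModel
from .state import G, SystemState, W

#: Solvent bead count of the reference (full-scale) scenario, used to scale
#: the termination threshold proportionally in reduced boxes.
REFERENCE_SOLVENT_BEADS = 634_000


@dataclass
class ExchangeProtocol:
    """Parameters of one dialysis run."""

    n_g_sup: int
    eligibility_distance: float = 1.0
    t_eq: int = 200_000
    termination_threshold: int = 200
    seed: int = 0
    stagnation_limit: int = 10

    def __post_init__(self) -> None:
        if self.n_g_sup < 1:
            raise ValueError("n_g_sup must be at least 1")
        if self.t_eq < 0 or self.termination_threshold < 0:
            raise ValueError("t_eq and termination_threshold must be >= 0")


@dataclass
class ExchangeRecord:
    """Ledger entry of one exchange round."""

    step: int
    n_g_out: int
    n_g_ex: int
    phi_w_after: float
    exchanged: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))


def protocol_for_state(state: SystemState, quota_percent: float = 1.25,
                       eligibility_distance: float = 1.0,
                       t_eq: int = 200_000, seed: int = 0,
                       base_termination: int = 200) -> ExchangeProtocol:
    """Protocol with the quota and termination threshold scaled to the box.

    The quota is ``quota_percent`` of the *total* solvent beads; the
    termination threshold scales with the solvent count relative to the
    full-size scenario (floor of 2) so reduced boxes terminate at the same
    relative trace amount.
    """
    counts = state.species_counts()
    n_solvent = int(counts[W] + counts[G])
    if n_solvent == 0:
        raise ValueError("state holds no solvent beads")
    threshold = max(2, math.ceil(base_termination * n_solvent
                                 / REFERENCE_SOLVENT_BEADS))
    return ExchangeProtocol(
        n_g_sup=max(1, int(round(quota_percent / 100.0 * n_solvent))),
        eligibility_distance=eligibility_distance,
        t_eq=t_eq, termination_threshold=threshold, seed=seed)


def phi_w(state: SystemState) -> float:
    """Water percentage of the solvent, n_W / (n_W + n_G) x 100."""
    counts = state.species_counts()
    n_w, n_g = int(counts[W]), int(counts[G])
    if n_w + n_g == 0:
        raise ValueError("state holds no solvent beads")
    return 100.0 * n_w / (n_w + n_g)


def eligible_g_indices(state: SystemState,
                       eligibility_distance: float) -> np.ndarray:
    """Indices of G beads farther than the eligibility distance from every
    copolymer bead (periodic minimum image)."""
    g_idx = np.flatnonzero(state.species == G)
    poly = state.chain_of >= 0
    if not poly.any() or g_idx.size == 0:
        return g_idx
    box = state.box_edge
    tree = cKDTree(np.mod(state.positions[poly], box), boxsize=box)
    d, _ = tree.query(np.mod(state.positions[g_idx], box), k=1)
    return g_idx[d > eligibility_distance]


def count_eligible_g(state: SystemState, eligibility_distance: float) -> int:
    return int(eligible_g_indices(state, eligibility_distance).size)


def exchange_quota(n_g_out: int, n_g_sup: int) -> int:
    """Number of beads to exchange this round: the full quota when eligible
    beads are plentiful (n_G,out > 2 n_G,sup), else floor(0.5 n_G,out)."""
    if n_g_out < 0 or n_g_sup < 0:
        raise ValueError("counts must be non-negative")
    if n_g_out > 2 * n_g_sup:
        return n_g_sup
    return n_g_out // 2


def apply_exchange(state: SystemState, quota: int, eligible: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Relabel ``quota`` uniformly-sampled eligible G beads to W, in place.

    Positions, velocities and bonds are untouched (identity swap only);
    cached forces are invalidated because species changed.  Returns the
    relabelled bead indices.
    """
    if quota > eligible.size:
        raise ValueError("quota exceeds the eligible bead count")
    if quota == 0:
        return np.empty(0, dtype=np.int64)
    chosen = rng.choice(eligible, size=quota, replace=False)
    if (state.species[chosen] != G).any():
        raise ValueError("eligible set contains non-G beads")
    state.species[chosen] = W
    state.forces = None
    return np.sort(chosen)


def run_dialysis(state: SystemState, model: InteractionModel,
                 protocol: ExchangeProtocol, engine_seed: int,
                 observers: Sequence[engine.Observer] = ()
                 ) -> tuple[SystemState, list[ExchangeRecord]]:
    """Loop {eligibility count -> quota -> exchange -> equilibrate} until
    fewer than the termination threshold of G beads remain, then relabel the
    trace cosolvent.  Returns the final state and the full exchange ledger."""
    rng = np.random.default_rng(protocol.seed)
    records: list[ExchangeRecord] = []
    stagnant = 0
    while int(np.count_nonzero(state.species == G)) >= protocol.termination_threshold:
        eligible = eligible_g_indices(state, protocol.eligibility_distance)
        quota = exchange_quota(eligible.size, protocol.n_g_sup)
        exchanged = apply_exchange(state, quota, eligible, rng)
        records.append(ExchangeRecord(
            step=state.step, n_g_out=int(eligible.size), n_g_ex=int(quota),
            phi_w_after=phi_w(state), exchanged=exchanged))
        if quota == 0:
            stagnant += 1
            if stagnant > protocol.stagnation_limit:
                raise RuntimeError(
                    f"exchange stagnated: quota was 0 for {stagnant} "
                    "consecutive rounds")
        else:
            stagnant = 0
        engine.run(state, model, protocol.t_eq, engine_seed, observers)
    # final sweep: switch the trace cosolvent
    trace = np.flatnonzero(state.species == G)
    if trace.size:
        state.species[trace] = W
        state.forces = None
    records.append(ExchangeRecord(
        step=state.step, n_g_out=int(trace.size), n_g_ex=int(trace.size),
        phi_w_after=phi_w(state), exchanged=trace))
    return state, records


def pre_equilibrate(state: SystemState, model: InteractionModel,
                    engine_seed: int, athermal_steps: int = 100_000,
                    equilibration_steps: int = 2_000_000,
                    observers: Sequence[engine.Observer] = ()) -> SystemState:
    """Two-stage preparation of a freshly built scenario: an athermal phase
    with every a_ij = 25 to homogenize the mixture, then the full interaction
    matrix for the main equilibration.  Positions are untouched at the
    switch; only forces are re-evaluated."""
    athermal = model.with_uniform_a(25.0)
    engine.run(state, athermal, athermal_steps, engine_seed, observers)
    state.forces = None  # matrix switch: same positions, new forces
    engine.run(state, model, equilibration_steps, engine_seed, observers)
    return state


def records_to_rows(records: Sequence[ExchangeRecord]) -> list[dict]:
    """Ledger rows for tabular (TSV) output."""
    return [{"step": r.step, "n_g_out": r.n_g_out, "n_g_ex": r.n_g_ex,
             "phi_w_after": r.phi_w_after} for r in records]
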