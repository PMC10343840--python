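"""Parameterization of the coarse-grained copolymer / binary-solvent system.

Four bead species are modelled: W, a selective solvent that is good for the
hydrophilic block only (water-like); G, a cosolvent that is good for both
blocks; A, the hydrophilic block; and B, the hydrophobic block.  The model
copolymer is the short-corona diblock A2B12.  Soft DPD repulsion amplitudes
``a_ij`` encode miscibility through the Groot-Warren linear mapping to the
Flory-Huggins parameter at reduced density 3:

    chi_ij = 0.286 * (a_ij - a_ii)

so ``a_BW = 50`` (chi = 7.15) makes B strongly hydrophobic, ``a_AB = 50``
makes the two blocks immiscible, and the single free knob ``a_WG`` tunes the
water-cosolvent affinity: 15 gives an attractive mixture (chi = -2.86, e.g.
DMSO/water) and 30 a marginally miscible one (chi = 1.43 < chi_crit = 2,
e.g. THF/water).
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .state import A, B, G, N_SPECIES, SPECIES_LABELS, W, SystemState

#: Slope of the Groot-Warren chi(a_ij) mapping at reduced bead density 3.
CHI_PER_DELTA_A = 0.286

#: Baseline like-bead repulsion amplitude at reduced density 3.
A_LIKE = 25.0


def chi_from_delta_a(delta_a: float) -> float:
    """Flory-Huggins parameter from the excess repulsion ``a_ij - a_ii``."""
    return CHI_PER_DELTA_A * delta_a


def chi_critical(n_a: float = 1.0, n_b: float = 1.0) -> float:
    """Critical Flory-Huggins parameter of a symmetric binary blend.

    ``chi_crit = (1/sqrt(N_A) + 1/sqrt(N_B))^2 / 2``; equals 2.0 for a blend
    of two monomeric species (``N_A = N_B = 1``), the relevant bound for the
    water/cosolvent pair.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("degrees of polymerization must be positive")
    return 0.5 * (n_a ** -0.5 + n_b ** -0.5) ** 2


@dataclass
class InteractionModel:
    """Force-field parameters in reduced DPD units (m = r_cut = kT = 1)."""

    a_matrix: np.ndarray
    spring_constant: float = 4.0
    gamma: float = 4.5
    sigma: float | None = None
    r_cut: float = 1.0
    kT: float = 1.0
    mass: float = 1.0
    dt: float = 0.05
    lambda_vv: float = 0.65  # velocity-prediction factor of the integrator

    def __post_init__(self) -> None:
        self.a_matrix = np.asarray(self.a_matrix, dtype=np.float64)
        if self.a_matrix.shape != (N_SPECIES, N_SPECIES):
            raise ValueError("a_matrix must be 4x4")
        if not np.allclose(self.a_matrix, self.a_matrix.T):
            raise ValueError("a_matrix must be symmetric")
        if self.sigma is None:
            # fluctuation-dissipation: sigma^2 = 2 gamma kT
            self.sigma = math.sqrt(2.0 * self.gamma * self.kT)

    def with_uniform_a(self, a: float = A_LIKE) -> "InteractionModel":
        """Copy of the model with every a_ij set to ``a`` (athermal mixing)."""
        return dataclasses.replace(self, a_matrix=np.full((N_SPECIES, N_SPECIES), a))

    def chi(self, i: int, j: int) -> float:
        """chi of a species pair via the Groot-Warren mapping."""
        return chi_from_delta_a(self.a_matrix[i, j] - A_LIKE)


def build_interaction_matrix(a_WG: float, **kwargs) -> InteractionModel:
    """Standard interaction matrix of the study: diagonals 25, a_BW = a_AB = 50,
    a_AW = a_AG = a_BG = 25, and the water-cosolvent amplitude as given."""
    if a_WG <= 0:
        raise ValueError("a_WG must be positive")
    m = np.full((N_SPECIES, N_SPECIES), A_LIKE)
    m[W, G] = m[G, W] = a_WG
    m[B, W] = m[W, B] = 50.0
    m[A, B] = m[B, A] = 50.0
    return InteractionModel(a_matrix=m, **kwargs)


@dataclass(frozen=True)
class ChainTopology:
    """Linear block sequence of one copolymer chain, e.g. A2B12."""

    blocks: tuple[tuple[int, int], ...] = ((A, 2), (B, 12))

    @property
    def n_beads(self) -> int:
        return sum(count for _, count in self.blocks)

    def species_sequence(self) -> np.ndarray:
        return np.concatenate(
            [np.full(count, sp, dtype=np.int8) for sp, count in self.blocks]
        )

    def local_bonds(self) -> np.ndarray:
        """Consecutive-bead bonds, indices local to one chain."""
        n = self.n_beads
        return np.column_stack([np.arange(n - 1), np.arange(1, n)])

    def __str__(self) -> str:
        return "".join(f"{SPECIES_LABELS[sp]}{count}" for sp, count in self.blocks)


def topology_from_string(text: str) -> ChainTopology:
    """Parse a block string such as ``"A2B12"`` into a topology."""
    parts = re.findall(r"([WGAB])(\d+)", text)
    if not parts or "".join(f"{s}{c}" for s, c in parts) != text:
        raise ValueError(f"cannot parse chain topology {text!r}")
    codes = {lab: i for i, lab in enumerate(SPECIES_LABELS)}
    return ChainTopology(tuple((codes[s], int(c)) for s, c in parts))


@dataclass
class ScenarioConfig:
    """One self-assembly scenario: geometry, composition and protocol knobs.

    Defaults reproduce the study conditions: a 60^3 periodic box at reduced
    density 3 (648,000 beads), 1000 A2B12 chains (~2.16 % copolymer volume
    fraction), dialysis quota 1.25 % of the solvent beads per exchange step,
    2e5-step equilibration between exchanges and termination once fewer than
    200 G beads remain.
    """

    box_edge: float = 60.0
    rho: float = 3.0
    n_chains: int = 1000
    topology: ChainTopology = field(default_factory=ChainTopology)
    a_WG: float = 15.0
    phi_w_init: float = 30.0
    quota_percent: float = 1.25
    eligibility_distance: float = 1.0
    t_eq: int = 200_000
    termination_threshold: int = 200
    pre_equilibration_steps: int = 100_000
    equilibration_steps: int = 2_000_000
    placement_seed: int = 0
    engine_seed: int = 1
    exchange_seed: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_w_init <= 100.0:
            raise ValueError("phi_w_init must lie in [0, 100]")
        if self.n_chains < 0 or self.rho <= 0 or self.box_edge <= 0:
            raise ValueError("geometry parameters must be positive")

    @property
    def n_beads_total(self) -> int:
        n = self.rho * self.box_edge ** 3
        if abs(n - round(n)) > 1e-6:
            raise ValueError("rho * box_edge^3 must be an integer bead count")
        return int(round(n))

    @property
    def n_polymer_beads(self) -> int:
        return self.n_chains * self.topology.n_beads

    @property
    def n_solvent_beads(self) -> int:
        n = self.n_beads_total - self.n_polymer_beads
        if n < 0:
            raise ValueError("more polymer beads than the box holds")
        return n

    @property
    def polymer_volume_fraction(self) -> float:
        """Copolymer bead fraction in percent (equal bead volumes)."""
        return 100.0 * self.n_polymer_beads / self.n_beads_total

    def solvent_split(self) -> tuple[int, int]:
        """(n_W, n_G) at phi_w_init; floor() applied to the W count."""
        n_w = int(math.floor(self.phi_w_init / 100.0 * self.n_solvent_beads))
        return n_w, self.n_solvent_beads - n_w

    def scaled(self, factor: float, n_chains: int | None = None,
               step_factor: float | None = None) -> "ScenarioConfig":
        """Scaled-down copy: box edge multiplied by ``factor`` (rho kept);
        chain count scaled with the volume unless given explicitly."""
        if step_factor is None:
            step_factor = factor
        return dataclasses.replace(
            self,
            box_edge=self.box_edge * factor,
            n_chains=(int(round(self.n_chains * factor ** 3))
                      if n_chains is None else n_chains),
            t_eq=max(1, int(round(self.t_eq * step_factor))),
            pre_equilibration_steps=max(
                1, int(round(self.pre_equilibration_steps * step_factor))),
            equilibration_steps=max(
                1, int(round(self.equilibration_steps * step_factor))),
        )


def make_scenario(config: ScenarioConfig) -> SystemState:
    """Build the initial random dispersion described by ``config``.

    Copolymer chains are placed as random walks with unit bond steps (the
    soft DPD potential tolerates overlap, so self-avoidance is not needed);
    solvent beads are uniform in the box with the W/G split given by
    ``phi_w_init``.  Velocities are Maxwellian with the total momentum
    removed and the kinetic temperature rescaled to exactly kT = 1.
    """
    rng = np.random.default_rng(config.placement_seed)
    n_total = config.n_beads_total
    n_chain_beads = config.topology.n_beads
    n_poly = config.n_polymer_beads
    n_w, n_g = config.solvent_split()
    if n_poly + n_w + n_g != n_total:
        raise RuntimeError("bead-count bookkeeping mismatch")

    box = config.box_edge
    positions = np.empty((n_total, 3))
    species = np.empty(n_total, dtype=np.int8)
    chain_of = np.full(n_total, -1, dtype=np.int64)

    # polymer: random walks, one chain per contiguous index range
    seq = config.topology.species_sequence()
    local = config.topology.local_bonds()
    bonds = np.empty((config.n_chains * (n_chain_beads - 1), 2), dtype=np.int64)
    for c in range(config.n_chains):
        start = c * n_chain_beads
        steps = rng.normal(size=(n_chain_beads - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        positions[start:start + n_chain_beads] = walk + rng.uniform(0, box, 3)
        species[start:start + n_chain_beads] = seq
        chain_of[start:start + n_chain_beads] = c
        bonds[c * (n_chain_beads - 1):(c + 1) * (n_chain_beads - 1)] = local + start

    # solvent: W beads first, then G, uniform positions
    positions[n_poly:] = rng.uniform(0, box, size=(n_total - n_poly, 3))
    species[n_poly:n_poly + n_w] = W
    species[n_poly + n_w:] = G

    velocities = rng.normal(size=(n_total, 3))
    velocities -= velocities.mean(axis=0)
    kin = np.square(velocities).sum() / (3.0 * n_total)
    velocities *= math.sqrt(1.0 / kin)

    state = SystemState(
        positions=positions, velocities=velocities, species=species,
        bonds=bonds, box_edge=box, chain_of=chain_of,
    )
    state.wrap()
    return state
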