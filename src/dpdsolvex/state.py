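"""Mutable bead-system state shared by the engine and the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer species codes used throughout the package.
W, G, A, B = 0, 1, 2, 3
SPECIES_LABELS = ("W", "G", "A", "B")
N_SPECIES = 4


@dataclass
class SystemState:
    """All per-bead data of one simulation system.

    Positions are reduced coordinates wrapped into ``[0, box_edge)``.
    ``chain_of`` maps each bead to its copolymer chain index, or ``-1`` for
    solvent beads.  ``forces`` caches the force evaluation of the current
    step so that a checkpointed run restarts bit-for-bit.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    bonds: np.ndarray
    box_edge: float
    chain_of: np.ndarray
    step: int = 0
    forces: np.ndarray | None = None
    overlap_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        if self.velocities.shape != (n, 3):
            raise ValueError("velocities shape mismatch")
        if self.species.shape != (n,) or self.chain_of.shape != (n,):
            raise ValueError("per-bead array shape mismatch")
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_of.max()) + 1 if (self.chain_of >= 0).any() else 0

    def species_counts(self) -> np.ndarray:
        return np.bincount(self.species, minlength=N_SPECIES)

    def wrap(self) -> None:
        np.mod(self.positions, self.box_edge, out=self.positions)

    def total_momentum(self) -> np.ndarray:
        # unit bead mass
        return self.velocities.sum(axis=0)

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature, sum(m v^2) / (3 N) with m = 1."""
        return float(np.square(self.velocities).sum() / (3.0 * self.n_beads))

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            bonds=self.bonds.copy(),
            box_edge=self.box_edge,
            chain_of=self.chain_of.copy(),
            step=self.step,
            forces=None if self.forces is None else self.forces.copy(),
            overlap_count=self.overlap_count,
        )


def minimum_image(disp: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image convention applied to a displacement array."""
    return disp - box_edge * np.round(disp / box_edge)
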