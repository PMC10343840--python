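"""Deterministic synthetic bead configurations with known topology.

These generators build idealized aggregates — solid spheres, hollow shells
(vesicle-like), punched shells, oblate disks, cylinders, well-mixed blobs
and uniform gases — whose shape and cavity structure are known by
construction.  They drive the morphology and solvation test oracles and the
classifier calibration; they emulate geometry only, not equilibrium DPD
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state import A, B, G, SystemState, W

FIXTURE_KINDS = ("solid-sphere", "hollow-shell", "shell-with-hole",
                 "oblate-disk", "cylinder", "mixed-blob", "uniform-gas")


@dataclass
class FixtureSpec:
    """Geometric recipe for one synthetic configuration."""

    kind: str
    radius: float = 4.0
    thickness: float = 1.0
    aspect: float = 5.0           # cylinder length / diameter; disk flattening
    hole_angle_deg: float = 50.0  # angular radius of the punched opening
    n_b: int = 1200
    n_a: int = 300
    n_w: int = 1500
    n_g: int = 0
    box_edge: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.radius <= 0 or self.thickness <= 0:
            raise ValueError("radius and thickness must be positive")
        if self.kind == "shell-with-hole" and not 0 < self.hole_angle_deg < 90:
            raise ValueError("hole angle must lie in (0, 90) degrees")


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    return _unit_vectors(rng, n) * radius * rng.uniform(0, 1, (n, 1)) ** (1 / 3)


def _shell(rng: np.random.Generator, n: int, radius: float,
           thickness: float) -> np.ndarray:
    r = rng.uniform(radius - thickness / 2, radius + thickness / 2, (n, 1))
    return _unit_vectors(rng, n) * r


def make_fixture(spec: FixtureSpec) -> SystemState:
    """Build the configuration described by ``spec``.

    Polymer beads (A, B) are registered as single-bead chains so the
    cluster machinery applies unchanged; there are no bonds.  Velocities
    are zero: fixtures are geometric objects, not dynamic states.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.kind
    R, t = spec.radius, spec.thickness
    box = spec.box_edge or max(6 * R, 4 * R * (spec.aspect if k == "cylinder"
                                               else 1.0) + 4)

    if k == "solid-sphere":
        b = _ball(rng, spec.n_b, R)
        a = _shell(rng, spec.n_a, R + 0.4, 0.4) if spec.n_a else np.empty((0, 3))
    elif k in ("hollow-shell", "shell-with-hole"):
        b = _shell(rng, spec.n_b, R, t)
        half = spec.n_a // 2
        a = np.vstack([
            _shell(rng, half, R - t / 2 - 0.3, 0.3),
            _shell(rng, spec.n_a - half, R + t / 2 + 0.3, 0.3),
        ]) if spec.n_a else np.empty((0, 3))
        if k == "shell-with-hole":
            cos_hole = np.cos(np.radians(spec.hole_angle_deg))
            for arr in (b,):
                keep = arr[:, 2] / np.linalg.norm(arr, axis=1) < cos_hole
                arr_kept = arr[keep]
                # resample dropped beads onto the remaining shell
                short = len(arr) - len(arr_kept)
                extra = []
                while short > 0:
                    cand = _shell(rng, 4 * short, R, t)
                    ok = cand[:, 2] / np.linalg.norm(cand, axis=1) < cos_hole
                    cand = cand[ok][:short]
                    extra.append(cand)
                    short -= len(cand)
                b = np.vstack([arr_kept] + extra)
            if spec.n_a:
                keep = a[:, 2] / np.linalg.norm(a, axis=1) < cos_hole
                a = a[keep]
    elif k == "oblate-disk":
        b = _ball(rng, spec.n_b, R)
        b[:, 2] /= spec.aspect
        a = np.empty((0, 3))
        if spec.n_a:
            a = _shell(rng, spec.n_a, R + 0.4, 0.4)
            a[:, 2] /= spec.aspect
    elif k == "cylinder":
        length = 2 * R * spec.aspect
        z = rng.uniform(-length / 2, length / 2, (spec.n_b, 1))
        rad = R * np.sqrt(rng.uniform(0, 1, (spec.n_b, 1)))
        phi = rng.uniform(0, 2 * np.pi, (spec.n_b, 1))
        b = np.hstack([rad * np.cos(phi), rad * np.sin(phi), z])
        a = np.empty((0, 3))
    elif k == "mixed-blob":
        b = _ball(rng, spec.n_b, R)
        a = _ball(rng, spec.n_a, R)
    else:  # uniform-gas
        b = rng.uniform(0, box, (spec.n_b, 3))
        a = rng.uniform(0, box, (spec.n_a, 3))

    if k == "mixed-blob":
        # solvent interleaved with the polymer inside the same sphere
        w = _ball(rng, spec.n_w, R)
        g = _ball(rng, spec.n_g, R) if spec.n_g else np.empty((0, 3))
    elif k in ("hollow-shell", "shell-with-hole"):
        n_in = spec.n_w // 2
        w = np.vstack([_ball(rng, n_in, R - t / 2 - 0.6),
                       rng.uniform(-box / 2, box / 2, (spec.n_w - n_in, 3))])
        g = (rng.uniform(-box / 2, box / 2, (spec.n_g, 3))
             if spec.n_g else np.empty((0, 3)))
    elif k == "uniform-gas":
        w = rng.uniform(0, box, (spec.n_w, 3))
        g = rng.uniform(0, box, (spec.n_g, 3))
    else:
        w = rng.uniform(-box / 2, box / 2, (spec.n_w, 3))
        g = (rng.uniform(-box / 2, box / 2, (spec.n_g, 3))
             if spec.n_g else np.empty((0, 3)))

    if k != "uniform-gas":
        center = np.full(3, box / 2)
        a, b, w, g = (arr + center for arr in (a, b, w, g))

    positions = np.vstack([a, b, w, g])
    species = np.concatenate([
        np.full(len(a), A, np.int8), np.full(len(b), B, np.int8),
        np.full(len(w), W, np.int8), np.full(len(g), G, np.int8)])
    n_poly = len(a) + len(b)
    chain_of = np.concatenate([
        np.arange(n_poly, dtype=np.int64),
        np.full(len(w) + len(g), -1, np.int64)])
    state = SystemState(
        positions=positions, velocities=np.zeros_like(positions),
        species=species, bonds=np.empty((0, 2), np.int64),
        box_edge=float(box), chain_of=chain_of)
    state.wrap()
    return state


def polymer_indices(state: SystemState) -> np.ndarray:
    """Bead indices of all polymer beads (the fixture's single aggregate)."""
    return np.flatnonzero(state.chain_of >= 0)
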