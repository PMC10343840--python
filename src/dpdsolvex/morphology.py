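"""Aggregate identification and shape / internal-structure analysis.

Aggregates are defined through hydrophobic contacts: two chains belong to
the same cluster when any of their B beads lie closer than 1.5 r_cut
(minimum image).  Cluster size is counted in chains (n_agg).  Shapes are
quantified by the gyration tensor

    S_ab = (1/n) sum_i (a_i - a_cm)(b_i - b_cm)

with sorted eigenvalues lambda_1 <= lambda_2 <= lambda_3, the ratios
r31 = l3/l1, r32 = l3/l2, r21 = l2/l1 and Rg^2 = l1 + l2 + l3.  Density
profiles, a lattice flood-fill cavity detector and a rule-based aggregate
classifier (micelle / disk / semi-vesicle / vesicle / LLPS-like) build on
these primitives.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .state import A, B, G, SystemState, W, minimum_image

#: Hydrophobic-contact criterion for cluster identification (strict <).
CLUSTER_CONTACT_CUTOFF = 1.5


@dataclass
class ClusterSet:
    """Partition of the copolymer chains into aggregates."""

    assignment: np.ndarray          # chain index -> cluster id
    n_agg: np.ndarray               # chains per cluster
    members: list[np.ndarray]       # bead indices per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def largest(self) -> int:
        """Cluster id of the largest aggregate (most chains)."""
        return int(np.argmax(self.n_agg))


@dataclass
class ShapeDescriptor:
    """Gyration-tensor summary of one aggregate."""

    tensor: np.ndarray
    eigenvalues: np.ndarray          # ascending
    r31: float
    r32: float
    r21: float
    rg2: float
    n: int
    degenerate: bool = False


@dataclass
class DensityProfile:
    """Per-species number density against a radial or axial coordinate."""

    mode: str                        # "radial" or "long-axis"
    bin_edges: np.ndarray
    density: np.ndarray              # (4, n_bins)
    counts: np.ndarray               # (4, n_bins)
    bin_volumes: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class CavityReport:
    """Closed solvent-accessible voids inside one aggregate."""

    count: int
    volumes: list[float]
    n_w_inside: list[int]
    n_g_inside: list[int]
    lattice_spacing: float

    @property
    def total_volume(self) -> float:
        return float(sum(self.volumes))


def find_clusters(state: SystemState,
                  contact_cutoff: float = CLUSTER_CONTACT_CUTOFF) -> ClusterSet:
    """Partition chains into aggregates via B-B contacts (< cutoff).

    Chains are atomic: a chain joins the component containing any of its
    hydrophobic beads; chains without such contacts form singleton clusters.
    Contacts between hydrophilic beads do not merge clusters.
    """
    n_chains = state.n_chains
    if n_chains == 0:
        return ClusterSet(np.empty(0, np.int64), np.empty(0, np.int64), [])
    box = state.box_edge
    b_idx = np.flatnonzero((state.species == B) & (state.chain_of >= 0))
    pos = np.mod(state.positions[b_idx], box)
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(r=contact_cutoff, output_type="ndarray")
    if pairs.size:
        # enforce the strict inequality of the contact criterion
        d = np.linalg.norm(
            minimum_image(pos[pairs[:, 0]] - pos[pairs[:, 1]], box), axis=1)
        pairs = pairs[d < contact_cutoff]
    ci = state.chain_of[b_idx[pairs[:, 0]]] if pairs.size else np.empty(0, int)
    cj = state.chain_of[b_idx[pairs[:, 1]]] if pairs.size else np.empty(0, int)
    graph = sparse.coo_matrix(
        (np.ones(ci.size), (ci, cj)), shape=(n_chains, n_chains))
    _, labels = connected_components(graph, directed=False)
    # relabel by first appearance for a deterministic, order-independent id
    _, assignment = np.unique(labels, return_inverse=True)
    n_clusters = int(assignment.max()) + 1
    n_agg = np.bincount(assignment, minlength=n_clusters)
    members: list[np.ndarray] = []
    chain_beads = np.flatnonzero(state.chain_of >= 0)
    bead_cluster = assignment[state.chain_of[chain_beads]]
    order = np.argsort(bead_cluster, kind="stable")
    bounds = np.searchsorted(bead_cluster[order], np.arange(n_clusters + 1))
    for c in range(n_clusters):
        members.append(chain_beads[order[bounds[c]:bounds[c + 1]]])
    return ClusterSet(assignment.astype(np.int64), n_agg.astype(np.int64),
                      members)


def unwrap_cluster(state: SystemState, bead_indices: np.ndarray,
                   contact_cutoff: float = CLUSTER_CONTACT_CUTOFF) -> np.ndarray:
    """Contiguous (unwrapped) coordinates of one cluster.

    A breadth-first search over the bead connectivity graph (bonds plus B-B
    contact pairs) places each bead at its minimum-image position relative
    to its parent, removing periodic-wrap jumps before any shape analysis.
    """
    bead_indices = np.asarray(bead_indices)
    n = bead_indices.size
    box = state.box_edge
    pos = np.mod(state.positions[bead_indices], box)
    local = {int(b): k for k, b in enumerate(bead_indices)}

    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in state.bonds:
        li, lj = local.get(int(i)), local.get(int(j))
        if li is not None and lj is not None:
            adj[li].append(lj)
            adj[lj].append(li)
    is_b = state.species[bead_indices] == B
    if is_b.any():
        bpos = pos[is_b]
        bmap = np.flatnonzero(is_b)
        tree = cKDTree(bpos, boxsize=box)
        for u, v in tree.query_pairs(r=contact_cutoff):
            adj[bmap[u]].append(bmap[v])
            adj[bmap[v]].append(bmap[u])

    out = pos.copy()
    seen = np.zeros(n, dtype=bool)
    for root in range(n):
        if seen[root]:
            continue
        seen[root] = True
        queue = deque([root])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    out[v] = out[u] + minimum_image(pos[v] - pos[u], box)
                    queue.append(v)
    return out


def gyration_descriptor(coords: np.ndarray,
                        box: float | None = None) -> ShapeDescriptor:
    """Gyration tensor, sorted eigenvalues and shape ratios of a point set.

    Coordinates must already be contiguous (unwrapped); pass ``box`` only as
    a guard that the spread does not exceed half the box.  Fewer than two
    points, or a vanishing smallest eigenvalue (collinear/coplanar sets),
    yield a descriptor flagged degenerate with infinite ratios.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        nan3 = np.full(3, np.nan)
        return ShapeDescriptor(np.full((3, 3), np.nan), nan3,
                               np.inf, np.inf, np.inf, 0.0, n, True)
    centred = coords - coords.mean(axis=0)
    tensor = centred.T @ centred / n
    eig = np.linalg.eigvalsh(tensor)
    eig = np.clip(eig, 0.0, None)
    l1, l2, l3 = eig
    rg2 = float(eig.sum())
    tiny = 1e-12 * max(rg2, 1.0)
    if l1 <= tiny:
        r31 = r21 = np.inf
        r32 = float(l3 / l2) if l2 > tiny else np.inf
        return ShapeDescriptor(tensor, eig, r31, r32, r21, rg2, n, True)
    return ShapeDescriptor(tensor, eig, float(l3 / l1), float(l3 / l2),
                           float(l2 / l1), rg2, n, False)


def long_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(center of mass, unit eigenvector of the largest eigenvalue)."""
    coords = np.asarray(coords, dtype=float)
    com = coords.mean(axis=0)
    centred = coords - com
    tensor = centred.T @ centred / coords.shape[0]
    _, vecs = np.linalg.eigh(tensor)
    return com, vecs[:, -1]


def classify_shape(desc: ShapeDescriptor, spheroid_threshold: float = 1.5,
                   flat_r21_threshold: float = 1.25) -> str:
    """Coarse shape label from the eigenvalue ratios.

    ``spheroidal`` when even the extreme ratio r31 stays below the spheroid
    threshold; otherwise ``flat-cylindrical`` when the two larger axes both
    clearly exceed the smallest (r21 above its threshold, the flattened
    ribbon/disk family), else ``elongated`` (prolate).  Degenerate
    descriptors are labelled ``degenerate``.
    """
    if desc.degenerate or not np.isfinite(desc.r31):
        return "degenerate"
    if desc.r31 <= spheroid_threshold:
        return "spheroidal"
    if desc.r21 >= flat_r21_threshold:
        return "flat-cylindrical"
    return "elongated"


def density_profile(state: SystemState, bead_indices: np.ndarray,
                    mode: str = "radial", n_bins: int = 30,
                    r_max: float | None = None,
                    slab_radius: float = 3.0) -> DensityProfile:
    """Number density of all four species around one aggregate.

    ``radial`` bins every bead of the box by its minimum-image distance from
    the cluster center of mass, in spherical shells.  ``long-axis`` projects
    onto the eigenvector of the largest gyration eigenvalue and bins in
    slabs, counting only beads within ``slab_radius`` of the axis (the slab
    volume is the corresponding cylinder section).  Empty bins report
    density zero.
    """
    if mode not in ("radial", "long-axis"):
        raise ValueError(f"unknown profile mode {mode!r}")
    box = state.box_edge
    coords = unwrap_cluster(state, bead_indices)
    com, axis = long_axis(coords)
    if r_max is None:
        r_max = box / 2.0
    disp = minimum_image(state.positions - com, box)
    edges = (np.linspace(0.0, r_max, n_bins + 1) if mode == "radial"
             else np.linspace(-r_max, r_max, n_bins + 1))
    if mode == "radial":
        coord = np.linalg.norm(disp, axis=1)
        keep = coord < r_max
        volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    else:
        proj = disp @ axis
        perp = np.linalg.norm(disp - np.outer(proj, axis), axis=1)
        keep = (perp <= slab_radius) & (np.abs(proj) < r_max)
        coord = proj
        volumes = np.pi * slab_radius ** 2 * np.diff(edges)
    counts = np.zeros((4, n_bins))
    for sp in (W, G, A, B):
        sel = keep & (state.species == sp)
        counts[sp], _ = np.histogram(coord[sel], bins=edges)
    return DensityProfile(mode, edges, counts / volumes, counts, volumes)


def detect_cavities(state: SystemState, bead_indices: np.ndarray,
                    lattice_spacing: float = 0.5,
                    occupancy_radius: float = 0.75,
                    min_cavity_volume: float = 1.0) -> CavityReport:
    """Closed interior voids of an aggregate by lattice flood fill.

    A bounding lattice around the unwrapped cluster is marked occupied
    wherever a hydrophobic bead lies within the occupancy radius; free cells
    connected to the lattice boundary are exterior, and any remaining free
    region is a cavity.  Enclosed regions smaller than ``min_cavity_volume``
    (reduced volume units, about one solvent bead's share of space at the
    working density) are packing voids, not cavities, and are dropped.
    Reports each cavity's lattice volume and the solvent beads (W/G) it
    encloses.
    """
    if lattice_spacing <= 0:
        raise ValueError("lattice_spacing must be positive")
    box = state.box_edge
    coords = unwrap_cluster(state, bead_indices)
    b_local = state.species[np.asarray(bead_indices)] == B
    b_coords = coords[b_local] if b_local.any() else coords
    margin = occupancy_radius + 2 * lattice_spacing
    lo = b_coords.min(axis=0) - margin
    hi = b_coords.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / lattice_spacing).astype(int), 1)
    grid = np.stack(np.meshgrid(
        *(lo[d] + (np.arange(shape[d]) + 0.5) * lattice_spacing
          for d in range(3)), indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)
    tree = cKDTree(b_coords)
    d, _ = tree.query(pts, k=1)
    occupied = (d <= occupancy_radius).reshape(tuple(shape))

    free = ~occupied
    labels, n_lab = ndimage.label(free)  # 6-connectivity
    boundary = np.zeros_like(free)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    exterior = np.unique(labels[boundary & free])
    cell_vol = lattice_spacing ** 3
    min_cells = max(1, int(np.ceil(min_cavity_volume / cell_vol)))
    sizes = np.bincount(labels.ravel(), minlength=n_lab + 1)
    cavity_ids = [lab for lab in range(1, n_lab + 1)
                  if lab not in exterior and sizes[lab] >= min_cells]

    volumes, n_w_in, n_g_in = [], [], []
    if cavity_ids:
        com = coords.mean(axis=0)
        solvent = np.flatnonzero((state.species == W) | (state.species == G))
        spos = com + minimum_image(state.positions[solvent] - com, box)
        cell = np.floor((spos - lo) / lattice_spacing).astype(int)
        inside = np.all((cell >= 0) & (cell < shape), axis=1)
        for lab in cavity_ids:
            mask = labels == lab
            volumes.append(float(mask.sum() * cell_vol))
            lab_of = np.zeros(len(solvent), dtype=bool)
            sel = np.flatnonzero(inside)
            lab_of[sel] = mask[cell[sel, 0], cell[sel, 1], cell[sel, 2]]
            sp = state.species[solvent[lab_of]]
            n_w_in.append(int((sp == W).sum()))
            n_g_in.append(int((sp == G).sum()))
    return CavityReport(len(cavity_ids), volumes, n_w_in, n_g_in,
                        lattice_spacing)


@dataclass
class AggregateReport:
    """Classification of one aggregate with its supporting signals."""

    label: str
    shape: str
    descriptor: ShapeDescriptor
    cavities: CavityReport | None
    segregation_index: float
    interior_solvent_fraction: float
    diagnostics: dict = field(default_factory=dict)


def _label_from_signals(shape: str, cavity_count: int, seg: float,
                        solv_frac: float, seg_threshold: float,
                        solvent_threshold: float) -> str:
    """Decision rule shared by the per-frame and consensus classifiers."""
    if cavity_count >= 1:
        return "vesicle" if shape == "spheroidal" else "semi-vesicle"
    if shape == "flat-cylindrical":
        return "disk"
    if abs(seg) < seg_threshold and solv_frac > solvent_threshold:
        return "LLPS-like"
    if seg < -seg_threshold:
        return "semi-vesicle"
    return "micelle"


def classify_aggregate(state: SystemState, bead_indices: np.ndarray,
                       min_beads: int = 30,
                       seg_threshold: float = 0.15,
                       solvent_threshold: float = 0.35,
                       lattice_spacing: float = 0.5,
                       occupancy_radius: float = 0.75) -> AggregateReport:
    """Rule-based label for one aggregate.

    Signals: gyration shape class; closed-cavity count; the segregation
    index (radial centroid of A minus radial centroid of B, normalized by
    Rg — positive when the hydrophilic corona sits outside the hydrophobic
    core, near zero when the blocks are mixed); and the solvent fraction
    inside the polymer-rich region (within the 80th percentile of polymer
    radial distances).  Rules: any closed cavity makes a vesicle (spheroidal)
    or semi-vesicle (anisotropic); without a cavity, a flat-cylindrical
    shape is a disk, a well-mixed solvent-rich interior is LLPS-like, an
    inward-drawn corona is a semi-vesicle, and the remainder are micelles.
    """
    bead_indices = np.asarray(bead_indices)
    coords = unwrap_cluster(state, bead_indices)
    desc = gyration_descriptor(coords)
    if bead_indices.size < min_beads or desc.degenerate:
        return AggregateReport("degenerate", classify_shape(desc), desc,
                               None, np.nan, np.nan)
    shape = classify_shape(desc)
    com = coords.mean(axis=0)
    r_poly = np.linalg.norm(coords - com, axis=1)
    sp = state.species[bead_indices]
    r_a = float(r_poly[sp == A].mean()) if (sp == A).any() else np.nan
    r_b = float(r_poly[sp == B].mean()) if (sp == B).any() else np.nan
    seg = (r_a - r_b) / np.sqrt(desc.rg2)

    r_p = float(np.percentile(r_poly, 80))
    disp = minimum_image(state.positions - com, state.box_edge)
    inside = np.linalg.norm(disp, axis=1) < r_p
    n_inside = int(inside.sum())
    solv_inside = int((inside & ((state.species == W) |
                                 (state.species == G))).sum())
    solv_frac = solv_inside / n_inside if n_inside else 0.0

    cav = detect_cavities(state, bead_indices, lattice_spacing,
                          occupancy_radius)
    label = _label_from_signals(shape, cav.count, seg, solv_frac,
                                seg_threshold, solvent_threshold)
    return AggregateReport(label, shape, desc, cav, float(seg),
                           float(solv_frac),
                           {"r_a": r_a, "r_b": r_b, "r_80": r_p})


def consensus_aggregate_report(reports: list[AggregateReport],
                               spheroid_threshold: float = 1.5,
                               flat_r21_threshold: float = 1.25,
                               seg_threshold: float = 0.15,
                               solvent_threshold: float = 0.35
                               ) -> AggregateReport:
    """Pathway label of a finished run from a window of per-frame reports.

    Instantaneous eigenvalue ratios of small aggregates fluctuate strongly,
    so the terminal structure is judged on tail-averaged signals: the sorted
    eigenvalues, segregation index and interior solvent fraction are
    averaged over the window and the cavity count is the window median,
    then the per-frame decision rule is applied to the averages.
    """
    valid = [r for r in reports if r.label != "degenerate"]
    if not valid:
        raise ValueError("no non-degenerate reports in the window")
    eig = np.mean([r.descriptor.eigenvalues for r in valid], axis=0)
    desc = gyration_descriptor_from_eigenvalues(eig)
    shape = classify_shape(desc, spheroid_threshold, flat_r21_threshold)
    cav_count = int(np.median([r.cavities.count for r in valid
                               if r.cavities is not None]))
    seg = float(np.mean([r.segregation_index for r in valid]))
    solv = float(np.mean([r.interior_solvent_fraction for r in valid]))
    label = _label_from_signals(shape, cav_count, seg, solv,
                                seg_threshold, solvent_threshold)
    return AggregateReport(label, shape, desc, None, seg, solv,
                           {"window": len(valid), "cavity_median": cav_count})


def gyration_descriptor_from_eigenvalues(eig: np.ndarray) -> ShapeDescriptor:
    """Descriptor built from (already sorted, ascending) eigenvalues."""
    eig = np.asarray(eig, dtype=float)
    l1, l2, l3 = eig
    rg2 = float(eig.sum())
    if l1 <= 1e-12 * max(rg2, 1.0):
        return ShapeDescriptor(np.diag(eig), eig, np.inf, np.inf, np.inf,
                               rg2, 0, True)
    return ShapeDescriptor(np.diag(eig), eig, float(l3 / l1), float(l3 / l2),
                           float(l2 / l1), rg2, 0, False)
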