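"""Structural metrics for peptide assemblies.

Three statistics distinguish liquid condensates from fibers in short-peptide
systems:

* **Aggregation propensity (AP)** — the ratio of the total solvent-accessible
  surface area (SASA) of the initial, fully dissolved state to that of the
  final state.  Compaction buries surface, so AP > 1 indicates aggregation;
  the reciprocal (final/initial SASA) is reported alongside as
  ``relative_sasa``.
* **Clustering degree (CD)** — the size of the largest contact-connected
  cluster of peptides divided by the total number of peptides.
* **Intermolecular hydrogen-bond census** — a geometric criterion
  (donor–acceptor distance < 0.35 nm and donor-side angle < 30 degrees),
  partitioned by the species pair of the peptides involved.

SASA is computed with the Shrake–Rupley point-sampling method on a
deterministic spherical Fibonacci lattice, so repeated runs are bit-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii in nm, used when an input file does not
#: override the per-atom radius.
BONDI_RADII_NM = {
    "H": 0.110,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}

DEFAULT_PROBE_RADIUS_NM = 0.14
DEFAULT_SASA_POINTS = 960
DEFAULT_CONTACT_CUTOFF_NM = 0.5
DEFAULT_HBOND_DISTANCE_NM = 0.35
DEFAULT_HBOND_ANGLE_DEG = 30.0


@dataclass
class AtomRecord:
    """One atom with its coordinates, radius, and hydrogen-bonding roles."""

    element: str
    position: np.ndarray  # (3,) in nm
    vdw_radius: float  # nm
    peptide_id: int
    species: str
    is_donor_heavy: bool = False
    bonded_hydrogen_index: int | None = None  # global atom index of the amide H
    is_acceptor: bool = False


@dataclass
class Configuration:
    """A molecular configuration: atoms grouped into peptides.

    Stored as parallel numpy arrays (one row per atom) for vectorized
    metric evaluation.  ``donor_h_index`` is -1 for non-donor atoms;
    a non-negative value is the global index of the hydrogen bonded to
    that donor heavy atom.
    """

    positions: np.ndarray  # (N, 3) nm
    radii: np.ndarray  # (N,) nm
    elements: np.ndarray  # (N,) str
    peptide_ids: np.ndarray  # (N,) int
    species: np.ndarray  # (N,) str
    donor_h_index: np.ndarray  # (N,) int, -1 if none
    is_acceptor: np.ndarray  # (N,) bool
    box_edge: float | None = None  # nm; enables minimum-image searches

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        self.peptide_ids = np.asarray(self.peptide_ids, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        self.donor_h_index = np.asarray(self.donor_h_index, dtype=int)
        self.is_acceptor = np.asarray(self.is_acceptor, dtype=bool)
        n = len(self.positions)
        if n == 0:
            raise ArgumentError("configuration has no atoms")
        if self.positions.shape != (n, 3):
            raise ArgumentError("positions must be an (N, 3) array")
        if not np.isfinite(self.positions).all():
            raise DataError("non-finite coordinates in configuration")
        if (self.radii <= 0).any():
            raise DataError("all van der Waals radii must be positive")
        pids = np.unique(self.peptide_ids)
        if pids.min() != 0 or not np.array_equal(pids, np.arange(len(pids))):
            raise DataError("peptide ids must be contiguous 0..n_peptides-1")
        bad = self.donor_h_index >= n
        if bad.any():
            raise DataError("donor hydrogen index out of range")
        has_h = self.donor_h_index >= 0
        if has_h.any():
            hidx = self.donor_h_index[has_h]
            if (self.elements[hidx] != "H").any():
                raise DataError("donor hydrogen index must refer to an H atom")
            if (self.peptide_ids[hidx] != self.peptide_ids[has_h]).any():
                raise DataError("donor hydrogen must belong to the same peptide")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_peptides(self) -> int:
        return int(self.peptide_ids.max()) + 1

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def peptide_species(self) -> np.ndarray:
        """Species tag of each peptide (one entry per peptide)."""
        out = np.empty(self.n_peptides, dtype=object)
        for pid in range(self.n_peptides):
            out[pid] = self.species[self.peptide_ids == pid][0]
        return out

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            hi = int(self.donor_h_index[i])
            yield AtomRecord(
                element=str(self.elements[i]),
                position=self.positions[i].copy(),
                vdw_radius=float(self.radii[i]),
                peptide_id=int(self.peptide_ids[i]),
                species=str(self.species[i]),
                is_donor_heavy=hi >= 0,
                bonded_hydrogen_index=hi if hi >= 0 else None,
                is_acceptor=bool(self.is_acceptor[i]),
            )

    @classmethod
    def from_atoms(cls, atoms: list[AtomRecord], box_edge: float | None = None) -> "Configuration":
        # A donor flagged without a recorded hydrogen cannot participate in
        # the H-bond census; skip it with a warning rather than failing.
        for i, a in enumerate(atoms):
            if a.is_donor_heavy and a.bonded_hydrogen_index is None:
                logger.warning("donor atom %d has no bonded hydrogen recorded; skipped", i)
        return cls(
            positions=np.array([a.position for a in atoms], dtype=float),
            radii=np.array([a.vdw_radius for a in atoms], dtype=float),
            elements=np.array([a.element for a in atoms], dtype=object),
            peptide_ids=np.array([a.peptide_id for a in atoms], dtype=int),
            species=np.array([a.species for a in atoms], dtype=object),
            donor_h_index=np.array(
                [a.bonded_hydrogen_index if a.bonded_hydrogen_index is not None else -1 for a in atoms],
                dtype=int,
            ),
            is_acceptor=np.array([a.is_acceptor for a in atoms], dtype=bool),
            box_edge=box_edge,
        )

    def transformed(self, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)) -> "Configuration":
        """Return a copy with a rigid motion applied to every atom."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        pos = pos + np.asarray(translation, dtype=float)
        return Configuration(
            positions=pos,
            radii=self.radii.copy(),
            elements=self.elements.copy(),
            peptide_ids=self.peptide_ids.copy(),
            species=self.species.copy(),
            donor_h_index=self.donor_h_index.copy(),
            is_acceptor=self.is_acceptor.copy(),
            box_edge=self.box_edge,
        )


@dataclass
class Trajectory:
    """An ordered sequence of configurations with strictly increasing times."""

    frames: list[Configuration]
    times: np.ndarray  # recorded units (arbitrary for morphs)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ArgumentError("one time per frame required")
        if len(self.frames) < 1:
            raise ArgumentError("trajectory needs at least one frame")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise DataError("frame times must be strictly increasing")
        n0 = self.frames[0].n_atoms
        if any(f.n_atoms != n0 for f in self.frames):
            raise DataError("all frames must have the same atom count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SasaResult:
    """Shrake–Rupley solvent-accessible surface area estimate."""

    per_atom_area: np.ndarray  # (N,) nm^2
    total_area: float  # nm^2
    probe_radius: float  # nm
    n_sphere_points: int


@dataclass
class ClusterAssignment:
    """Partition of peptides into contact-connected clusters."""

    labels: np.ndarray  # (n_peptides,) cluster id per peptide
    cluster_sizes: np.ndarray  # sizes, descending
    contact_cutoff: float  # nm

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


@dataclass
class HBond:
    """One geometric hydrogen bond D–H···A."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    distance_da: float  # nm
    angle_deg: float  # donor-side angle between D->H and D->A
    intermolecular: bool
    species_pair: tuple[str, str]  # sorted, unordered pair


@dataclass
class PhaseMetrics:
    """The classifier's input: AP, relative SASA, CD and the H-bond census."""

    ap: float
    relative_sasa: float
    cd: float
    n_hbonds_total: float
    n_hbonds_by_pair: dict[tuple[str, str], float] = field(default_factory=dict)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (deterministic spiral lattice)."""
    i = np.arange(n_points)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    config: Configuration,
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
    n_sphere_points: int = DEFAULT_SASA_POINTS,
) -> SasaResult:
    """Shrake–Rupley SASA with a probe rolled over the van der Waals surface.

    For each atom, test points are placed on the sphere of radius
    ``r + probe_radius``; the accessible fraction is the share of points not
    strictly inside any other atom's expanded sphere.  The point set is a
    fixed Fibonacci lattice, so the estimate is deterministic.
    """
    if n_sphere_points < 32:
        raise ArgumentError("n_sphere_points must be >= 32")
    if probe_radius < 0:
        raise ArgumentError("probe_radius must be non-negative")
    pos = config.positions
    if not np.isfinite(pos).all():
        raise DataError("non-finite coordinates")
    expanded = config.radii + probe_radius
    unit = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(pos)
    rmax = expanded.max()
    per_atom = np.empty(config.n_atoms)
    for i in range(config.n_atoms):
        ri = expanded[i]
        cand = tree.query_ball_point(pos[i], ri + rmax)
        nbr = [j for j in cand if j != i and np.linalg.norm(pos[j] - pos[i]) < ri + expanded[j]]
        area_i = 4.0 * np.pi * ri * ri
        if not nbr:
            per_atom[i] = area_i
            continue
        pts = pos[i] + ri * unit
        d2 = ((pts[:, None, :] - pos[nbr][None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (expanded[nbr] ** 2)[None, :]).any(axis=1)
        per_atom[i] = area_i * (1.0 - buried.mean())
    return SasaResult(
        per_atom_area=per_atom,
        total_area=float(per_atom.sum()),
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


def aggregation_propensity(sasa_initial: float, sasa_final: float) -> tuple[float, float]:
    """AP and relative SASA from initial/final total areas.

    AP = initial/final (compaction gives AP > 1); relative SASA is the
    reciprocal, final/initial.
    """
    if sasa_initial <= 0 or sasa_final <= 0:
        raise ArgumentError("SASA values must be positive")
    relative = sasa_final / sasa_initial
    return 1.0 / relative, relative


def find_clusters(
    config: Configuration,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    use_pbc: bool = False,
) -> ClusterAssignment:
    """Connected components of the peptide contact graph.

    Two peptides are in contact iff any inter-peptide heavy-atom distance is
    strictly below the cutoff.  With ``use_pbc`` (requires ``box_edge``),
    distances use the minimum-image convention.
    """
    if contact_cutoff <= 0:
        raise ArgumentError("contact_cutoff must be positive")
    heavy = config.heavy_mask
    hpos = config.positions[heavy]
    hpid = config.peptide_ids[heavy]
    n_pep = config.n_peptides
    if use_pbc:
        if config.box_edge is None:
            raise ArgumentError("use_pbc requires box_edge")
        box = float(config.box_edge)
        hpos = np.mod(hpos, box)
        tree = cKDTree(hpos, boxsize=box)
    else:
        tree = cKDTree(hpos)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
    if len(pairs):
        a, b = pairs[:, 0], pairs[:, 1]
        delta = hpos[a] - hpos[b]
        if use_pbc:
            box = float(config.box_edge)
            delta -= box * np.round(delta / box)
        dist = np.linalg.norm(delta, axis=1)
        keep = (dist < contact_cutoff) & (hpid[a] != hpid[b])
        pa, pb = hpid[a][keep], hpid[b][keep]
    else:
        pa = pb = np.empty(0, dtype=int)
    adj = sparse.coo_matrix(
        (np.ones(len(pa)), (pa, pb)), shape=(n_pep, n_pep)
    )
    _, labels = connected_components(adj, directed=False)
    sizes = np.sort(np.bincount(labels))[::-1]
    return ClusterAssignment(labels=labels, cluster_sizes=sizes, contact_cutoff=contact_cutoff)


def clustering_degree(assignment: ClusterAssignment, n_peptides: int) -> float:
    """CD: largest cluster size over the total number of peptides."""
    if len(assignment.cluster_sizes) == 0:
        raise ArgumentError("empty cluster assignment")
    if n_peptides <= 0 or assignment.cluster_sizes.sum() != n_peptides:
        raise ArgumentError("cluster sizes must sum to n_peptides")
    return float(assignment.cluster_sizes[0]) / n_peptides


def detect_hbonds(
    config: Configuration,
    d_max: float = DEFAULT_HBOND_DISTANCE_NM,
    angle_max: float = DEFAULT_HBOND_ANGLE_DEG,
    intermolecular_only: bool = True,
) -> list[HBond]:
    """Geometric hydrogen-bond census.

    A bond D–H···A is reported iff the donor–acceptor distance is strictly
    below ``d_max`` and the donor-side angle between D->H and D->A is
    strictly below ``angle_max`` degrees.  Donors flagged without a bonded
    hydrogen are skipped with a logged warning.
    """
    if d_max <= 0 or angle_max <= 0:
        raise ArgumentError("hydrogen-bond cutoffs must be positive")
    pos = config.positions
    pep_species = config.peptide_species()
    donor_idx = np.flatnonzero(config.donor_h_index >= 0)
    acceptor_idx = np.flatnonzero(config.is_acceptor)
    if len(acceptor_idx) == 0 or len(donor_idx) == 0:
        return []
    atree = cKDTree(pos[acceptor_idx])
    bonds: list[HBond] = []
    for d in donor_idx:
        h = int(config.donor_h_index[d])
        dh = pos[h] - pos[d]
        dh_norm = np.linalg.norm(dh)
        if dh_norm == 0:
            logger.warning("donor atom %d has zero-length D-H vector; skipped", d)
            continue
        for ai in atree.query_ball_point(pos[d], d_max):
            a = int(acceptor_idx[ai])
            if a == d or a == h:
                continue
            da = pos[a] - pos[d]
            dist = float(np.linalg.norm(da))
            if not dist < d_max or dist == 0:
                continue
            inter = config.peptide_ids[d] != config.peptide_ids[a]
            if intermolecular_only and not inter:
                continue
            cosang = np.dot(dh, da) / (dh_norm * dist)
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if not angle < angle_max:
                continue
            sp = tuple(sorted((str(pep_species[config.peptide_ids[d]]),
                               str(pep_species[config.peptide_ids[a]]))))
            bonds.append(
                HBond(
                    donor_index=int(d),
                    hydrogen_index=h,
                    acceptor_index=a,
                    distance_da=dist,
                    angle_deg=angle,
                    intermolecular=bool(inter),
                    species_pair=sp,
                )
            )
    return bonds


def hbond_species_partition(bonds: list[HBond]) -> dict[tuple[str, str], int]:
    """Count hydrogen bonds by unordered species pair; counts sum to len(bonds)."""
    out: dict[tuple[str, str], int] = {}
    for b in bonds:
        out[b.species_pair] = out.get(b.species_pair, 0) + 1
    return out


def phase_metrics(
    traj: Trajectory,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    hbond_params: dict | None = None,
    tail_frames: int = 1,
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
    n_sphere_points: int = DEFAULT_SASA_POINTS,
) -> PhaseMetrics:
    """AP, CD and the H-bond census for a trajectory.

    AP compares frame 0 against the mean total SASA of the last
    ``tail_frames`` frames; CD and H-bond counts are averaged over the same
    tail window.
    """
    if traj.n_frames < 2:
        raise ArgumentError("trajectory needs at least 2 frames")
    if not 1 <= tail_frames < traj.n_frames:
        raise ArgumentError("tail_frames must be in [1, n_frames)")
    hb = hbond_params or {}
    sasa0 = compute_sasa(traj.frames[0], probe_radius, n_sphere_points).total_area
    tail = traj.frames[-tail_frames:]
    sasa_tail = np.mean([compute_sasa(f, probe_radius, n_sphere_points).total_area for f in tail])
    ap, relative = aggregation_propensity(sasa0, float(sasa_tail))
    cds = []
    totals = []
    pair_sums: dict[tuple[str, str], float] = {}
    for f in tail:
        assignment = find_clusters(f, contact_cutoff)
        cds.append(clustering_degree(assignment, f.n_peptides))
        bonds = detect_hbonds(f, **hb)
        totals.append(len(bonds))
        for pair, c in hbond_species_partition(bonds).items():
            pair_sums[pair] = pair_sums.get(pair, 0.0) + c
    n_tail = len(tail)
    return PhaseMetrics(
        ap=ap,
        relative_sasa=relative,
        cd=float(np.mean(cds)),
        n_hbonds_total=float(np.mean(totals)),
        n_hbonds_by_pair={k: v / n_tail for k, v in pair_sums.items()},
    )
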