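"""Synthetic inputs: planted stacked clusters, equilibrium trajectories, and a
stochastic association simulator.

Three generators cover the pipeline's input needs without any external data:

* :func:`build_conformation` — a single frame of rigid hexagonal "aromatic"
  molecules with a prescribed multiset of planted dimers/trimers in
  face-to-face, offset face-to-face, or edge-to-face geometry, everything
  else well separated.  This is ground truth for the stacking detector.
* :func:`build_equilibrium_trajectory` — a multi-frame trajectory whose
  cluster-size multiset is constant (the census is stationary) while cluster
  *membership* exchanges between frames, emulating a dynamic equilibrium of
  aggregation and segregation.
* :func:`simulate_aggregation` — a Metropolis Monte-Carlo model of point
  particles with a hard core and a square attractive well, a deliberately
  minimal stand-in for solute association: strong enough attraction and
  high enough concentration raise the aggregate fraction, which is the
  qualitative behavior of aromatic solutes in octanol.

The template molecule is a rigid planar C6 hexagon with 1.40 Å edges
regardless of chemical identity: the census machinery tests geometry, not
chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._util import min_image_vector
from .census import (AggregateCensus, StackingCriteria, census,
                     cluster_points_by_distance)
from .trajectory import Frame, MoleculeTopology, Trajectory

BOLTZMANN_KCAL = 0.0019872041  # kcal mol^-1 K^-1

#: Lateral slide used when planting offset face-to-face stacks, Å.  Chosen
#: above the 1.0 Å face-to-face/offset discrimination threshold and small
#: enough that typical planted centroid distances stay under the 3.9 Å cutoff.
OFFSET_LATERAL = 1.2

_DEFAULT_DISTANCE = {"face-to-face": 3.5, "offset-face-to-face": 3.5, "edge-to-face": 4.5}


def hexagon_template(edge: float = 1.40) -> np.ndarray:
    """Regular C6 hexagon in the z=0 plane; circumradius equals the edge length."""
    ang = np.arange(6) * np.pi / 3.0
    return np.column_stack([edge * np.cos(ang), edge * np.sin(ang), np.zeros(6)])


@dataclass(frozen=True)
class ClusterPlant:
    """One planted aggregate: its size, stacking conformer and member spacing (Å)."""

    size: int
    conformer: Literal["face-to-face", "offset-face-to-face", "edge-to-face"] = "face-to-face"
    distance: float | None = None

    def spacing(self) -> float:
        return self.distance if self.distance is not None else _DEFAULT_DISTANCE[self.conformer]


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for a planted configuration of N molecules in a cubic box."""

    n_molecules: int
    box_edge: float
    clusters: tuple[ClusterPlant, ...] = ()
    min_separation: float = 6.0
    template: np.ndarray = field(default_factory=hexagon_template)
    seed: int = 0
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        criteria = StackingCriteria()
        if sum(c.size for c in self.clusters) > self.n_molecules:
            raise ValueError("planted cluster sizes exceed n_molecules")
        if self.min_separation <= criteria.cutoff_e2f:
            raise ValueError(
                f"min_separation must exceed the widest cutoff ({criteria.cutoff_e2f} A)")
        for c in self.clusters:
            if c.spacing() >= criteria.cutoff_for(c.conformer):
                raise ValueError(
                    f"planted {c.conformer} spacing {c.spacing()} A not below its cutoff")

    @property
    def planted_size_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        n_clustered = 0
        for c in self.clusters:
            counts[c.size] = counts.get(c.size, 0) + 1
            n_clustered += c.size
        n_mono = self.n_molecules - n_clustered
        if n_mono:
            counts[1] = counts.get(1, 0) + n_mono
        return counts


class PackingError(RuntimeError):
    """Rejection sampling could not place all molecules; try a larger box."""


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _rot_x90() -> np.ndarray:
    return np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


def _cluster_geometry(plant: ClusterPlant, rot: np.ndarray
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centroid offset, orientation) per member, in the cluster's frame."""
    normal = rot @ np.array([0.0, 0.0, 1.0])
    lateral = rot @ np.array([1.0, 0.0, 0.0])
    d = plant.spacing()
    members: list[tuple[np.ndarray, np.ndarray]] = []
    if plant.conformer == "face-to-face":
        step = d * normal
        for i in range(plant.size):
            members.append((i * step, rot))
    elif plant.conformer == "offset-face-to-face":
        axial = float(np.sqrt(d * d - OFFSET_LATERAL ** 2))
        step = axial * normal + OFFSET_LATERAL * lateral
        for i in range(plant.size):
            members.append((i * step, rot))
    else:  # edge-to-face: alternate perpendicular orientations along the stack axis
        step = d * normal
        perp = rot @ _rot_x90()
        for i in range(plant.size):
            members.append((i * step, rot if i % 2 == 0 else perp))
    return members


def _place_conformation(spec: PlantSpec, rng: np.random.Generator
                        ) -> tuple[np.ndarray, list[int]]:
    """Place all molecules; returns (per-molecule atom coords stacked, cluster id per slot).

    Cluster members are listed first (cluster by cluster), then monomers;
    the slot order is the molecule order in the resulting topology.
    """
    box = np.full(3, spec.box_edge)
    centroids: list[np.ndarray] = []
    rotations: list[np.ndarray] = []
    cluster_of: list[int] = []

    def far_enough(new_pts: list[np.ndarray]) -> bool:
        for p in new_pts:
            for q in centroids:
                d = np.linalg.norm(min_image_vector(p - q, box))
                if d <= spec.min_separation:
                    return False
        return True

    for ci, plant in enumerate(spec.clusters):
        for _ in range(spec.max_attempts):
            center = rng.uniform(0, spec.box_edge, size=3)
            rot = _random_rotation(rng)
            members = _cluster_geometry(plant, rot)
            pts = [center + off for off, _ in members]
            if far_enough(pts):
                for (off, r), p in zip(members, pts):
                    centroids.append(p)
                    rotations.append(r)
                    cluster_of.append(ci)
                break
        else:
            raise PackingError(
                f"could not place cluster {ci} after {spec.max_attempts} attempts; "
                "try a larger box or fewer molecules")

    n_mono = spec.n_molecules - len(centroids)
    for mi in range(n_mono):
        for _ in range(spec.max_attempts):
            p = rng.uniform(0, spec.box_edge, size=3)
            if far_enough([p]):
                centroids.append(p)
                rotations.append(_random_rotation(rng))
                cluster_of.append(len(spec.clusters) + mi)
                break
        else:
            raise PackingError(
                f"could not place monomer after {spec.max_attempts} attempts; "
                "try a larger box or fewer molecules")

    coords = np.concatenate([
        (c - box * np.floor(c / box)) + (rot @ spec.template.T).T
        for c, rot in zip(centroids, rotations)])
    return coords, cluster_of


def _hexagon_topology(n_molecules: int, atoms_per: int) -> list[MoleculeTopology]:
    topo = []
    for i in range(n_molecules):
        base = i * atoms_per
        idx = tuple(range(base, base + atoms_per))
        topo.append(MoleculeTopology(
            molecule_id=f"mol-{i}", atom_indices=idx,
            elements=("C",) * atoms_per, rings=(idx,)))
    return topo


def grouping_spec(spec: PlantSpec) -> dict:
    """Uniform grouping spec matching the generated XYZ output."""
    per = spec.template.shape[0]
    return {"mode": "uniform", "n_molecules": spec.n_molecules,
            "atoms_per_molecule": per, "rings": [list(range(per))]}


def build_conformation(spec: PlantSpec) -> Trajectory:
    """Single-frame trajectory realizing the planted cluster multiset.

    Deterministic under ``spec.seed``; raises :class:`PackingError` when the
    box cannot host the requested separation.
    """
    rng = np.random.default_rng(spec.seed)
    coords, _ = _place_conformation(spec, rng)
    per = spec.template.shape[0]
    topo = _hexagon_topology(spec.n_molecules, per)
    frame = Frame(time=0.0, box=np.full(3, spec.box_edge), coords=coords)
    return Trajectory(topology=topo, frames=[frame])


def build_equilibrium_trajectory(spec: PlantSpec, n_frames: int,
                                 exchange_rate: int = 1, dt: float = 10.0) -> Trajectory:
    """Trajectory with a conserved cluster-size multiset but exchanging membership.

    Every frame is a fresh placement of the same planted multiset (clusters
    appear in different places), and ``exchange_rate`` random cross-cluster
    partner swaps per frame reassign which molecules occupy which cluster
    slots.  With ``exchange_rate=0`` membership is frozen.  The census over
    any checkpoint set is therefore constant by construction.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    per = spec.template.shape[0]
    topo = _hexagon_topology(spec.n_molecules, per)
    box = np.full(3, spec.box_edge)
    perm = np.arange(spec.n_molecules)  # slot -> molecule id
    swap_rng = np.random.default_rng([spec.seed, 0x51AB])
    frames = []
    cluster_of_ref: list[int] | None = None
    for f in range(n_frames):
        frame_rng = np.random.default_rng([spec.seed, f + 1])
        slot_coords, cluster_of = _place_conformation(spec, frame_rng)
        if cluster_of_ref is None:
            cluster_of_ref = cluster_of
        if f > 0:
            for _ in range(exchange_rate):
                _apply_cross_cluster_swap(perm, cluster_of, swap_rng)
        coords = np.empty_like(slot_coords)
        for slot in range(spec.n_molecules):
            mol = perm[slot]
            coords[mol * per:(mol + 1) * per] = slot_coords[slot * per:(slot + 1) * per]
        frames.append(Frame(time=f * dt, box=box, coords=coords))
    return Trajectory(topology=topo, frames=frames)


def _apply_cross_cluster_swap(perm: np.ndarray, cluster_of: Sequence[int],
                              rng: np.random.Generator, tries: int = 50) -> None:
    n = len(perm)
    if n < 2 or len(set(cluster_of)) < 2:
        return
    for _ in range(tries):
        a, b = rng.integers(0, n, size=2)
        if cluster_of[a] != cluster_of[b]:
            perm[a], perm[b] = perm[b], perm[a]
            return


# ---------------------------------------------------------------------------
# Metropolis association simulator

@dataclass(frozen=True)
class SimParams:
    """Square-well Metropolis model parameters.

    ``sigma`` is the hard-core diameter (Å), ``epsilon`` the well depth
    (kcal/mol, positive = attractive), ``well_range`` the attraction range
    (Å, also the contact cutoff for the census).  ``n_sweeps`` counts N-move
    sweeps; a frame and census are recorded after every sweep.
    """

    n_particles: int
    box_edge: float
    epsilon: float
    sigma: float = 3.4
    well_range: float = 5.0
    temperature: float = 298.15
    n_sweeps: int = 300
    max_displacement: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.box_edge <= 0 or self.sigma <= 0:
            raise ValueError("invalid geometry parameters")
        if self.well_range <= self.sigma:
            raise ValueError("well_range must exceed the hard-core diameter")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kbt(self) -> float:
        return BOLTZMANN_KCAL * self.temperature


@dataclass
class SimResult:
    """Simulator output: frames, per-sweep censuses, and move statistics."""

    trajectory: Trajectory
    censuses: list[AggregateCensus]
    aggregate_fraction: np.ndarray  # per recorded sweep, fraction of non-monomer particles
    attempted: int
    accepted: int
    overlap_rejected: int

    def mean_aggregate_fraction(self, discard: float = 0.5) -> float:
        """Mean aggregate fraction over the last (1-discard) of the run."""
        start = int(len(self.aggregate_fraction) * discard)
        return float(self.aggregate_fraction[start:].mean())


def epsilon_from_pipi(energy_kcal: float, scale: float = 0.10) -> float:
    """Map a π–π interaction energy (kcal/mol, negative = attractive) to a well depth.

    The default 0.10 scale keeps ε/k_BT near 1.6–1.9 so that association
    stays reversible at desk scale; full-strength stacking energies would
    freeze aggregates irreversibly in this minimal model.
    """
    return abs(energy_kcal) * scale


def random_hard_sphere_configuration(n: int, box_edge: float, sigma: float,
                                     rng: np.random.Generator,
                                     max_attempts: int = 20000) -> np.ndarray:
    """Sequential random insertion of non-overlapping points in a periodic cube."""
    box = np.full(3, box_edge)
    pts = np.empty((n, 3))
    placed = 0
    for _ in range(max_attempts):
        cand = rng.uniform(0, box_edge, size=3)
        if placed == 0 or np.all(
                np.linalg.norm(min_image_vector(pts[:placed] - cand, box), axis=1) >= sigma):
            pts[placed] = cand
            placed += 1
            if placed == n:
                return pts
    raise PackingError(f"could not insert {n} hard spheres in a {box_edge} A box")


def _pair_energy(dists: np.ndarray, sigma: float, well_range: float,
                 epsilon: float) -> float:
    if np.any(dists < sigma):
        return np.inf
    return -epsilon * int(np.count_nonzero(dists < well_range))


def simulate_aggregation(params: SimParams, record_every: int = 1) -> SimResult:
    """Run the square-well Metropolis model and census every recorded sweep.

    Single-particle displacement moves (uniform in a cube of half-width
    ``max_displacement``) are accepted with probability min(1, exp(−ΔU/k_BT));
    overlap moves are rejected outright.  Contacts for the census are simply
    separations below the well range, clustered by connected components.
    """
    rng = np.random.default_rng(params.seed)
    box = np.full(3, params.box_edge)
    pts = random_hard_sphere_configuration(params.n_particles, params.box_edge,
                                           params.sigma, rng)
    ids = [f"p-{i}" for i in range(params.n_particles)]
    attempted = accepted = overlap_rejected = 0
    frames: list[Frame] = []
    censuses: list[AggregateCensus] = []
    fractions: list[float] = []

    def local_dists(coords: np.ndarray, i: int, pos: np.ndarray) -> np.ndarray:
        others = np.delete(coords, i, axis=0)
        return np.linalg.norm(min_image_vector(others - pos, box), axis=1)

    for sweep in range(1, params.n_sweeps + 1):
        for _ in range(params.n_particles):
            attempted += 1
            i = int(rng.integers(params.n_particles))
            disp = rng.uniform(-params.max_displacement, params.max_displacement, size=3)
            new = pts[i] + disp
            new -= box * np.floor(new / box)
            d_new = local_dists(pts, i, new)
            if np.any(d_new < params.sigma):
                overlap_rejected += 1
                continue
            d_old = local_dists(pts, i, pts[i])
            du = (_pair_energy(d_new, params.sigma, params.well_range, params.epsilon)
                  - _pair_energy(d_old, params.sigma, params.well_range, params.epsilon))
            if du <= 0 or rng.random() < np.exp(-du / params.kbt):
                pts[i] = new
                accepted += 1
        if sweep % record_every == 0:
            t = float(sweep)
            frames.append(Frame(time=t, box=box.copy(), coords=pts.copy()))
            cs = cluster_points_by_distance(t, ids, pts, box, params.well_range)
            c = census(cs)
            censuses.append(c)
            fractions.append(1.0 - c.counts.get(1, 0) / params.n_particles)

    topo = [MoleculeTopology(molecule_id=ids[i], atom_indices=(i,), elements=("C",))
            for i in range(params.n_particles)]
    traj = Trajectory(topology=topo, frames=frames)
    return SimResult(trajectory=traj, censuses=censuses,
                     aggregate_fraction=np.asarray(fractions),
                     attempted=attempted, accepted=accepted,
                     overlap_rejected=overlap_rejected)
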