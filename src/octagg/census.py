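"""π-stacking contact detection and aggregate census on molecular frames.

A pair of aromatic solute molecules counts as a stacked dimer contact when
their centroid distance (under the minimum-image convention) falls below a
conformer-specific cutoff: 3.8 Å face-to-face, 3.9 Å offset face-to-face,
5.0 Å edge-to-face.  The conformer is decided geometrically: the interplanar
angle γ between the two molecular ring-plane normals (folded to [0°, 90°])
separates the parallel family (γ ≤ 50° by default) from edge-to-face; the
lateral offset (component of the centroid–centroid vector perpendicular to
the mean plane normal) separates eclipsed face-to-face (< 1.0 Å) from the
slipped offset geometry.  The distance cutoffs are the recognition rule;
the angle/offset subdivision thresholds follow common stacking-geometry
conventions and are configurable.

Contacts define an undirected graph over molecules; connected components are
the aggregates.  The census reports, per frame, the percentage of molecules
residing in clusters of each size (monomer, dimer, trimer, ≥4 "polymer"),
half-up rounded to one decimal as such tables are conventionally printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from ._util import min_image_distance, min_image_vector, round_half_up
from .trajectory import Frame, MoleculeTopology, Trajectory

logger = logging.getLogger(__name__)

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "F": 18.998, "Cl": 35.45, "Br": 79.904, "X": 1.0,
}

Conformer = Literal["face-to-face", "offset-face-to-face", "edge-to-face"]


@dataclass(frozen=True)
class StackingCriteria:
    """Distance cutoffs and geometric thresholds for stacked-pair recognition.

    ``mode`` selects the tested distance: ``molecule-centroid`` (default,
    the whole-molecule centroid) or ``ring-pair`` (every ring–ring pair is
    tested and the closest qualifying pair decides — more appropriate for
    large multi-ring solutes).
    """

    cutoff_f2f: float = 3.8
    cutoff_offset: float = 3.9
    cutoff_e2f: float = 5.0
    parallel_angle_max: float = 50.0
    offset_lateral_min: float = 1.0
    mode: Literal["molecule-centroid", "ring-pair"] = "molecule-centroid"

    def __post_init__(self) -> None:
        if min(self.cutoff_f2f, self.cutoff_offset, self.cutoff_e2f) <= 0:
            raise ValueError("cutoffs must be positive")
        if not self.cutoff_f2f <= self.cutoff_offset <= self.cutoff_e2f:
            raise ValueError("cutoffs must satisfy f2f <= offset <= e2f")

    def cutoff_for(self, conformer: Conformer) -> float:
        return {"face-to-face": self.cutoff_f2f,
                "offset-face-to-face": self.cutoff_offset,
                "edge-to-face": self.cutoff_e2f}[conformer]


@dataclass(frozen=True)
class PairContact:
    """A recognized stacked pair with its classifying geometry."""

    mol_a: str
    mol_b: str
    conformer: Conformer
    distance: float
    interplanar_angle: float
    lateral_offset: float


@dataclass(frozen=True)
class ClusterSet:
    """Partition of a frame's molecules into aggregates (singletons included)."""

    time: float
    clusters: tuple[frozenset[str], ...]
    n_molecules: int

    def __post_init__(self) -> None:
        total = sum(len(c) for c in self.clusters)
        ids: set[str] = set()
        for c in self.clusters:
            if ids & c:
                raise ValueError("clusters must be disjoint")
            ids |= c
        if total != self.n_molecules:
            raise ValueError(f"cluster sizes sum to {total}, expected {self.n_molecules}")

    def size_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for c in self.clusters:
            counts[len(c)] = counts.get(len(c), 0) + 1
        return counts


@dataclass(frozen=True)
class AggregateCensus:
    """Per-frame percent-of-molecules by aggregate size.

    ``counts`` maps cluster size k to the number of such clusters n_k;
    Σ k·n_k = N.  Percentages are 100·k·n_k/N, half-up to one decimal;
    clusters of size ≥ 4 are pooled under the "polymer" label for display
    while exact sizes stay in ``counts``.
    """

    time: float
    n_molecules: int
    counts: Mapping[int, int]

    def percent(self, k: int) -> float:
        return round_half_up(100.0 * k * self.counts.get(k, 0) / self.n_molecules, 1)

    @property
    def percent_polymer(self) -> float:
        heavy = sum(k * n for k, n in self.counts.items() if k >= 4)
        return round_half_up(100.0 * heavy / self.n_molecules, 1)

    @property
    def percentages(self) -> dict[str, float]:
        return {"monomer": self.percent(1), "dimer": self.percent(2),
                "trimer": self.percent(3), "polymer": self.percent_polymer}


# ---------------------------------------------------------------------------
# geometry

def unwrap_molecule(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shift every atom to the periodic image nearest the first atom."""
    coords = np.asarray(coords, float)
    ref = coords[0]
    return ref + min_image_vector(coords - ref, box)


def molecule_centroid(frame: Frame, mol: MoleculeTopology,
                      weighting: Literal["geometric", "mass"] = "geometric") -> np.ndarray:
    """Molecule centroid after unwrapping across periodic images, wrapped into [0, L).

    Geometric (unweighted) mean by default; ``weighting="mass"`` uses atomic
    masses.
    """
    if not mol.atom_indices:
        raise ValueError(f"{mol.molecule_id}: molecule has no atoms")
    pts = unwrap_molecule(frame.coords[list(mol.atom_indices)], frame.box)
    if weighting == "mass":
        w = np.asarray([ATOMIC_MASS.get(el, 12.011) for el in mol.elements])
        c = (pts * w[:, None]).sum(axis=0) / w.sum()
    elif weighting == "geometric":
        c = pts.mean(axis=0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return c - frame.box * np.floor(c / frame.box)


def ring_plane(frame: Frame, ring_atoms: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane of a ring: (centroid, unit normal), sign-free.

    The normal is the least-squares plane normal (smallest principal axis of
    the centered ring coordinates); a degenerate (collinear) ring raises.
    """
    if len(ring_atoms) < 3:
        raise ValueError("ring plane needs at least 3 atoms")
    pts = unwrap_molecule(np.asarray([frame.coords[a] for a in ring_atoms]), frame.box)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-300):
        raise ValueError("degenerate ring geometry: atoms are collinear")
    return centroid, vt[2]


def _molecule_plane(frame: Frame, mol: MoleculeTopology) -> tuple[np.ndarray, np.ndarray]:
    """Plane over the union of a molecule's ring atoms (its aromatic plane)."""
    if not mol.rings:
        raise ValueError(f"{mol.molecule_id}: no ring definition in grouping spec")
    atoms = sorted({a for ring in mol.rings for a in ring})
    return ring_plane(frame, atoms)


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two sign-free plane normals, folded to [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _lateral_offset(sep: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> float:
    """Component of the centroid separation perpendicular to the mean normal."""
    n2a = n2 if np.dot(n1, n2) >= 0 else -n2
    mean_n = n1 + n2a
    norm = np.linalg.norm(mean_n)
    if norm < 1e-12:
        return float(np.linalg.norm(sep))
    mean_n = mean_n / norm
    return float(np.linalg.norm(sep - np.dot(sep, mean_n) * mean_n))


def _classify_geometry(sep: np.ndarray, dist: float, n_a: np.ndarray, n_b: np.ndarray,
                       criteria: StackingCriteria) -> tuple[Conformer, float, float]:
    gamma = _interplanar_angle(n_a, n_b)
    offset = _lateral_offset(sep, n_a, n_b)
    if gamma <= criteria.parallel_angle_max:
        conformer: Conformer = ("face-to-face" if offset < criteria.offset_lateral_min
                                else "offset-face-to-face")
    else:
        conformer = "edge-to-face"
    return conformer, gamma, offset


def classify_pair(frame: Frame, mol_a: MoleculeTopology, mol_b: MoleculeTopology,
                  criteria: StackingCriteria = StackingCriteria()) -> PairContact | None:
    """Test one molecule pair for a stacked contact; None if no conformer qualifies."""
    if criteria.mode == "ring-pair":
        if not mol_a.rings or not mol_b.rings:
            raise ValueError("ring-pair mode requires ring definitions on both molecules")
        best: PairContact | None = None
        for ring_a in mol_a.rings:
            ca, na = ring_plane(frame, ring_a)
            for ring_b in mol_b.rings:
                cb, nb = ring_plane(frame, ring_b)
                sep = min_image_vector(cb - ca, frame.box)
                dist = float(np.linalg.norm(sep))
                conformer, gamma, offset = _classify_geometry(sep, dist, na, nb, criteria)
                if dist < criteria.cutoff_for(conformer):
                    if best is None or dist < best.distance:
                        best = PairContact(mol_a.molecule_id, mol_b.molecule_id,
                                           conformer, dist, gamma, offset)
        return best

    ca, na = _molecule_plane(frame, mol_a)
    cb, nb = _molecule_plane(frame, mol_b)
    pa = molecule_centroid(frame, mol_a)
    pb = molecule_centroid(frame, mol_b)
    sep = min_image_vector(pb - pa, frame.box)
    dist = float(np.linalg.norm(sep))
    conformer, gamma, offset = _classify_geometry(sep, dist, na, nb, criteria)
    if dist < criteria.cutoff_for(conformer):
        return PairContact(mol_a.molecule_id, mol_b.molecule_id, conformer, dist, gamma, offset)
    return None


# ---------------------------------------------------------------------------
# clustering and census

def cluster_frame(frame: Frame, molecules: Sequence[MoleculeTopology],
                  criteria: StackingCriteria = StackingCriteria()) -> ClusterSet:
    """Aggregates of a frame: connected components of the stacked-contact graph."""
    if not molecules:
        raise ValueError("need at least one molecule")
    graph = nx.Graph()
    graph.add_nodes_from(m.molecule_id for m in molecules)
    for i, ma in enumerate(molecules):
        for mb in molecules[i + 1:]:
            if classify_pair(frame, ma, mb, criteria) is not None:
                graph.add_edge(ma.molecule_id, mb.molecule_id)
    comps = tuple(frozenset(c) for c in nx.connected_components(graph))
    return ClusterSet(time=frame.time, clusters=comps, n_molecules=len(molecules))


def cluster_points_by_distance(time: float, ids: Sequence[str], points: np.ndarray,
                               box: np.ndarray, cutoff: float) -> ClusterSet:
    """Single-cutoff distance clustering of point particles (no conformer typing).

    Used by the stochastic association simulator, where particles carry no
    ring geometry and a contact is simply a separation below the well range.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    pts = np.asarray(points, float)
    for i in range(len(ids)):
        d = np.linalg.norm(min_image_vector(pts[i + 1:] - pts[i], box), axis=1)
        for j in np.nonzero(d < cutoff)[0]:
            graph.add_edge(ids[i], ids[i + 1 + j])
    comps = tuple(frozenset(c) for c in nx.connected_components(graph))
    return ClusterSet(time=time, clusters=comps, n_molecules=len(ids))


def census(clusters: ClusterSet) -> AggregateCensus:
    """Percent-of-molecules census of one frame's cluster partition."""
    if clusters.n_molecules == 0:
        raise ValueError("census of an empty frame is undefined")
    return AggregateCensus(time=clusters.time, n_molecules=clusters.n_molecules,
                           counts=clusters.size_counts())


def census_timeseries(traj: Trajectory, checkpoints: Sequence[float],
                      criteria: StackingCriteria = StackingCriteria()) -> list[AggregateCensus]:
    """Census at each checkpoint time, using the nearest stored frame.

    Checkpoints must lie within the trajectory's time span; the time delta to
    the matched frame is logged.
    """
    if not traj.frames:
        raise ValueError("empty trajectory")
    times = traj.times
    out = []
    for t in checkpoints:
        if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
            raise ValueError(f"checkpoint {t} outside trajectory span [{times[0]}, {times[-1]}]")
        idx = int(np.argmin(np.abs(times - t)))
        delta = abs(times[idx] - t)
        if delta > 1e-9:
            logger.info("checkpoint %g matched to frame t=%g (delta %g)", t, times[idx], delta)
        out.append(census(cluster_frame(traj.frames[idx], traj.topology, criteria)))
    return out


def pair_distance_trace(traj: Trajectory, mol_a: str, mol_b: str,
                        criteria: StackingCriteria = StackingCriteria()
                        ) -> tuple[np.ndarray, dict[str, float]]:
    """Per-frame minimum-image centroid distance of a molecule pair.

    Returns the distance series and, for each conformer cutoff, the fraction
    of frames with separation below it — a proxy for the pair's bound-state
    occupancy in a dynamic aggregation/segregation equilibrium.
    """
    if mol_a == mol_b:
        raise ValueError("pair trace needs two distinct molecules")
    ma, mb = traj.molecule(mol_a), traj.molecule(mol_b)
    dists = np.asarray([
        min_image_distance(molecule_centroid(f, ma), molecule_centroid(f, mb), f.box)
        for f in traj.frames])
    fractions = {
        "face-to-face": float(np.mean(dists < criteria.cutoff_f2f)),
        "offset-face-to-face": float(np.mean(dists < criteria.cutoff_offset)),
        "edge-to-face": float(np.mean(dists < criteria.cutoff_e2f)),
    }
    return dists, fractions


def detect_equilibrium(series: Sequence[AggregateCensus], window: int = 2,
                       tol: float = 5.0) -> float | None:
    """Earliest checkpoint from which all species percentages stay within ``tol``.

    A checkpoint qualifies when, over the remainder of the series (at least
    ``window`` entries), each species' percentage spans ≤ tol percentage
    points.  Returns its time, or None if the series never settles.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    keys = ("monomer", "dimer", "trimer", "polymer")
    values = {k: np.asarray([c.percentages[k] for c in series]) for k in keys}
    for i in range(len(series) - window + 1):
        if all(values[k][i:].max() - values[k][i:].min() <= tol for k in keys):
            return series[i].time
    return None


# ---------------------------------------------------------------------------
# hydrogen bonds

def count_hbonds(frame: Frame, donors: Iterable[tuple[int, int]],
                 acceptors: Iterable[int], d_max: float = 3.5,
                 angle_min: float = 130.0) -> int:
    """Geometric hydrogen-bond count: H···A ≤ d_max and D–H···A angle ≥ angle_min.

    ``donors`` are (D, H) atom-index pairs; ``acceptors`` are acceptor atom
    indices.  Distances and angle vectors use the minimum-image convention.
    """
    count = 0
    acceptors = list(acceptors)
    for d_idx, h_idx in donors:
        if h_idx is None or h_idx < 0 or h_idx >= frame.coords.shape[0]:
            raise ValueError(f"donor {d_idx}: missing or invalid hydrogen index {h_idx}")
        h = frame.coords[h_idx]
        to_d = min_image_vector(frame.coords[d_idx] - h, frame.box)
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            to_a = min_image_vector(frame.coords[a_idx] - h, frame.box)
            dist = float(np.linalg.norm(to_a))
            if dist > d_max or dist < 1e-12:
                continue
            cosang = np.dot(to_d, to_a) / (np.linalg.norm(to_d) * dist)
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle >= angle_min:
                count += 1
    return count
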