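"""Delaunay tessellation of C-alpha traces with a long-edge filter.

A Delaunay tessellation of the C-alpha point set partitions the convex
hull of a structure into tetrahedra whose circumspheres contain no other
point; each tetrahedron objectively identifies four nearest-neighbor
residues.  Tetrahedra containing any edge longer than a cutoff (12 Å by
default) are discarded so that only physically plausible quadruplet
contacts remain.  The retained tetrahedra define the contact graph,
per-position incidence, and surface/undersurface/buried depth classes
used throughout the toolkit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .structure_io import CoarseStructure

log = logging.getLogger(__name__)

DEFAULT_EDGE_CUTOFF = 12.0  # Å

#: Seed of the deterministic fallback perturbation for degenerate inputs.
_JOGGLE_SEED = 20180529
_JOGGLE_SCALE = 1e-6  # Å


class TessellationError(ValueError):
    """Raised when a point set cannot be tessellated."""


@dataclass(frozen=True)
class Tetrahedron:
    """One retained tetrahedron: sorted vertex ids plus its geometry."""

    vertex_ids: tuple[int, int, int, int]
    volume: float
    tetrahedrality: float
    max_edge: float

    def edges(self) -> list[tuple[int, int]]:
        return list(combinations(self.vertex_ids, 2))


def tetra_geometry(coords: np.ndarray) -> tuple[float, float]:
    """Volume (Å³) and tetrahedrality of four points.

    Volume is |(b−a)·((c−a)×(d−a))| / 6.  Tetrahedrality is the
    normalized edge-length variance

        T = Σ_{i<j} (l_i − l_j)² / (15 · l̄²),

    zero for a regular tetrahedron and growing with distortion.  Coplanar
    points give volume 0 (degenerate; callers may flag it).
    """
    c = np.asarray(coords, dtype=float)
    if c.shape != (4, 3):
        raise ValueError("tetra_geometry expects four 3-vectors")
    a, b, cc, d = c
    volume = abs(np.dot(b - a, np.cross(cc - a, d - a))) / 6.0
    lengths = np.array([np.linalg.norm(c[i] - c[j]) for i, j in combinations(range(4), 2)])
    lbar = lengths.mean()
    if lbar == 0.0:
        return 0.0, 0.0
    diffs = lengths[:, None] - lengths[None, :]
    # Σ_{i<j}(l_i - l_j)^2 = half the full symmetric sum
    tetrahedrality = float((diffs ** 2).sum() / 2.0 / (15.0 * lbar ** 2))
    return float(volume), tetrahedrality


@dataclass
class Tessellation:
    """Filtered Delaunay tessellation of a coarse structure."""

    structure: CoarseStructure
    tetrahedra: list[Tetrahedron]
    edge_cutoff: float = DEFAULT_EDGE_CUTOFF
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    incident: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.edges:
            edge_set: set[tuple[int, int]] = set()
            for t in self.tetrahedra:
                edge_set.update(t.edges())
            self.edges = frozenset(edge_set)
        if not self.incident:
            inc: dict[int, list[int]] = {}
            for ti, t in enumerate(self.tetrahedra):
                for v in t.vertex_ids:
                    inc.setdefault(v, []).append(ti)
            self.incident = {v: tuple(ts) for v, ts in inc.items()}

    def neighbor_positions(self, pos: int) -> set[int]:
        """Positions sharing a retained edge with ``pos`` (never ``pos`` itself)."""
        if not 0 <= pos < len(self.structure):
            raise KeyError(f"position {pos} not in structure of size {len(self.structure)}")
        out: set[int] = set()
        for a, b in self.edges:
            if a == pos:
                out.add(b)
            elif b == pos:
                out.add(a)
        return out

    def incident_tetrahedra(self, pos: int) -> list[Tetrahedron]:
        return [self.tetrahedra[i] for i in self.incident.get(pos, ())]


def tessellate(structure: CoarseStructure,
               edge_cutoff: float = DEFAULT_EDGE_CUTOFF) -> Tessellation:
    """Delaunay-tessellate a structure and drop long-edged tetrahedra.

    Any tetrahedron containing an edge longer than ``edge_cutoff`` is
    discarded whole: downstream scoring is per-tetrahedron, and a
    tetrahedron with a missing edge would not be scoreable.  Degenerate
    (cospherical/coplanar-heavy) inputs are retried once with a tiny,
    seed-fixed perturbation, which is logged.
    """
    coords = structure.coords
    if len(coords) < 4:
        raise TessellationError("tessellation undefined: fewer than 4 sites")
    try:
        delaunay = Delaunay(coords)
    except QhullError:
        rng = np.random.default_rng(_JOGGLE_SEED)
        jitter = rng.normal(scale=_JOGGLE_SCALE, size=coords.shape)
        log.warning("degenerate point set: applying deterministic %g Å joggle",
                    _JOGGLE_SCALE)
        try:
            delaunay = Delaunay(coords + jitter)
        except QhullError as exc:
            raise TessellationError(f"tessellation undefined: {exc}") from exc
    if delaunay.simplices.size == 0:
        raise TessellationError("tessellation undefined: no tetrahedra (coplanar input?)")

    tetrahedra: list[Tetrahedron] = []
    for simplex in delaunay.simplices:
        ids = tuple(sorted(int(i) for i in simplex))
        pts = coords[list(ids)]
        edge_lengths = [np.linalg.norm(pts[i] - pts[j])
                        for i, j in combinations(range(4), 2)]
        max_edge = float(max(edge_lengths))
        if max_edge > edge_cutoff:
            continue
        volume, tetrahedrality = tetra_geometry(pts)
        tetrahedra.append(Tetrahedron(ids, volume, tetrahedrality, max_edge))
    tetrahedra.sort(key=lambda t: t.vertex_ids)
    return Tessellation(structure, tetrahedra, edge_cutoff)


def classify_depth(tess: Tessellation) -> tuple[dict[int, str], dict[int, int]]:
    """Surface / undersurface / buried classes plus surface-contact counts.

    Surface positions are vertices of the convex hull of the full point
    set; undersurface positions share at least one retained edge with a
    surface position; everything else is buried.  The contact count is
    the number of retained edges a position has to surface positions.
    """
    coords = tess.structure.coords
    try:
        hull = ConvexHull(coords)
        surface = set(int(v) for v in hull.vertices)
    except QhullError as exc:
        raise TessellationError(f"convex hull undefined: {exc}") from exc
    contacts = {i: 0 for i in range(len(coords))}
    neighbor_sets: dict[int, set[int]] = {i: set() for i in range(len(coords))}
    for a, b in tess.edges:
        neighbor_sets[a].add(b)
        neighbor_sets[b].add(a)
    classes: dict[int, str] = {}
    for i in range(len(coords)):
        contacts[i] = sum(1 for n in neighbor_sets[i] if n in surface)
        if i in surface:
            classes[i] = "surface"
        elif contacts[i] > 0:
            classes[i] = "undersurface"
        else:
            classes[i] = "buried"
    return classes, contacts


def tessellation_to_dict(tess: Tessellation) -> dict:
    """JSON-serializable summary of a tessellation."""
    classes, contacts = classify_depth(tess)
    return {
        "source_id": tess.structure.source_id,
        "edge_cutoff": tess.edge_cutoff,
        "n_sites": len(tess.structure),
        "sites": [
            {"flat_index": s.flat_index, "chain": s.chain_id,
             "resnum": s.author_resnum, "res_type": s.res_type,
             "depth": classes[s.flat_index],
             "surface_contacts": contacts[s.flat_index]}
            for s in tess.structure.sites
        ],
        "tetrahedra": [
            {"vertices": list(t.vertex_ids), "volume": t.volume,
             "tetrahedrality": t.tetrahedrality, "max_edge": t.max_edge}
            for t in tess.tetrahedra
        ],
    }
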