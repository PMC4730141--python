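"""Alpha-complex detection and measurement of pockets and internal cavities.

The detector Delaunay-tetrahedralizes the atom centers and keeps a
tetrahedron in the alpha complex when its circumsphere radius is at most
the mean van der Waals radius of its four atoms plus the probe radius;
the complement ("empty" tetrahedra, where a probe sphere can sit) is
segmented into connected components across shared facets that are wide
enough for the probe (facet circumradius above the same threshold).
A component's open facets on the convex hull are its mouths: their
edge-connected patches are counted, and a component with no open hull
facet is an insulated internal cavity.  Volumes are probe-excluded
Monte-Carlo measures of the tetrahedron union minus the inflated atom
spheres.

This is a deliberately simple unweighted variant of the alpha-shape /
discrete-flow pocket computation used by tools such as CASTp: with
near-uniform atomic radii it recovers the same pocket topology, but no
claim is made about matching solvent-accessible pocket volumes of a
weighted triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import Delaunay

from .structures import Structure

DEFAULT_PROBE_RADIUS = 1.4

#: volume classes for mouth-bearing cavities (Angstrom^3 boundaries)
DENT_CRACK_BOUNDARY = 500.0
CRACK_CREVICE_BOUNDARY = 1000.0


@dataclass(frozen=True)
class GeometryParams:
    """Tunable parameters of the cavity detector."""

    probe_radius: float = DEFAULT_PROBE_RADIUS
    volume_mc_samples: int = 200_000
    min_tetra_volume: float = 5.0  # drop sliver components below this total (A^3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.volume_mc_samples < 1:
            raise ValueError("volume_mc_samples must be >= 1")


@dataclass
class Cavity:
    """One detected void: member tetrahedra, topology and measurements."""

    id: int
    tetrahedra: np.ndarray  # simplex indices into the Delaunay triangulation
    mouth_count: int
    lining_residues: FrozenSet[int]
    tetra_volume: float  # exact union-of-tetrahedra volume (no sphere exclusion)
    volume: Optional[float] = None  # probe-excluded MC volume
    volume_se: Optional[float] = None
    area: Optional[float] = None
    area_se: Optional[float] = None
    class_label: Optional[str] = None


@dataclass
class AlphaComplex:
    """Labeled Delaunay complex of a structure."""

    structure: Structure
    params: GeometryParams
    delaunay: Delaunay
    in_alpha: np.ndarray  # bool per tetrahedron
    tetra_circumradius: np.ndarray
    tetra_circumcenter: np.ndarray
    facet_open: np.ndarray  # (n_tetra, 4) facet wide enough for the probe
    tetra_volumes: np.ndarray

    @property
    def n_tetra(self) -> int:
        return len(self.in_alpha)


def _circumspheres(points: np.ndarray, simplices: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Circumsphere centers and radii of tetrahedra; degenerate ones get +inf."""
    a = points[simplices[:, 0]]
    rhs = np.empty((len(simplices), 3))
    mat = np.empty((len(simplices), 3, 3))
    for k in range(3):
        b = points[simplices[:, k + 1]]
        mat[:, k, :] = 2 * (b - a)
        rhs[:, k] = (b**2).sum(axis=1) - (a**2).sum(axis=1)
    radii = np.full(len(simplices), np.inf)
    centers = np.full((len(simplices), 3), np.nan)
    det = np.abs(np.linalg.det(mat))
    ok = det > 1e-12
    if ok.any():
        sol = np.linalg.solve(mat[ok], rhs[ok][..., None])[..., 0]
        centers[ok] = sol
        radii[ok] = np.linalg.norm(sol - a[ok], axis=1)
    return centers, radii


def _triangle_circumradius(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    a = np.linalg.norm(p1 - p0, axis=-1)
    b = np.linalg.norm(p2 - p1, axis=-1)
    c = np.linalg.norm(p0 - p2, axis=-1)
    cross = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(cross, axis=-1)  # twice the area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (2.0 * area2)
    return np.where(area2 > 1e-12, r, np.inf)


def _tetra_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    m = np.stack(
        [points[simplices[:, k]] - a for k in (1, 2, 3)], axis=1
    )
    return np.abs(np.linalg.det(m)) / 6.0


def build_alpha_complex(
    structure: Structure,
    params: Optional[GeometryParams] = None,
    jitter: bool = False,
) -> AlphaComplex:
    """Delaunay tetrahedralization labeled by the probe-augmented alpha test.

    A tetrahedron is inside the alpha complex iff its circumsphere
    radius is at most the mean radius of its four atoms plus the probe
    radius; a shared facet is "open" (probe-passable) iff its triangle
    circumradius exceeds the analogous facet threshold.  Coplanar input
    raises; ``jitter=True`` applies a seeded 1e-6 A perturbation first.
    """
    if params is None:
        params = GeometryParams()
    pts = structure.coords
    if len(pts) < 4:
        raise ValueError("need at least 4 atoms for tetrahedralization")
    if jitter:
        rng = np.random.default_rng(params.seed)
        pts = pts + rng.normal(scale=1e-6, size=pts.shape)
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # qhull degeneracy
        raise ValueError(
            "degenerate (coplanar) atom coordinates; retry with jitter=True"
        ) from exc
    if tri.simplices.size == 0:
        raise ValueError("triangulation produced no tetrahedra (coplanar input?)")

    radii = structure.radii
    centers, circum = _circumspheres(pts, tri.simplices)
    thresh_tet = radii[tri.simplices].mean(axis=1) + params.probe_radius
    in_alpha = circum <= thresh_tet

    # facet f of tetra i is the triangle opposite vertex f
    n_t = len(tri.simplices)
    facet_open = np.zeros((n_t, 4), dtype=bool)
    for f in range(4):
        cols = [k for k in range(4) if k != f]
        v = tri.simplices[:, cols]
        r_f = _triangle_circumradius(pts[v[:, 0]], pts[v[:, 1]], pts[v[:, 2]])
        thresh_f = radii[v].mean(axis=1) + params.probe_radius
        facet_open[:, f] = r_f > thresh_f

    return AlphaComplex(
        structure=structure,
        params=params,
        delaunay=tri,
        in_alpha=in_alpha,
        tetra_circumradius=circum,
        tetra_circumcenter=centers,
        facet_open=facet_open,
        tetra_volumes=_tetra_volumes(pts, tri.simplices),
    )


def _mouth_patches(mouth_facets: List[Tuple[int, int]], simplices: np.ndarray) -> int:
    """Count edge-connected patches among hull facets (tetra, facet) pairs."""
    if not mouth_facets:
        return 0
    facet_vertices = []
    for t, f in mouth_facets:
        verts = [simplices[t, k] for k in range(4) if k != f]
        facet_vertices.append(frozenset(verts))
    parent = list(range(len(mouth_facets)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edge_owner: Dict[FrozenSet[int], int] = {}
    for i, verts in enumerate(facet_vertices):
        vs = sorted(verts)
        for e in ((vs[0], vs[1]), (vs[0], vs[2]), (vs[1], vs[2])):
            key = frozenset(e)
            if key in edge_owner:
                ra, rb = find(edge_owner[key]), find(i)
                parent[ra] = rb
            else:
                edge_owner[key] = i
    return len({find(i) for i in range(len(mouth_facets))})


def find_voids(complex_: AlphaComplex) -> List[Cavity]:
    """Connected components of probe-admitting empty space, with mouths.

    Empty tetrahedra are joined across probe-passable (open) shared
    facets.  A component's mouths are the edge-connected patches of its
    open convex-hull facets; a component with none is an insulated
    internal cavity.  Sliver components whose summed tetrahedron volume
    falls below ``params.min_tetra_volume`` are discarded.
    """
    tri = complex_.delaunay
    empty = ~complex_.in_alpha
    n_t = complex_.n_tetra
    parent = np.arange(n_t)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for i in np.nonzero(empty)[0]:
        for f in range(4):
            j = tri.neighbors[i, f]
            if j >= 0 and empty[j] and complex_.facet_open[i, f]:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[ri] = rj

    groups: Dict[int, List[int]] = {}
    for i in np.nonzero(empty)[0]:
        groups.setdefault(find(int(i)), []).append(int(i))

    from scipy.spatial import cKDTree

    pts = complex_.structure.coords
    inflated = complex_.structure.radii + complex_.params.probe_radius
    kdt = cKDTree(pts)

    cavities: List[Cavity] = []
    for members in groups.values():
        tet = np.asarray(sorted(members))
        tet_vol = float(complex_.tetra_volumes[tet].sum())
        if tet_vol < complex_.params.min_tetra_volume:
            continue
        # sliver screen: a genuine void must have somewhere for the probe
        # to sit.  Sliver components (flat tetrahedra wedged between
        # atoms) have exactly zero probe-free measure, so a short seeded
        # stratified sample never clears the inflated spheres there.
        rng = np.random.default_rng(complex_.params.seed + 7)
        vols = complex_.tetra_volumes[tet]
        alloc = np.maximum((400 * vols / vols.sum()).astype(int), 4)
        holds_probe = False
        for t, n in zip(tet, alloc):
            samples = _sample_in_tetra(rng, pts[tri.simplices[t]], int(n))
            d, i = kdt.query(samples, k=1)
            if np.any(d > inflated[i]):
                holds_probe = True
                break
        if not holds_probe:
            continue
        member_set = set(int(t) for t in tet)
        mouth_facets = []
        n_closed_boundary = 0
        for t in tet:
            for f in range(4):
                j = int(tri.neighbors[t, f])
                if j < 0 and complex_.facet_open[t, f]:
                    mouth_facets.append((int(t), f))
                elif j < 0 or j not in member_set:
                    n_closed_boundary += 1
        # exterior screen: a component whose boundary is dominated by
        # open hull facets is open space outside the molecular body
        # (e.g. the gap amid a handful of atoms), not a pocket
        if len(mouth_facets) > n_closed_boundary:
            continue
        mouth_count = _mouth_patches(mouth_facets, tri.simplices)
        verts = np.unique(tri.simplices[tet])
        lining = frozenset(int(r) for r in complex_.structure.residue_indices[verts])
        cavities.append(
            Cavity(
                id=0,
                tetrahedra=tet,
                mouth_count=mouth_count,
                lining_residues=lining,
                tetra_volume=tet_vol,
            )
        )
    # deterministic ordering: largest first, ties by smallest simplex index
    cavities.sort(key=lambda c: (-c.tetra_volume, int(c.tetrahedra[0])))
    for k, cav in enumerate(cavities, start=1):
        cav.id = k
    return cavities


def _sample_in_tetra(
    rng: np.random.Generator, verts: np.ndarray, n: int
) -> np.ndarray:
    """Uniform points inside one tetrahedron (Dirichlet barycentric weights)."""
    bary = rng.dirichlet((1.0, 1.0, 1.0, 1.0), size=n)
    return bary @ verts


def measure_cavity(
    cavity: Cavity,
    complex_: AlphaComplex,
    params: Optional[GeometryParams] = None,
) -> Cavity:
    """Monte-Carlo probe-excluded volume and mouth-free surface area.

    Sampling is stratified over member tetrahedra proportionally to
    their volume; a point counts toward the cavity volume when it clears
    every inflated atom sphere (atom radius + probe radius).  The area
    sums the sphere-free fraction of the cavity's boundary facets.
    """
    if params is None:
        params = complex_.params
    if params.volume_mc_samples < 10_000:
        raise ValueError("at least 1e4 Monte-Carlo samples required for reported volumes")
    if len(cavity.tetrahedra) == 0:
        raise ValueError("cavity has no tetrahedra")
    from scipy.spatial import cKDTree

    tri = complex_.delaunay
    pts = complex_.structure.coords
    inflated = complex_.structure.radii + params.probe_radius
    kdt = cKDTree(pts)
    r_uniformish = float(inflated.max())
    rng = np.random.default_rng(params.seed)

    vols = complex_.tetra_volumes[cavity.tetrahedra]
    total_vol = vols.sum()
    alloc = np.maximum(
        np.round(params.volume_mc_samples * vols / total_vol).astype(int), 8
    )
    est = 0.0
    var = 0.0
    for t, v, n in zip(cavity.tetrahedra, vols, alloc):
        verts = pts[tri.simplices[t]]
        samples = _sample_in_tetra(rng, verts, int(n))
        d, i = kdt.query(samples, k=1)
        p = float((d > inflated[i]).mean())
        est += v * p
        var += (v**2) * p * (1 - p) / n

    # boundary facets: shared with non-member tetra or on the hull
    member = set(int(t) for t in cavity.tetrahedra)
    area_est = 0.0
    area_var = 0.0
    for t in cavity.tetrahedra:
        for f in range(4):
            j = int(tri.neighbors[t, f])
            if j in member:
                continue
            verts = pts[[tri.simplices[t, k] for k in range(4) if k != f]]
            tri_area = 0.5 * np.linalg.norm(
                np.cross(verts[1] - verts[0], verts[2] - verts[0])
            )
            if tri_area <= 0:
                continue
            n = 64
            w = rng.random((n, 2))
            flip = w.sum(axis=1) > 1
            w[flip] = 1 - w[flip]
            samples = (
                verts[0]
                + np.outer(w[:, 0], verts[1] - verts[0])
                + np.outer(w[:, 1], verts[2] - verts[0])
            )
            d, i = kdt.query(samples, k=1)
            p = float((d > inflated[i]).mean())
            area_est += tri_area * p
            area_var += (tri_area**2) * p * (1 - p) / n

    cavity.volume = float(est)
    cavity.volume_se = float(np.sqrt(var))
    cavity.area = float(area_est)
    cavity.area_se = float(np.sqrt(area_var))
    cavity.class_label = classify_cavity(cavity.volume, cavity.mouth_count)
    return cavity


def lining_residues(cavity: Cavity, complex_: AlphaComplex) -> FrozenSet[int]:
    """Residues owning any atom that is a vertex of a member tetrahedron."""
    verts = np.unique(complex_.delaunay.simplices[cavity.tetrahedra])
    return frozenset(int(r) for r in complex_.structure.residue_indices[verts])


def classify_cavity(volume: float, mouth_count: int) -> str:
    """Volume class of a cavity: internal / dent / crack / crevice.

    A cavity with no mouth is an insulated internal cavity regardless of
    volume; mouth-bearing cavities are dents below 500 A^3, cracks from
    500 (inclusive) to 1000, crevices from 1000 (inclusive) upward.
    """
    if volume < 0:
        raise ValueError("volume must be nonnegative")
    if mouth_count == 0:
        return "internal"
    if volume < DENT_CRACK_BOUNDARY:
        return "dent"
    if volume < CRACK_CREVICE_BOUNDARY:
        return "crack"
    return "crevice"


CLASS_LETTER = {"dent": "d", "crack": "k", "crevice": "v", "internal": "i"}


def detect_cavities(
    structure: Structure,
    params: Optional[GeometryParams] = None,
    jitter: bool = False,
) -> List[Cavity]:
    """Full detector: alpha complex, void segmentation, measurement, class."""
    complex_ = build_alpha_complex(structure, params, jitter=jitter)
    cavities = find_voids(complex_)
    for cav in cavities:
        measure_cavity(cav, complex_)
    return cavities


def cavities_to_table(cavities: Sequence[Cavity], structure: Structure):
    """TSV-ready table (one row per cavity)."""
    import pandas as pd

    rows = []
    for c in cavities:
        rows.append(
            {
                "id": c.id,
                "class": c.class_label,
                "volume": c.volume,
                "volume_se": c.volume_se,
                "area": c.area,
                "mouths": c.mouth_count,
                "lining_residues": ",".join(
                    f"{structure.chains[0]}:{r}" for r in sorted(c.lining_residues)
                ),
            }
        )
    return pd.DataFrame(rows)
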