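"""Seeded synthetic fixtures: trees, codon alignments, atom-cloud structures.

The generator defines the verification conditions for the whole
pipeline.  Codon alignments are evolved column-by-column down a rooted
tree with planted per-column selection regimes (hotspot / background /
conserved nonsynonymous-to-synonymous rate ratios), keeping the true
ancestral sequences and the full mutation-event log so that selection
statistics can be checked against exact ground truth.  Structures are
atom clouds with voids of known topology: a sealed spherical cage (one
internal cavity, no mouth), an aperture cage (one mouth), a surface
dent, and a convex blob (no void).  An independent Monte-Carlo oracle
measures the enclosed, probe-excluded void volume for each structure so
that the alpha-complex cavity detector can be validated against a
second, unrelated implementation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .alignment import CodonAlignment
from .genetics import NUCLEOTIDES, GeneticCode, standard_code
from .phylo import (
    iter_branches,
    label_internal_nodes,
    node_name,
    scale_tree_length,
    write_tree,
)
from .structures import Structure, write_column_map

DEFAULT_PROBE_RADIUS = 1.4  # water probe
DEFAULT_ATOM_RADIUS = 1.8  # united-atom carbon


# ---------------------------------------------------------------------------
# simulation settings


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one simulated codon alignment.

    ``omega_*`` are nonsynonymous acceptance probabilities relative to
    synonymous changes (the planted dN/dS regime per column class);
    ``total_tree_length`` is in expected proposed substitutions per
    nucleotide site summed over all branches.
    """

    n_leaves: int = 8
    tree_shape: str = "yule"
    total_tree_length: float = 1.5
    n_columns: int = 300
    hotspot_columns: frozenset = frozenset()
    conserved_columns: frozenset = frozenset()
    omega_hotspot: float = 5.0
    omega_background: float = 0.2
    omega_conserved: float = 0.0
    base_frequencies: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("n_leaves must be >= 3")
        if self.tree_shape not in ("yule", "balanced"):
            raise ValueError(f"unknown tree_shape {self.tree_shape!r}")
        if self.total_tree_length < 0:
            raise ValueError("total_tree_length must be >= 0")
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")
        hot, cons = frozenset(self.hotspot_columns), frozenset(self.conserved_columns)
        if hot & cons:
            raise ValueError("hotspot and conserved column sets must be disjoint")
        for c in hot | cons:
            if not 1 <= c <= self.n_columns:
                raise ValueError(f"column index {c} outside [1, {self.n_columns}]")
        if self.omega_hotspot <= 0 or self.omega_background <= 0:
            raise ValueError("omega_hotspot and omega_background must be > 0")
        if self.omega_conserved < 0:
            raise ValueError("omega_conserved must be >= 0")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")

    def regime_of(self, column: int) -> str:
        if column in self.hotspot_columns:
            return "hotspot"
        if column in self.conserved_columns:
            return "conserved"
        return "background"

    def omega_of(self, column: int) -> float:
        return {
            "hotspot": self.omega_hotspot,
            "background": self.omega_background,
            "conserved": self.omega_conserved,
        }[self.regime_of(column)]


@dataclass(frozen=True)
class StructureSpec:
    """Conditions for one synthetic atom-cloud structure."""

    kind: str = "sealed_cage"
    cage_radius: float = 8.0
    n_shell_atoms: int = 200
    aperture_solid_angle: Optional[float] = None  # steradians
    atom_radius: float = DEFAULT_ATOM_RADIUS
    probe_radius: float = DEFAULT_PROBE_RADIUS
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = ("sealed_cage", "aperture_cage", "surface_dent", "convex_blob")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.cage_radius <= self.atom_radius:
            raise ValueError("cage_radius must exceed atom_radius")
        if self.n_shell_atoms < 12:
            raise ValueError("n_shell_atoms must be >= 12")
        if self.aperture_solid_angle is not None and self.kind != "aperture_cage":
            raise ValueError("aperture_solid_angle only applies to aperture_cage")
        if self.kind == "aperture_cage":
            omega = self.aperture_solid_angle
            if omega is None or not 0 < omega < 2 * np.pi:
                raise ValueError("aperture_cage needs aperture_solid_angle in (0, 2*pi)")


@dataclass
class GroundTruth:
    """Recorded truth for a simulated alignment or structure."""

    true_ancestral_sequences: Dict[str, str] = field(default_factory=dict)
    true_column_regime: Dict[int, str] = field(default_factory=dict)
    event_log: List[dict] = field(default_factory=list)
    reference_void_volume: Optional[float] = None
    reference_mouth_count: Optional[int] = None


# ---------------------------------------------------------------------------
# trees


def generate_tree(spec: SimulationSpec) -> dendropy.Tree:
    """Rooted binary tree with branch lengths summing to total_tree_length.

    ``yule`` grows the tree by repeated random tip splitting with
    exponential branch lengths; ``balanced`` splits leaf counts evenly
    with equal branch lengths.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = dendropy.TaxonNamespace([f"T{i+1}" for i in range(spec.n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)

    if spec.tree_shape == "balanced":

        def split(node: dendropy.Node, names: List[str]) -> None:
            if len(names) == 1:
                node.taxon = taxa.get_taxon(names[0])
                return
            mid = (len(names) + 1) // 2
            for part in (names[:mid], names[mid:]):
                child = node.new_child(edge_length=1.0)
                split(child, part)

        split(tree.seed_node, [t.label for t in taxa])
    else:  # yule
        tips = [tree.seed_node.new_child(edge_length=float(rng.exponential())) for _ in range(2)]
        while len(tips) < spec.n_leaves:
            idx = int(rng.integers(len(tips)))
            parent = tips.pop(idx)
            for _ in range(2):
                tips.append(parent.new_child(edge_length=float(rng.exponential())))
        order = rng.permutation(spec.n_leaves)
        for tip, k in zip(tips, order):
            tip.taxon = taxa.get_taxon(f"T{k+1}")

    if spec.total_tree_length > 0:
        scale_tree_length(tree, spec.total_tree_length)
    else:
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = 0.0
    label_internal_nodes(tree)
    return tree


# ---------------------------------------------------------------------------
# codon evolution


def _sample_root_sequence(
    rng: np.random.Generator, spec: SimulationSpec, code: GeneticCode
) -> List[str]:
    """Sense codons sampled with probability proportional to base-frequency products."""
    sense = code.sense_codons()
    pi = dict(zip(NUCLEOTIDES, spec.base_frequencies))
    weights = np.array([pi[c[0]] * pi[c[1]] * pi[c[2]] for c in sense])
    weights /= weights.sum()
    idx = rng.choice(len(sense), size=spec.n_columns, p=weights)
    return [sense[i] for i in idx]


def _evolve_codon(
    codon: str,
    t: float,
    omega: float,
    pi: np.ndarray,
    rng: np.random.Generator,
    code: GeneticCode,
    log: List[dict],
    branch: str,
    column: int,
) -> str:
    """Gillespie simulation of one codon along one branch.

    Nucleotide changes are proposed under an F81-style generator
    (target-frequency proportional, scaled to one expected proposal per
    site per unit time at neutrality).  Synonymous proposals are always
    accepted and proposals creating a stop codon are always rejected.
    For omega <= 1 nonsynonymous proposals are accepted with probability
    omega (thinning); for omega > 1 thinning cannot raise the rate, so
    the nonsynonymous proposal rate itself is scaled by omega instead
    (the two constructions realize the same dN/dS law).
    """
    mu = 1.0 - float((pi**2).sum())  # proposal-rate normalizer
    boost = max(omega, 1.0)  # rate scaling for positive selection
    elapsed = 0.0
    while True:
        bases = np.array([NUCLEOTIDES.index(b) for b in codon])
        # per-position, per-target proposal rates
        rates = np.zeros((3, 4))
        for p in range(3):
            for b in range(4):
                if b == bases[p]:
                    continue
                mutant = codon[:p] + NUCLEOTIDES[b] + codon[p + 1 :]
                w = 1.0
                if not code.is_stop(mutant) and code.translate_codon(
                    mutant
                ) != code.translate_codon(codon):
                    w = boost
                rates[p, b] = pi[b] / mu * w
        total = rates.sum()
        elapsed += rng.exponential(1.0 / total)
        if elapsed >= t:
            return codon
        flat = int(rng.choice(12, p=rates.ravel() / total))
        pos, target = divmod(flat, 4)
        mutant = codon[:pos] + NUCLEOTIDES[target] + codon[pos + 1 :]
        if code.is_stop(mutant):
            accepted = False
            syn = False
        else:
            syn = code.translate_codon(mutant) == code.translate_codon(codon)
            # omega > 1 is already in the proposal rate; omega <= 1 thins
            accepted = syn or (omega > 1.0) or (rng.random() < omega)
        log.append(
            {
                "branch": branch,
                "column": column,
                "position": pos + 1,
                "from": codon,
                "to": mutant,
                "synonymous": syn,
                "to_stop": code.is_stop(mutant),
                "accepted": accepted,
            }
        )
        if accepted:
            codon = mutant


def evolve_codon_alignment(
    tree: dendropy.Tree, spec: SimulationSpec, code: Optional[GeneticCode] = None
) -> Tuple[CodonAlignment, GroundTruth]:
    """Simulate codon substitution down the tree with planted regimes.

    Returns the leaf alignment and a :class:`GroundTruth` holding every
    internal node's true sequence, the per-column regime and the full
    accepted/rejected mutation-event log.
    """
    if code is None:
        code = standard_code()
    rng = np.random.default_rng(spec.seed + 1)
    pi = np.asarray(spec.base_frequencies)
    root_codons = _sample_root_sequence(rng, spec, code)
    label_internal_nodes(tree)

    truth = GroundTruth(
        true_column_regime={c: spec.regime_of(c) for c in range(1, spec.n_columns + 1)}
    )
    sequences: Dict[str, List[str]] = {node_name(tree.seed_node): root_codons}
    leaf_rows: Dict[str, str] = {}

    for parent, child in iter_branches(tree):
        t = child.edge.length or 0.0
        parent_codons = sequences[node_name(parent)]
        child_name = node_name(child)
        child_codons = []
        for col in range(1, spec.n_columns + 1):
            codon = parent_codons[col - 1]
            if t > 0:
                codon = _evolve_codon(
                    codon,
                    t,
                    spec.omega_of(col),
                    pi,
                    rng,
                    code,
                    truth.event_log,
                    child_name,
                    col,
                )
            child_codons.append(codon)
        sequences[child_name] = child_codons
        if child.is_leaf():
            leaf_rows[child_name] = "".join(child_codons)

    for name, codons in sequences.items():
        if name not in leaf_rows:
            truth.true_ancestral_sequences[name] = "".join(codons)
    return CodonAlignment(leaf_rows), truth


# ---------------------------------------------------------------------------
# structures


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic Fibonacci lattice)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0, 1))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _ball_lattice(radius: float, spacing: float) -> np.ndarray:
    """Cubic-lattice points within a ball (deterministic dense packing)."""
    k = int(np.floor(radius / spacing))
    axis = np.arange(-k, k + 1) * spacing
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid[np.linalg.norm(grid, axis=1) <= radius]


def generate_structure(
    spec: StructureSpec,
    columns: Optional[Sequence[int]] = None,
    mc_samples: int = 1_000_000,
    oracle_seed: int = 20200101,
) -> Tuple[Structure, GroundTruth]:
    """Synthetic atom cloud with a void of known topology plus its oracle volume.

    Cage kinds place atoms on a Fibonacci lattice of radius
    ``cage_radius``; the aperture cage removes atoms inside the aperture
    cone around +z; the surface dent is a dense lattice ball with a
    spherical scoop removed at the surface; the convex blob is a dense
    lattice ball with no void.  Every atom is its own residue
    (1-based); ``columns`` optionally maps residue i to alignment column
    columns[i-1].  The reference void volume comes from the independent
    Monte-Carlo oracle (enclosed, probe-excluded space).
    """
    r_atom = spec.atom_radius
    if spec.kind in ("sealed_cage", "aperture_cage"):
        pts = _fibonacci_sphere(spec.n_shell_atoms) * spec.cage_radius
        if spec.kind == "aperture_cage":
            cos_theta = 1.0 - spec.aperture_solid_angle / (2 * np.pi)
            keep = pts[:, 2] / spec.cage_radius <= cos_theta
            pts = pts[keep]
        mouth_truth = 0 if spec.kind == "sealed_cage" else 1
    elif spec.kind == "surface_dent":
        spacing = 1.4 * r_atom
        pts = _ball_lattice(spec.cage_radius, spacing)
        # the scoop sphere is centred below the surface so that its
        # probe-free core stays inside the convex hull while the scoop
        # still breaks the surface (an open pocket, not a sealed void);
        # it must out-reach the probe-inflated atom radius to leave any
        # free space at all
        scoop_center = np.array([0.0, 0.0, 0.6 * spec.cage_radius])
        scoop_radius = 0.6 * spec.cage_radius
        pts = pts[np.linalg.norm(pts - scoop_center, axis=1) > scoop_radius]
        mouth_truth = 1
    else:  # convex_blob
        spacing = 1.4 * r_atom
        pts = _ball_lattice(spec.cage_radius, spacing)
        mouth_truth = 0

    n = len(pts)
    residues = np.arange(1, n + 1)
    col_map = None
    if columns is not None:
        if len(columns) < n:
            raise ValueError("need one alignment column per residue")
        col_map = {int(r): int(columns[i]) for i, r in enumerate(residues)}
    structure = Structure(
        coords=pts,
        radii=np.full(n, r_atom),
        residue_indices=residues,
        residue_to_column=col_map,
        name=spec.kind,
    )
    volume = mc_void_volume(
        structure.coords,
        structure.radii,
        probe_radius=spec.probe_radius,
        n_samples=mc_samples,
        seed=oracle_seed,
    )
    truth = GroundTruth(
        reference_void_volume=volume,
        reference_mouth_count=0 if spec.kind == "convex_blob" else mouth_truth,
    )
    if spec.kind == "convex_blob":
        truth.reference_void_volume = volume  # expected 0 by construction
    return structure, truth


def mc_void_volume(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_samples: int = 1_000_000,
    seed: int = 20200101,
    voxel: float = 0.3,
) -> float:
    """Monte-Carlo oracle for enclosed, probe-excluded void volume (A^3).

    A point belongs to the void iff it lies inside the convex hull of
    the atom centers, farther than (atom radius + probe radius) from
    every atom center, and is not connected to the outside: free space
    connectivity is resolved on a voxel grid by flood fill from the
    bounding-box border.  Entirely independent of the alpha-complex
    cavity detector.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 4:
        return 0.0
    inflated = np.asarray(radii, dtype=float) + probe_radius
    tree = cKDTree(coords)
    r_max = float(inflated.max())
    try:
        hull = Delaunay(coords)
    except Exception:
        return 0.0

    lo = coords.min(axis=0) - 2 * voxel
    hi = coords.max(axis=0) + 2 * voxel
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * voxel for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    # voxel is free if its center clears every inflated sphere
    dist, idx = tree.query(centers, k=1)
    free = dist > inflated[idx]
    free = free.reshape(tuple(shape))
    labels, n_lab = ndimage.label(free)
    border = set()
    for axis in range(3):
        border |= set(np.unique(np.take(labels, [0, -1], axis=axis)))
    border.discard(0)
    enclosed_mask = np.isin(labels, [l for l in range(1, n_lab + 1) if l not in border])
    if not enclosed_mask.any():
        return 0.0
    # grow by one voxel so that free sample points sitting in a blocked
    # boundary voxel are still attributed to the enclosed component
    enclosed_mask = ndimage.binary_dilation(enclosed_mask)

    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    inside_hull = hull.find_simplex(pts) >= 0
    d, i = tree.query(pts, k=1)
    outside_spheres = d > inflated[i]
    vox_idx = np.floor((pts - lo) / voxel).astype(int)
    vox_idx = np.clip(vox_idx, 0, shape - 1)
    in_enclosed = enclosed_mask[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]]
    hits = inside_hull & outside_spheres & in_enclosed
    box_volume = float(np.prod(hi - lo))
    return box_volume * hits.sum() / n_samples


# ---------------------------------------------------------------------------
# wired end-to-end scenario


@dataclass
class WiredScenario:
    """A fully wired synthetic study: sequences, tree, truth and structures.

    Cage structures are attached to tree nodes with residue-to-column
    maps that place their cavity-lining residues onto a chosen mix of
    hotspot, conserved and background columns, so the selection/cavity
    overlay has a known answer: every planted "cavity-opening" hotspot
    column lines a cavity, and a known set of purifying-selection
    columns lines cavities too (cavity-forming but conserved).
    """

    spec: SimulationSpec
    tree: dendropy.Tree
    alignment: CodonAlignment
    truth: GroundTruth
    structures: Dict[str, Tuple[Structure, GroundTruth]]
    cavity_hotspot_columns: frozenset
    cavity_conserved_columns: frozenset
    cavity_background_columns: frozenset

    @property
    def wired_columns(self) -> frozenset:
        return (
            self.cavity_hotspot_columns
            | self.cavity_conserved_columns
            | self.cavity_background_columns
        )


def wired_scenario(
    seed: int,
    n_leaves: int = 8,
    n_columns: int = 120,
    n_hotspot: int = 10,
    n_conserved: int = 20,
    n_conserved_lining: int = 5,
    n_background_lining: int = 15,
    n_structures: int = 3,
    cage_radius: float = 6.0,
    total_tree_length: float = 1.5,
    mc_samples: int = 120_000,
) -> WiredScenario:
    """Build the synthetic end-to-end study with cavity-wired columns.

    Hotspot columns occupy 1..n_hotspot and conserved columns follow;
    every structure is a sealed cage whose shell residues cycle through
    the wired column set (all hotspots, the first ``n_conserved_lining``
    conserved columns, and ``n_background_lining`` background columns).
    Structures are attached to the root and the first leaves in name
    order.
    """
    hot = frozenset(range(1, n_hotspot + 1))
    cons = frozenset(range(n_hotspot + 1, n_hotspot + n_conserved + 1))
    spec = SimulationSpec(
        n_leaves=n_leaves,
        n_columns=n_columns,
        hotspot_columns=hot,
        conserved_columns=cons,
        total_tree_length=total_tree_length,
        seed=seed,
    )
    tree = generate_tree(spec)
    alignment, truth = evolve_codon_alignment(tree, spec)

    cav_cons = frozenset(sorted(cons)[:n_conserved_lining])
    first_bg = n_hotspot + n_conserved + 1
    cav_bg = frozenset(range(first_bg, first_bg + n_background_lining))
    wired = sorted(hot | cav_cons | cav_bg)

    nodes = [node_name(tree.seed_node)] + sorted(
        node_name(l) for l in tree.leaf_node_iter()
    )[: n_structures - 1]
    structures: Dict[str, Tuple[Structure, GroundTruth]] = {}
    for k, node in enumerate(nodes):
        s_spec = StructureSpec(
            kind="sealed_cage",
            cage_radius=cage_radius,
            n_shell_atoms=max(112, 4 * len(wired)),
            seed=seed + k,
        )
        n_atoms = s_spec.n_shell_atoms
        columns = [wired[i % len(wired)] for i in range(n_atoms)]
        structures[node] = generate_structure(
            s_spec, columns=columns, mc_samples=mc_samples, oracle_seed=seed + 17 * k
        )
    return WiredScenario(
        spec=spec,
        tree=tree,
        alignment=alignment,
        truth=truth,
        structures=structures,
        cavity_hotspot_columns=hot,
        cavity_conserved_columns=cav_cons,
        cavity_background_columns=cav_bg,
    )


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(
    out_dir: str | Path,
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    truth: GroundTruth,
    structures: Optional[Dict[str, Tuple[Structure, GroundTruth]]] = None,
    seeds: Optional[Dict[str, int]] = None,
) -> Dict:
    """Write FASTA + Newick + PDB + TSV fixtures and a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: List[Path] = []

    aln_path = out / "alignment.fasta"
    alignment.to_fasta(aln_path)
    files.append(aln_path)

    tree_path = out / "tree.nwk"
    write_tree(tree, tree_path)
    files.append(tree_path)

    if truth.true_ancestral_sequences:
        anc = CodonAlignment(truth.true_ancestral_sequences)
        anc_path = out / "true_ancestors.fasta"
        anc.to_fasta(anc_path)
        files.append(anc_path)

    if truth.true_column_regime:
        regime_path = out / "column_regimes.tsv"
        with open(regime_path, "w") as fh:
            fh.write("column\tregime\n")
            for col in sorted(truth.true_column_regime):
                fh.write(f"{col}\t{truth.true_column_regime[col]}\n")
        files.append(regime_path)

    for name, (structure, struct_truth) in (structures or {}).items():
        pdb_path = out / f"{name}.pdb"
        structure.to_pdb(pdb_path)
        files.append(pdb_path)
        if structure.residue_to_column:
            map_path = out / f"{name}.columns.tsv"
            write_column_map(structure.residue_to_column, map_path)
            files.append(map_path)
        truth_path = out / f"{name}.truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("reference_void_volume\treference_mouth_count\n")
            fh.write(
                f"{struct_truth.reference_void_volume}\t{struct_truth.reference_mouth_count}\n"
            )
        files.append(truth_path)

    manifest = {
        "seeds": seeds or {},
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
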