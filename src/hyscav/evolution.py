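"""Cavity lineages across a phylogeny and the selection/cavity overlay.

Cavities detected in the structures of different tree nodes are matched
by the Jaccard overlap of their lining residues mapped onto common
alignment columns; matched cavities along parent-to-child branches form
lineages numbered by order of first appearance in a preorder traversal
(ancestors before descendants).  The per-column cavity score counts in
how many structures the residue at that column lines any cavity; the
overlay joins this score with the per-column deltaN/deltaS selection
profile to expose, e.g., cavity-forming columns that are nevertheless
under purifying selection (deltaN - deltaS < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import CLASS_LETTER, Cavity
from .phylo import node_name
from .selection import SiteSelectionProfile
from .structures import Structure

DEFAULT_JACCARD_MIN = 0.3


@dataclass
class NodeCavities:
    """Cavities of one tree node's structure, with its column map."""

    node: str
    structure: Structure
    cavities: List[Cavity]

    def lining_columns(self, cavity: Cavity) -> FrozenSet[int]:
        return self.structure.columns_of(sorted(cavity.lining_residues))

    @classmethod
    def from_tables(
        cls, node: str, cavity_table: pd.DataFrame, column_map: Dict[int, int]
    ) -> "NodeCavities":
        """Rebuild from a cavity TSV (as written by the detector) and a column map."""
        stub = Structure(
            coords=np.zeros((0, 3)),
            radii=np.zeros(0),
            residue_indices=np.zeros(0, dtype=int),
            residue_to_column=dict(column_map),
            name=node,
        )
        cavities = []
        for _, row in cavity_table.iterrows():
            lining = frozenset(
                int(tok.split(":")[-1])
                for tok in str(row["lining_residues"]).split(",")
                if tok
            )
            cavities.append(
                Cavity(
                    id=int(row["id"]),
                    tetrahedra=np.zeros(0, dtype=int),
                    mouth_count=int(row["mouths"]),
                    lining_residues=lining,
                    tetra_volume=0.0,
                    volume=float(row["volume"]),
                    class_label=str(row["class"]),
                )
            )
        return cls(node, stub, cavities)


def _jaccard(a: FrozenSet[int], b: FrozenSet[int]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def match_cavities(
    a: NodeCavities,
    b: NodeCavities,
    jaccard_min: float = DEFAULT_JACCARD_MIN,
) -> List[Tuple[int, int, float]]:
    """Greedy maximum-Jaccard pairing of cavities between two structures.

    Returns (cavity id in a, cavity id in b, jaccard) triples.  Pairs
    scoring below ``jaccard_min`` stay unmatched; ties break toward the
    lower cavity id in a, then in b, so the pairing is deterministic and
    symmetric up to transposition.
    """
    if a.structure.residue_to_column is None or b.structure.residue_to_column is None:
        raise ValueError("both structures need residue-to-column maps for matching")
    cols_a = {c.id: a.lining_columns(c) for c in a.cavities}
    cols_b = {c.id: b.lining_columns(c) for c in b.cavities}
    candidates = [
        (_jaccard(ca, cb), ia, ib)
        for ia, ca in cols_a.items()
        for ib, cb in cols_b.items()
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set = set()
    used_b: set = set()
    pairs: List[Tuple[int, int, float]] = []
    for score, ia, ib in candidates:
        if score < jaccard_min:
            break
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib, score))
    pairs.sort(key=lambda t: t[0])
    return pairs


@dataclass
class CavityLineage:
    """A cavity identity tracked across tree nodes.

    ``members`` maps node name to the cavity id in that node's
    structure; ``class_history`` records the volume class per node;
    ``lineage_id`` is the order of first appearance (preorder).
    """

    lineage_id: int
    first_node: str
    members: Dict[str, int] = field(default_factory=dict)
    class_history: Dict[str, str] = field(default_factory=dict)

    def label_at(self, node: str) -> Optional[str]:
        """Fig-style composite label, e.g. '5d' for lineage 5 as a dent."""
        if node not in self.members:
            return None
        return f"{self.lineage_id}{CLASS_LETTER.get(self.class_history[node], '?')}"


def number_by_appearance(
    tree,
    node_cavities: Dict[str, NodeCavities],
    jaccard_min: float = DEFAULT_JACCARD_MIN,
) -> List[CavityLineage]:
    """Track cavity lineages down the tree, numbering by first appearance.

    The tree is walked preorder (root first).  Cavities at a node are
    matched against the parent structure's cavities; an unmatched cavity
    starts a new lineage with the next integer id, a matched one
    inherits its parent cavity's lineage.  Nodes without a structure are
    transparent: matching is against the nearest structured ancestor.
    """
    lineages: List[CavityLineage] = []
    # (node name) -> {cavity id -> lineage index}
    assignment: Dict[str, Dict[int, int]] = {}

    def structured_ancestor(node) -> Optional[str]:
        p = node.parent_node
        while p is not None:
            if node_name(p) in node_cavities:
                return node_name(p)
            p = p.parent_node
        return None

    for node in tree.preorder_node_iter():
        name = node_name(node)
        if name not in node_cavities:
            continue
        nc = node_cavities[name]
        anc_name = structured_ancestor(node)
        matched: Dict[int, int] = {}
        if anc_name is not None:
            pairs = match_cavities(node_cavities[anc_name], nc, jaccard_min)
            parent_assign = assignment[anc_name]
            seen_parents: set = set()
            for ia, ib, _ in pairs:
                if ia in seen_parents:
                    raise ValueError(f"cavity {ia} at {anc_name} matched twice")
                seen_parents.add(ia)
                matched[ib] = parent_assign[ia]
        assignment[name] = {}
        for cav in sorted(nc.cavities, key=lambda c: c.id):
            if cav.id in matched:
                li = matched[cav.id]
            else:
                li = len(lineages)
                lineages.append(CavityLineage(lineage_id=li + 1, first_node=name))
            lineage = lineages[li]
            lineage.members[name] = cav.id
            lineage.class_history[name] = cav.class_label or "?"
            assignment[name][cav.id] = li
    return lineages


def node_composition(lineages: Sequence[CavityLineage], node: str) -> str:
    """Composite per-node cavity label, e.g. '3k + 5i'."""
    parts = [lin.label_at(node) for lin in sorted(lineages, key=lambda l: l.lineage_id)]
    return " + ".join(p for p in parts if p)


@dataclass
class CavityScoreProfile:
    """Per-column count of structures whose residue there lines a cavity."""

    scores: pd.Series  # indexed by 1-based column
    n_structures: int

    @property
    def n_columns(self) -> int:
        return len(self.scores)


def cavity_score_profile(
    node_cavities: Dict[str, NodeCavities],
    n_columns: int,
    per_structure_count: bool = True,
) -> CavityScoreProfile:
    """Column-wise cavity involvement over a set of structures.

    With ``per_structure_count`` (default) the score at a column is the
    number of structures in which the residue mapped to that column
    lines at least one cavity; the alternative sums lining residues over
    structures (a column can then count more than once per structure).
    """
    index = pd.RangeIndex(1, n_columns + 1, name="column")
    scores = pd.Series(0, index=index, dtype=int)
    for nc in node_cavities.values():
        if per_structure_count:
            cols: set = set()
            for cav in nc.cavities:
                cols |= nc.lining_columns(cav)
            for c in cols:
                if 1 <= c <= n_columns:
                    scores.loc[c] += 1
        else:
            for cav in nc.cavities:
                for r in sorted(cav.lining_residues):
                    c = nc.structure.residue_to_column.get(r)
                    if c is not None and 1 <= c <= n_columns:
                        scores.loc[c] += 1
    return CavityScoreProfile(scores=scores, n_structures=len(node_cavities))


@dataclass
class OverlayReport:
    """Joined selection/cavity table plus the headline counts."""

    table: pd.DataFrame
    n_positive: int  # columns with deltaN - deltaS > 0
    n_cavity: int  # columns with cavity score > 0
    n_positive_and_cavity: int
    n_cavity_but_conserved: int  # cavity-forming yet deltaN - deltaS < 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="column", float_format="%.6g")


def overlay_report(
    score_profile: CavityScoreProfile,
    selection_profile: SiteSelectionProfile,
) -> OverlayReport:
    """Overlay the cavity score with the deltaN/deltaS selection profile.

    The summary counts reproduce the comparison of interest: how many
    columns show positive selection pressure, how many line cavities,
    their intersection, and the cavity-forming-but-conserved complement.
    """
    sel = selection_profile.table
    if len(sel) != score_profile.n_columns:
        raise ValueError(
            f"column mismatch: selection profile has {len(sel)}, "
            f"cavity scores have {score_profile.n_columns}"
        )
    table = sel[["deltaN", "deltaS", "deltaN_minus_deltaS"]].copy()
    table["cavity_score"] = score_profile.scores.values
    diff = table["deltaN_minus_deltaS"]
    cav = table["cavity_score"] > 0
    return OverlayReport(
        table=table,
        n_positive=int((diff > 0).sum()),
        n_cavity=int(cav.sum()),
        n_positive_and_cavity=int(((diff > 0) & cav).sum()),
        n_cavity_but_conserved=int(((diff < 0) & cav).sum()),
    )
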