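"""End-to-end pipeline: ASR -> selection profile -> cavities -> lineages -> overlay.

A single YAML config drives the run; every stage writes its table into
the output directory and a manifest records input checksums, seeds and
per-stage timings so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .alignment import CodonAlignment
from .ancestral import SubstitutionModel, fit_model, marginal_asr
from .evolution import (
    NodeCavities,
    cavity_score_profile,
    node_composition,
    number_by_appearance,
    overlay_report,
)
from .genetics import get_code
from .geometry import GeometryParams, detect_cavities
from .phylo import leaf_names, read_tree
from .selection import site_profile, summarize_positive_sites
from .structures import Structure, read_column_map


@dataclass
class PipelineConfig:
    """Validated file paths and stage settings for one pipeline run."""

    alignment: Path
    tree: Path
    structures: Dict[str, Path] = field(default_factory=dict)  # node -> PDB
    column_maps: Dict[str, Path] = field(default_factory=dict)  # node -> TSV
    output_dir: Path = Path("hyscav_out")
    genetic_code: str = "standard"
    fit_substitution_model: bool = True
    gamma_shape: Optional[float] = 1.0
    p_invariant: float = 0.0
    n_rate_categories: int = 4
    probe_radius: float = 1.4
    volume_mc_samples: int = 200_000
    jaccard_min: float = 0.3
    selection_bootstrap: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for key in ("alignment", "tree"):
            if key not in raw:
                raise ValueError(f"{path}: missing required field {key!r}")
        base = Path(path).parent
        def _p(v):  # resolve relative to the config file
            p = Path(v)
            return p if p.is_absolute() else base / p
        return cls(
            alignment=_p(raw["alignment"]),
            tree=_p(raw["tree"]),
            structures={k: _p(v) for k, v in raw.get("structures", {}).items()},
            column_maps={k: _p(v) for k, v in raw.get("column_maps", {}).items()},
            output_dir=_p(raw.get("output_dir", "hyscav_out")),
            genetic_code=raw.get("genetic_code", "standard"),
            fit_substitution_model=bool(raw.get("fit_substitution_model", True)),
            gamma_shape=raw.get("gamma_shape", 1.0),
            p_invariant=float(raw.get("p_invariant", 0.0)),
            n_rate_categories=int(raw.get("n_rate_categories", 4)),
            probe_radius=float(raw.get("probe_radius", 1.4)),
            volume_mc_samples=int(raw.get("volume_mc_samples", 200_000)),
            jaccard_min=float(raw.get("jaccard_min", 0.3)),
            selection_bootstrap=int(raw.get("selection_bootstrap", 200)),
            seed=int(raw.get("seed", 0)),
        )


def validate_inputs(config: PipelineConfig) -> Dict[str, List[str]]:
    """Parse-and-bind check of all inputs; returns errors and warnings."""
    errors: List[str] = []
    warnings: List[str] = []
    aln = tree = None
    for name, path in (("alignment", config.alignment), ("tree", config.tree)):
        if not Path(path).exists():
            errors.append(f"{name}: file not found: {path}")
    if not errors:
        try:
            aln = CodonAlignment.from_fasta(config.alignment)
        except ValueError as exc:
            errors.append(f"alignment: {exc}")
        try:
            tree = read_tree(config.tree)
        except Exception as exc:
            errors.append(f"tree: {exc}")
    if aln is not None and tree is not None:
        for leaf in leaf_names(tree):
            if leaf not in aln.sequences:
                errors.append(f"tree leaf {leaf!r} has no alignment row")
        extra = set(aln.sequences) - set(leaf_names(tree))
        if extra:
            warnings.append(f"alignment rows without tree leaves: {sorted(extra)}")
    for node, path in config.structures.items():
        if not Path(path).exists():
            errors.append(f"structure {node!r}: file not found: {path}")
            continue
        try:
            structure = Structure.from_pdb(path)
        except Exception as exc:
            errors.append(f"structure {node!r}: {exc}")
            continue
        map_path = config.column_maps.get(node)
        if map_path is None:
            warnings.append(f"structure {node!r}: no residue-to-column map")
        elif not Path(map_path).exists():
            errors.append(f"column map {node!r}: file not found: {map_path}")
        else:
            mapping = read_column_map(map_path)
            missing = set(mapping) - set(int(r) for r in structure.residues())
            if missing:
                warnings.append(
                    f"structure {node!r}: mapped residues absent from PDB: {sorted(missing)[:5]}..."
                    if len(missing) > 5
                    else f"structure {node!r}: mapped residues absent from PDB: {sorted(missing)}"
                )
    return {"errors": errors, "warnings": warnings}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage and return the run manifest.

    Stages: ancestral reconstruction, per-column selection profile,
    cavity detection per structure, lineage tracking, overlay.  Any
    stage failure raises with the stage name attached.
    """
    report = validate_inputs(config)
    if report["errors"]:
        raise ValueError("input validation failed: " + "; ".join(report["errors"]))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "alignment": _sha256(config.alignment),
            "tree": _sha256(config.tree),
            **{f"structure:{k}": _sha256(Path(v)) for k, v in config.structures.items()},
        },
        "stages": {},
        "warnings": report["warnings"],
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = {"seconds": round(time.perf_counter() - self.t0, 3)}

        return _Timer()

    alignment = CodonAlignment.from_fasta(config.alignment)
    tree = read_tree(config.tree)
    code = get_code(config.genetic_code)

    with stage("asr"):
        if config.fit_substitution_model:
            fit = fit_model(alignment, tree, n_rate_categories=config.n_rate_categories)
            model = fit.model
        else:
            from .ancestral import empirical_frequencies

            model = SubstitutionModel(
                base_frequencies=empirical_frequencies(alignment),
                gamma_shape=config.gamma_shape,
                n_rate_categories=config.n_rate_categories,
                p_invariant=config.p_invariant,
            )
        ancestors = marginal_asr(tree, alignment, model, code=code)
        anc_path = out / "ancestors.fasta"
        CodonAlignment(dict(ancestors.codon_sequences)).to_fasta(anc_path)

    with stage("selection_profile"):
        profile = site_profile(
            alignment,
            tree,
            ancestors.codon_sequences,
            code,
            n_bootstrap=config.selection_bootstrap,
            seed=config.seed,
        )
        profile.to_tsv(out / "selection_profile.tsv")
        manifest["positive_sites"] = summarize_positive_sites(profile)

    node_cavities: Dict[str, NodeCavities] = {}
    with stage("cavities"):
        params = GeometryParams(
            probe_radius=config.probe_radius,
            volume_mc_samples=config.volume_mc_samples,
            seed=config.seed,
        )
        for node, pdb in config.structures.items():
            col_map = (
                read_column_map(config.column_maps[node])
                if node in config.column_maps
                else None
            )
            structure = Structure.from_pdb(pdb, residue_to_column=col_map)
            cavities = detect_cavities(structure, params)
            node_cavities[node] = NodeCavities(node, structure, cavities)
        from .geometry import cavities_to_table

        for node, nc in node_cavities.items():
            cavities_to_table(nc.cavities, nc.structure).to_csv(
                out / f"cavities_{node}.tsv", sep="\t", index=False
            )

    with stage("track"):
        mappable = {
            k: v for k, v in node_cavities.items() if v.structure.residue_to_column
        }
        lineages = number_by_appearance(tree, mappable, config.jaccard_min) if mappable else []
        rows = []
        for lin in lineages:
            for node, cav_id in lin.members.items():
                rows.append(
                    {
                        "lineage": lin.lineage_id,
                        "node": node,
                        "cavity_id": cav_id,
                        "class": lin.class_history[node],
                        "label": lin.label_at(node),
                    }
                )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "lineages.tsv", sep="\t", index=False)
        manifest["compositions"] = {
            node: node_composition(lineages, node) for node in mappable
        }

    with stage("overlay"):
        if node_cavities:
            mappable = {
                k: v for k, v in node_cavities.items() if v.structure.residue_to_column
            }
            scores = cavity_score_profile(mappable, alignment.n_columns)
            overlay = overlay_report(scores, profile)
            overlay.to_tsv(out / "overlay.tsv")
            manifest["overlay"] = {
                "n_positive": overlay.n_positive,
                "n_cavity": overlay.n_cavity,
                "n_positive_and_cavity": overlay.n_positive_and_cavity,
                "n_cavity_but_conserved": overlay.n_cavity_but_conserved,
            }

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*")) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
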