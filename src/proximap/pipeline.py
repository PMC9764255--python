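"""End-to-end orchestration: simulate/load -> filter -> enrich -> classify ->
topology -> report.

A run is driven by a single YAML config holding either a ``simulate`` block
(:class:`~proximap.synthetic.SimulationParams` fields) or a ``paths`` block
naming the input files, plus optional ``thresholds``, ``enrichment`` and
``topology`` blocks.  Every threshold is echoed into the summary JSON for
provenance, and a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import filters, quant_io, synthetic, topology
from .errors import ConfigurationError
from .quant_io import Group, QuantTable, SampleDesign

logger = logging.getLogger(__name__)

_PATH_KEYS = ("table", "design", "fasta", "annotations", "landmarks", "categories")
_REQUIRED_PATH_KEYS = ("table", "design")


@dataclass
class RunConfig:
    """Validated run configuration; exactly one of simulate/paths is set."""

    simulate: Optional[synthetic.SimulationParams] = None
    paths: Optional[dict[str, Path]] = None
    thresholds: filters.FilterThresholds = field(
        default_factory=filters.FilterThresholds
    )
    ef_cutoff: float = 2.0
    enrichment_p_cutoff: float = 0.05
    background: str = "presence_filtered"  # or "all_input"
    labelable_residues: str = "YWHC"
    tyrosine_only: bool = False
    overlap_default_imp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.paths is None):
            raise ConfigurationError(
                "config needs exactly one of a 'simulate' or a 'paths' block"
            )
        if self.background not in {"presence_filtered", "all_input"}:
            raise ConfigurationError(f"unknown background '{self.background}'")
        if self.paths is not None:
            for key in _REQUIRED_PATH_KEYS:
                if key not in self.paths:
                    raise ConfigurationError(f"paths block missing '{key}'")
            for key, p in self.paths.items():
                if not Path(p).exists():
                    raise ConfigurationError(f"input file for '{key}' not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Optional[Path] = None) -> "RunConfig":
        kwargs: dict = {}
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            kwargs["simulate"] = synthetic.SimulationParams(**sim)
        if "paths" in raw:
            base = base_dir or Path(".")
            kwargs["paths"] = {
                k: (base / v if not Path(v).is_absolute() else Path(v))
                for k, v in raw["paths"].items()
            }
        if "thresholds" in raw:
            kwargs["thresholds"] = filters.FilterThresholds(**raw["thresholds"])
        for key in (
            "ef_cutoff",
            "enrichment_p_cutoff",
            "background",
            "labelable_residues",
            "tyrosine_only",
            "overlap_default_imp",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _load_inputs(config: RunConfig):
    """Return (table, design, sequences, annotations, landmarks, categories)."""
    if config.simulate is not None:
        params = config.simulate
        design = synthetic.default_design()
        proteome = synthetic.generate_proteome(params)
        table, _ = synthetic.simulate_experiment(proteome, design, params)
        positives, negatives = synthetic.landmark_sets(proteome)
        categories = {
            p.protein_id: {synthetic._compartment(p.true_class)}
            for p in proteome.proteins
        }
        return (
            table,
            design,
            proteome.sequences(),
            proteome.annotations(),
            (positives, negatives),
            categories,
        )
    paths = config.paths
    design = quant_io.read_design(paths["design"])
    table = quant_io.read_protein_groups(paths["table"], design)
    sequences = quant_io.read_fasta(paths["fasta"]) if "fasta" in paths else {}
    annotations = (
        quant_io.read_annotations(paths["annotations"])
        if "annotations" in paths
        else {}
    )
    landmarks: tuple[set, set] = (set(), set())
    if "landmarks" in paths:
        lm = pd.read_csv(paths["landmarks"], sep="\t", dtype=str)
        landmarks = (
            set(lm.loc[lm["role"] == "positive", "protein_id"]),
            set(lm.loc[lm["role"] == "negative", "protein_id"]),
        )
    categories = (
        enr.read_categories(paths["categories"]) if "categories" in paths else {}
    )
    return table, design, sequences, annotations, landmarks, categories


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage, write all artifacts under ``outdir``, and return
    the machine-readable run summary (also written as ``summary.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, design, sequences, annotations, (positives, negatives), categories = (
        _load_inputs(config)
    )

    clean = quant_io.drop_flagged(table)
    report = filters.sequential_filter(clean, design, config.thresholds)
    landmark_summary = filters.landmark_check(report, positives, negatives)

    for stage in report.stages:
        stage.frame.to_csv(
            outdir / f"stage_{stage.control_group.value}.tsv", sep="\t", index=False
        )
    pd.DataFrame({"protein_id": report.final_set}).to_csv(
        outdir / "final_set.tsv", sep="\t", index=False
    )

    # replicate QC
    min_r2: dict[str, float] = {}
    for group in sorted({s.group for s in design}, key=lambda g: g.value):
        r2 = filters.replicate_correlation(clean, design, group)
        off_diag = r2.to_numpy()[~np.eye(len(r2), dtype=bool)]
        finite = off_diag[np.isfinite(off_diag)]
        min_r2[group.value] = float(finite.min()) if finite.size else float("nan")
        r2.to_csv(outdir / f"replicate_r2_{group.value}.tsv", sep="\t")

    # enrichment against the configured background
    enrichment_rows = 0
    if categories:
        background = (
            report.presence_ids
            if config.background == "presence_filtered"
            else clean.protein_ids
        )
        results = enr.fisher_enrichment(
            report.final_set,
            background,
            categories,
            ef_cutoff=config.ef_cutoff,
            p_cutoff=config.enrichment_p_cutoff,
        )
        enr.results_frame(results).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        enrichment_rows = len(results)

    # localization + topology of the final set
    labelable = topology.LabelableSet(
        residues=frozenset(config.labelable_residues),
        tyrosine_only_mode=config.tyrosine_only,
    )
    class_counts = {c.value: 0 for c in topology.LocalizationClass}
    topo_rows = []
    for pid in report.final_set:
        ann = topology.resolve_annotation(pid, annotations.get(pid), sequences.get(pid))
        call = topology.classify_localization(
            ann, overlap_default_imp=config.overlap_default_imp
        )
        class_counts[call.loc_class.value] += 1
        orientation, loops_txt = "", ""
        if ann.tm_segments and ann.sequence:
            topo = topology.infer_topology(
                ann.sequence, ann.tm_segments, labelable, protein_id=pid
            )
            orientation = topo.orientation.value
            loops_txt = topo.serialize_loops()
        topo_rows.append(
            {
                "protein_id": pid,
                "class": call.loc_class.value,
                "basis": call.basis,
                "n_tm": len(ann.tm_segments),
                "signal_peptide": int(ann.has_signal_peptide),
                "orientation": orientation,
                "loops": loops_txt,
            }
        )
    pd.DataFrame(
        topo_rows,
        columns=[
            "protein_id", "class", "basis", "n_tm", "signal_peptide",
            "orientation", "loops",
        ],
    ).to_csv(outdir / "topology.tsv", sep="\t", index=False)

    n_imp = class_counts[topology.LocalizationClass.IMP.value]
    summary = {
        "seed": config.seed,
        "n_input": report.n_input,
        "n_after_presence": report.n_after_presence,
        "stage_counts": report.stage_counts,
        "n_final": len(report.final_set),
        "n_IMP": n_imp,
        "n_luminal": len(report.final_set) - n_imp,
        "class_counts": class_counts,
        "landmark_summary": landmark_summary,
        "min_r2_per_group": min_r2,
        "n_enrichment_categories": enrichment_rows,
        "thresholds": {
            "min_target_replicates": config.thresholds.min_target_replicates,
            "min_msms_total": config.thresholds.min_msms_total,
            "p_cutoff": config.thresholds.p_cutoff,
            "fold_change": config.thresholds.fold_change,
            "control_order": [g.value for g in config.thresholds.control_order],
            "missing_policy": config.thresholds.missing_policy,
            "welch": config.thresholds.welch,
            "bh_correction": config.thresholds.bh_correction,
        },
        "enrichment": {
            "ef_cutoff": config.ef_cutoff,
            "p_cutoff": config.enrichment_p_cutoff,
            "background": config.background,
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
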