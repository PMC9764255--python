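"""Synthetic proximity-labeling experiments with known ground truth.

Generates a small proteome (sequences with planted transmembrane segments,
signal peptides, and labelable residues), then simulates a four-group
label-free quantification table over it.  Intensities are drawn on the log2
scale and exponentiated (LFQ intensities are approximately log-normal);
missingness is intensity-dependent via a logistic in log2 intensity, which
reproduces the left-censoring of real LFQ data.

Randomness: one user seed drives a named, independent stream per stage
(proteome, base intensities, replicate noise, detection, MS/MS counts), so
enlarging one class does not perturb draws in other stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .quant_io import (
    Group,
    ProteinAnnotation,
    QuantTable,
    SampleDesign,
    write_annotations,
    write_design,
    write_fasta,
    write_protein_groups,
)


class TrueClass(str, Enum):
    BAIT_PROXIMAL_LUMINAL = "bait_proximal_luminal"
    BAIT_PROXIMAL_IMP = "bait_proximal_imp"
    DISTAL_LUMINAL = "distal_luminal"
    CYTOPLASMIC = "cytoplasmic"
    ENDOGENOUS_BIOTINYLATED = "endogenous_biotinylated"
    PHYCOBILISOME_LIKE_LANDMARK = "phycobilisome_like_landmark"
    OEC_LIKE_LANDMARK = "oec_like_landmark"


#: classes whose members are genuinely proximal to the bait (should survive).
PROXIMAL_CLASSES = {
    TrueClass.BAIT_PROXIMAL_LUMINAL,
    TrueClass.BAIT_PROXIMAL_IMP,
    TrueClass.OEC_LIKE_LANDMARK,
}
#: classes behaving like cytoplasmic proteins (leak into the target group).
CYTO_CLASSES = {TrueClass.CYTOPLASMIC, TrueClass.PHYCOBILISOME_LIKE_LANDMARK}

_DEFAULT_N_PER_CLASS = {
    TrueClass.BAIT_PROXIMAL_LUMINAL.value: 30,
    TrueClass.BAIT_PROXIMAL_IMP.value: 20,
    TrueClass.DISTAL_LUMINAL.value: 30,
    TrueClass.CYTOPLASMIC.value: 120,
    TrueClass.ENDOGENOUS_BIOTINYLATED.value: 10,
    TrueClass.PHYCOBILISOME_LIKE_LANDMARK.value: 6,
    TrueClass.OEC_LIKE_LANDMARK.value: 3,
}

# hydrophilic, non-labelable residue pool for loop/body construction; excludes
# Y/W/H/C (labelable) and strong hydrophobics (would seed spurious TMs)
_LOOP_POOL = "DEGKNPQRST"
_TM_POOL = "LLLLIVFA"

_STREAMS = {"proteome": 0, "base": 1, "noise": 2, "detect": 3, "msms": 4}


@dataclass
class SimulationParams:
    """All knobs of the generator; defaults give a well-separated experiment."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_PER_CLASS)
    )
    base_log_intensity_mean: float = 25.0
    base_log_intensity_sd: float = 2.0
    target_enrichment_log2fc: float = 3.0
    peroxidase_background_log2: float = 0.5
    endogenous_biotin_log2: float = 2.0
    cyto_leak_log2fc: float = 2.0
    cyto_leak_target_fraction: float = 0.3
    landmark_abundance_log2: float = 3.0
    replicate_sd: float = 0.3
    detection_logistic_midpoint: float = 21.0
    detection_logistic_slope: float = 1.2
    missing_values: bool = True
    msms_per_log2intensity: float = 0.4
    sp_fraction_luminal: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_log_intensity_sd < 0 or self.replicate_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.target_enrichment_log2fc < 0:
            raise ConfigurationError("target_enrichment_log2fc must be >= 0")
        if not 0 <= self.cyto_leak_target_fraction <= 1:
            raise ConfigurationError("cyto_leak_target_fraction must be in [0, 1]")
        if not 0 <= self.sp_fraction_luminal <= 1:
            raise ConfigurationError("sp_fraction_luminal must be in [0, 1]")
        for cls, n in self.n_per_class.items():
            TrueClass(cls)  # raises on unknown class
            if n < 0:
                raise ConfigurationError(f"n_per_class[{cls}] must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SyntheticProtein:
    protein_id: str
    true_class: TrueClass
    sequence: str
    tm_segments: list[tuple[int, int]]
    sp_region: Optional[tuple[int, int]]
    planted_orientation: Optional[str]  # "N_lumen" / "N_cyto" for IMPs


@dataclass
class SyntheticProteome:
    proteins: list[SyntheticProtein]

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    def by_class(self, cls: TrueClass) -> list[SyntheticProtein]:
        return [p for p in self.proteins if p.true_class is cls]

    def sequences(self) -> dict[str, str]:
        return {p.protein_id: p.sequence for p in self.proteins}

    def annotations(self) -> dict[str, ProteinAnnotation]:
        out = {}
        for p in self.proteins:
            out[p.protein_id] = ProteinAnnotation(
                protein_id=p.protein_id,
                sequence=p.sequence,
                tm_segments=list(p.tm_segments),
                has_signal_peptide=p.sp_region is not None,
                sp_region=p.sp_region,
                categories={_compartment(p.true_class)},
            )
        return out

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [p.protein_id for p in self.proteins],
                "true_class": [p.true_class.value for p in self.proteins],
                "planted_orientation": [
                    p.planted_orientation or "" for p in self.proteins
                ],
            }
        )


def _compartment(cls: TrueClass) -> str:
    if cls is TrueClass.BAIT_PROXIMAL_IMP:
        return "thylakoid_membrane"
    if cls in {
        TrueClass.BAIT_PROXIMAL_LUMINAL,
        TrueClass.DISTAL_LUMINAL,
        TrueClass.OEC_LIKE_LANDMARK,
    }:
        return "thylakoid_lumen"
    return "cytoplasm"


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[name])))


def default_design(replicates: int = 3) -> list[SampleDesign]:
    """Four groups x ``replicates`` samples, named ``<group>_<rep>``."""
    design = []
    for group in Group:
        for r in range(1, replicates + 1):
            design.append(SampleDesign(f"{group.value}_{r}", group, r))
    return design


# ---------------------------------------------------------------------------
# sequence construction


def _loop(rng: np.random.Generator, length: int, n_labelable: int) -> str:
    """Loop of hydrophilic residues with exactly ``n_labelable`` tyrosines."""
    residues = list(rng.choice(list(_LOOP_POOL), size=length))
    if n_labelable > 0:
        pos = rng.choice(length, size=min(n_labelable, length), replace=False)
        for p in pos:
            residues[p] = "Y"
    return "".join(residues)


def _tm(rng: np.random.Generator, length: int = 21) -> str:
    return "".join(rng.choice(list(_TM_POOL), size=length))


def _signal_peptide(rng: np.random.Generator) -> str:
    # K/R within residues 1-5, 12-residue hydrophobic core inside 1-35, then a
    # small residue ("A") terminating the region -- matches the heuristic SP rule
    return "MK" + _loop(rng, 2, 0) + "L" * 12 + "A"


def _imp_sequence(
    rng: np.random.Generator, n_tm: int, orientation: str
) -> tuple[str, list[tuple[int, int]]]:
    """Build an IMP sequence with labelable residues only on the lumen side.

    Loops alternate sides starting from the N-terminal loop; ``orientation``
    "N_lumen" puts even-index loops (0-based) in the lumen, "N_cyto" the odd
    ones.  Every lumen-side loop carries 1-4 tyrosines; cytoplasmic loops
    carry none.
    """
    lumen_parity = 0 if orientation == "N_lumen" else 1
    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_tm + 1):
        length = int(rng.integers(8, 25))
        lumen = i % 2 == lumen_parity
        n_lab = int(rng.integers(1, 5)) if lumen else 0
        loop = _loop(rng, length, n_lab)
        parts.append(loop)
        pos += len(loop)
        if i < n_tm:
            tm = _tm(rng, int(rng.integers(19, 24)))
            segments.append((pos + 1, pos + len(tm)))
            parts.append(tm)
            pos += len(tm)
    return "".join(parts), segments


def _soluble_sequence(rng: np.random.Generator, with_sp: bool) -> tuple[
    str, Optional[tuple[int, int]]
]:
    body = _loop(rng, int(rng.integers(60, 140)), int(rng.integers(2, 8)))
    if with_sp:
        sp = _signal_peptide(rng)
        return sp + body, (1, len(sp))
    return "M" + body, None


def generate_proteome(params: SimulationParams) -> SyntheticProteome:
    """Generate sequences and ground truth; deterministic given the seed."""
    rng = _stream(params.seed, "proteome")
    proteins: list[SyntheticProtein] = []
    counter = 0
    prefixes = {
        TrueClass.OEC_LIKE_LANDMARK: "OEC",
        TrueClass.PHYCOBILISOME_LIKE_LANDMARK: "PBS",
    }
    for cls_name in sorted(params.n_per_class):
        cls = TrueClass(cls_name)
        for k in range(params.n_per_class[cls_name]):
            counter += 1
            prefix = prefixes.get(cls, "SYN")
            pid = f"{prefix}{counter:04d}"
            orientation: Optional[str] = None
            sp_region: Optional[tuple[int, int]] = None
            if cls is TrueClass.BAIT_PROXIMAL_IMP:
                n_tm = int(rng.integers(1, 4))
                orientation = "N_lumen" if rng.random() < 0.5 else "N_cyto"
                seq, tm_segments = _imp_sequence(rng, n_tm, orientation)
            else:
                luminal = cls in {
                    TrueClass.BAIT_PROXIMAL_LUMINAL,
                    TrueClass.DISTAL_LUMINAL,
                    TrueClass.OEC_LIKE_LANDMARK,
                }
                with_sp = luminal and rng.random() < params.sp_fraction_luminal
                seq, sp_region = _soluble_sequence(rng, with_sp)
                tm_segments = []
            proteins.append(
                SyntheticProtein(pid, cls, seq, tm_segments, sp_region, orientation)
            )
    return SyntheticProteome(proteins)


# ---------------------------------------------------------------------------
# quantification


def _effect_matrix(
    proteome: SyntheticProteome,
    design: Sequence[SampleDesign],
    params: SimulationParams,
) -> np.ndarray:
    """Class x group systematic log2 effects, expanded to protein x sample."""
    n, m = len(proteome.proteins), len(design)
    eff = np.zeros((n, m))
    for i, prot in enumerate(proteome.proteins):
        cls = prot.true_class
        for j, s in enumerate(design):
            e = 0.0
            if s.group is Group.TARGET:
                if cls in PROXIMAL_CLASSES:
                    e += params.target_enrichment_log2fc
                if cls in CYTO_CLASSES:
                    e += params.cyto_leak_log2fc * params.cyto_leak_target_fraction
            elif s.group is Group.CTRL_CYTO_BAIT:
                if cls in CYTO_CLASSES:
                    e += params.cyto_leak_log2fc
            elif s.group is Group.CTRL_WILDTYPE:
                e += params.peroxidase_background_log2
            if cls is TrueClass.ENDOGENOUS_BIOTINYLATED:
                e += params.endogenous_biotin_log2  # all groups incl. no-BP
            eff[i, j] = e
    return eff


def simulate_experiment(
    proteome: SyntheticProteome,
    design: Sequence[SampleDesign],
    params: SimulationParams,
) -> tuple[QuantTable, pd.DataFrame]:
    """Simulate the four-group quantification table over ``proteome``.

    Returns the table and a truth frame (protein_id, true_class,
    planted_orientation) in the same protein order.
    """
    missing_groups = set(Group) - {s.group for s in design}
    if missing_groups:
        raise ConfigurationError(
            f"design missing group(s): {sorted(g.value for g in missing_groups)}"
        )
    n, m = len(proteome.proteins), len(design)
    base = _stream(params.seed, "base").normal(
        params.base_log_intensity_mean, params.base_log_intensity_sd, size=n
    )
    # landmark classes emulate highly abundant complexes, so they are
    # reliably detected in every group (as real landmark subunits are)
    is_landmark = np.array(
        [
            p.true_class
            in {TrueClass.OEC_LIKE_LANDMARK, TrueClass.PHYCOBILISOME_LIKE_LANDMARK}
            for p in proteome.proteins
        ]
    )
    base = base + is_landmark * params.landmark_abundance_log2
    log2_int = (
        base[:, None]
        + _effect_matrix(proteome, design, params)
        + _stream(params.seed, "noise").normal(0.0, params.replicate_sd, size=(n, m))
    )

    if params.missing_values:
        z = params.detection_logistic_slope * (
            log2_int - params.detection_logistic_midpoint
        )
        p_detect = 1.0 / (1.0 + np.exp(-z))
        detected = _stream(params.seed, "detect").random(size=(n, m)) < p_detect
    else:
        detected = np.ones((n, m), dtype=bool)

    intensities = np.where(detected, np.exp2(log2_int), 0.0)
    lam = params.msms_per_log2intensity * np.clip(log2_int, 0.0, None)
    msms = _stream(params.seed, "msms").poisson(lam)
    msms = np.where(detected, np.maximum(msms, 1), 0).astype(np.int64)

    table = QuantTable(
        protein_ids=list(proteome.protein_ids),
        sample_ids=[s.sample_id for s in design],
        intensities=intensities,
        msms_counts=msms,
        flags=pd.DataFrame(
            {k: np.zeros(n, dtype=bool) for k in ("is_contaminant", "is_decoy", "only_by_site")}
        ),
    )
    return table, proteome.truth_frame()


def landmark_sets(proteome: SyntheticProteome) -> tuple[set[str], set[str]]:
    """(positive, negative) landmark protein-id sets."""
    pos = {p.protein_id for p in proteome.by_class(TrueClass.OEC_LIKE_LANDMARK)}
    neg = {
        p.protein_id
        for p in proteome.by_class(TrueClass.PHYCOBILISOME_LIKE_LANDMARK)
    }
    return pos, neg


def write_experiment(
    proteome: SyntheticProteome,
    table: QuantTable,
    design: Sequence[SampleDesign],
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit the TSV/FASTA artifacts quant_io reads, plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "proteinGroups.tsv",
        "design": outdir / "design.tsv",
        "fasta": outdir / "proteome.fasta",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
        "landmarks": outdir / "landmarks.tsv",
        "categories": outdir / "categories.tsv",
    }
    write_protein_groups(table, paths["table"])
    write_design(design, paths["design"])
    write_fasta(proteome.sequences(), paths["fasta"])
    write_annotations(proteome.annotations(), paths["annotations"])
    proteome.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    pos, neg = landmark_sets(proteome)
    pd.DataFrame(
        {
            "protein_id": sorted(pos) + sorted(neg),
            "role": ["positive"] * len(pos) + ["negative"] * len(neg),
        }
    ).to_csv(paths["landmarks"], sep="\t", index=False)
    pd.DataFrame(
        {
            "protein_id": proteome.protein_ids,
            "category": [_compartment(p.true_class) for p in proteome.proteins],
            "source": "custom",
        }
    ).to_csv(paths["categories"], sep="\t", index=False)
    return paths
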