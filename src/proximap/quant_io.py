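"""Readers and writers for the pipeline's standard input artifacts.

The quantification table follows MaxQuant ``proteinGroups.txt`` conventions:
one ``LFQ intensity <sample>`` and one ``MS/MS count <sample>`` column per
sample, ``Protein IDs`` as the accession column, and contaminant / decoy /
site-only rows marked either by ``+`` in the standard marker columns or by
``CON__`` / ``REV__`` accession prefixes.  Empty or non-numeric intensity
cells parse as 0 (MaxQuant's encoding for "not quantified"), never as an
error.

All residue coordinates (transmembrane segments, signal-peptide regions) are
1-based inclusive throughout the package.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Marker columns MaxQuant uses to flag rows that must not enter quantitation.
FLAG_COLUMNS = {
    "is_contaminant": "Potential contaminant",
    "is_decoy": "Reverse",
    "only_by_site": "Only identified by site",
}

PROTEIN_ID_COLUMN = "Protein IDs"
INTENSITY_PREFIX = "LFQ intensity"
MSMS_PREFIX = "MS/MS count"

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


class Group(str, Enum):
    """The four experimental groups of a bait-APEX2 labeling design."""

    TARGET = "target"
    CTRL_NO_SUBSTRATE = "ctrl_no_substrate"
    CTRL_WILDTYPE = "ctrl_wildtype"
    CTRL_CYTO_BAIT = "ctrl_cyto_bait"


CONTROL_GROUPS = (Group.CTRL_NO_SUBSTRATE, Group.CTRL_WILDTYPE, Group.CTRL_CYTO_BAIT)


@dataclass(frozen=True)
class SampleDesign:
    """One sample of the experimental design.

    Attributes
    ----------
    sample_id:
        Name used in the quantification table's column headers.
    group:
        Experimental group the sample belongs to.
    replicate:
        Positive replicate index, unique within the group.
    """

    sample_id: str
    group: Group
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise InputError(f"replicate must be >= 1, got {self.replicate}")


def validate_design(design: Sequence[SampleDesign]) -> None:
    """Check design invariants; raise :class:`ConfigurationError` on violation."""
    seen = set()
    for s in design:
        key = (s.group, s.replicate)
        if key in seen:
            raise ConfigurationError(f"duplicate (group, replicate) pair {key}")
        seen.add(key)
    ids = [s.sample_id for s in design]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate sample_id in design")
    n_target = sum(1 for s in design if s.group is Group.TARGET)
    if n_target and n_target < 2:
        raise ConfigurationError("target group needs >= 2 replicates")


def groups_present(design: Sequence[SampleDesign]) -> set[Group]:
    return {s.group for s in design}


def sample_ids_for_group(design: Sequence[SampleDesign], group: Group) -> list[str]:
    return [s.sample_id for s in design if s.group is group]


@dataclass
class QuantTable:
    """Protein x sample intensity and MS/MS-count matrices with row flags.

    ``intensities`` is nonnegative; 0 encodes "not detected".  Rows are kept
    in file order; flagged rows are retained until :func:`drop_flagged` is
    called so that counts before/after removal stay auditable.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    msms_counts: np.ndarray
    flags: pd.DataFrame  # bool columns: is_contaminant, is_decoy, only_by_site

    def __post_init__(self) -> None:
        n, m = len(self.protein_ids), len(self.sample_ids)
        if self.intensities.shape != (n, m) or self.msms_counts.shape != (n, m):
            raise InputError("matrix shapes do not match protein/sample lists")
        if np.any(self.intensities < 0):
            raise InputError("negative intensity")
        if np.any(self.msms_counts < 0):
            raise InputError("negative MS/MS count")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def leading_ids(self) -> list[str]:
        """First accession of each (possibly multi-accession) protein group."""
        return [pid.split(";")[0] for pid in self.protein_ids]

    def flagged_mask(self) -> np.ndarray:
        return self.flags.to_numpy(dtype=bool).any(axis=1)

    def sample_indices(self, design: Sequence[SampleDesign], group: Group) -> list[int]:
        wanted = sample_ids_for_group(design, group)
        missing = [s for s in wanted if s not in self.sample_ids]
        if missing:
            raise ConfigurationError(f"samples not in table: {missing}")
        return [self.sample_ids.index(s) for s in wanted]

    def subset(self, row_indices: Sequence[int]) -> "QuantTable":
        idx = list(row_indices)
        return QuantTable(
            protein_ids=[self.protein_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            intensities=self.intensities[idx, :].copy(),
            msms_counts=self.msms_counts[idx, :].copy(),
            flags=self.flags.iloc[idx].reset_index(drop=True),
        )

    def subset_by_ids(self, ids: Iterable[str]) -> "QuantTable":
        wanted = set(ids)
        return self.subset([i for i, p in enumerate(self.protein_ids) if p in wanted])


@dataclass
class ProteinAnnotation:
    """Imported per-protein annotation (TM segments, signal peptide, categories).

    TM and signal-peptide coordinates come from external predictors or from
    the synthetic ground truth; this type only validates their invariants.
    """

    protein_id: str
    sequence: Optional[str] = None
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    has_signal_peptide: bool = False
    sp_region: Optional[tuple[int, int]] = None
    categories: set[str] = field(default_factory=set)
    literature_imp: Optional[bool] = None
    literature_luminal: Optional[bool] = None

    def __post_init__(self) -> None:
        segs = sorted(self.tm_segments)
        for start, end in segs:
            if end < start or start < 1:
                raise InputError(
                    f"{self.protein_id}: invalid TM interval {start}-{end}"
                )
            if self.sequence is not None and end > len(self.sequence):
                raise InputError(
                    f"{self.protein_id}: TM interval {start}-{end} outside sequence"
                )
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise InputError(f"{self.protein_id}: overlapping TM intervals")
        self.tm_segments = segs
        if self.sp_region is not None:
            s, e = self.sp_region
            if s != 1:
                raise InputError(f"{self.protein_id}: signal peptide must start at 1")
            if e < s:
                raise InputError(f"{self.protein_id}: invalid SP region {s}-{e}")


# ---------------------------------------------------------------------------
# design file


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read a design file, TSV (sample_id, group, replicate) or YAML list."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rows = [(r["sample_id"], r["group"], int(r["replicate"])) for r in raw]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("sample_id", "group", "replicate"):
            if col not in df.columns:
                raise ConfigurationError(f"design file missing column '{col}'")
        rows = [
            (r.sample_id, r.group, int(r.replicate)) for r in df.itertuples(index=False)
        ]
    design = []
    for sample_id, group, replicate in rows:
        try:
            g = Group(group)
        except ValueError as exc:
            raise InputError(f"unknown group '{group}'") from exc
        design.append(SampleDesign(sample_id, g, replicate))
    validate_design(design)
    return design


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "group": [s.group.value for s in design],
            "replicate": [s.replicate for s in design],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein-groups table


def read_protein_groups(
    path: str | Path, design: Sequence[SampleDesign]
) -> QuantTable:
    """Parse a MaxQuant-style protein-groups TSV into a :class:`QuantTable`.

    Rows are flagged, not dropped; missing numeric cells parse as 0.

    Raises
    ------
    ConfigurationError
        If a required per-sample column is absent (the message names it).
    InputError
        On duplicate protein accessions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if PROTEIN_ID_COLUMN not in df.columns:
        raise ConfigurationError(f"missing required column '{PROTEIN_ID_COLUMN}'")
    protein_ids = df[PROTEIN_ID_COLUMN].fillna("").tolist()
    if len(set(protein_ids)) != len(protein_ids):
        dupes = df[PROTEIN_ID_COLUMN][df[PROTEIN_ID_COLUMN].duplicated()].tolist()
        raise InputError(f"duplicate protein accession(s): {dupes[:5]}")

    n = len(df)
    m = len(design)
    intensities = np.zeros((n, m), dtype=float)
    msms = np.zeros((n, m), dtype=np.int64)
    for j, s in enumerate(design):
        icol = f"{INTENSITY_PREFIX} {s.sample_id}"
        mcol = f"{MSMS_PREFIX} {s.sample_id}"
        for col in (icol, mcol):
            if col not in df.columns:
                raise ConfigurationError(f"missing required column '{col}'")
        # Python's float() is correctly rounded (pandas' fast parser is not),
        # which keeps the text round-trip bit-exact
        intensities[:, j] = [_parse_float(v) for v in df[icol].fillna("")]
        msms[:, j] = (
            pd.to_numeric(df[mcol], errors="coerce").fillna(0).astype(np.int64)
        )
    if np.any(intensities < 0):
        raise InputError("negative intensity in table")

    flags = pd.DataFrame(index=range(n))
    for key, col in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[key] = df[col].fillna("").str.strip().eq("+").to_numpy()
        else:
            flags[key] = False
    # fall back to accession-prefix conventions when marker columns are absent
    lead = pd.Series([p.split(";")[0] for p in protein_ids])
    if "Potential contaminant" not in df.columns:
        flags["is_contaminant"] = flags["is_contaminant"] | lead.str.startswith(
            "CON__"
        ).to_numpy()
    if "Reverse" not in df.columns:
        flags["is_decoy"] = flags["is_decoy"] | lead.str.startswith("REV__").to_numpy()

    return QuantTable(
        protein_ids=protein_ids,
        sample_ids=[s.sample_id for s in design],
        intensities=intensities,
        msms_counts=msms,
        flags=flags,
    )


def write_protein_groups(
    table: QuantTable, path: str | Path, design: Optional[Sequence[SampleDesign]] = None
) -> None:
    """Write a QuantTable back to the MaxQuant-style TSV dialect.

    Float intensities are written with 17 significant digits so a re-parse is
    bit-exact.
    """
    cols: dict[str, object] = {PROTEIN_ID_COLUMN: table.protein_ids}
    for j, sid in enumerate(table.sample_ids):
        cols[f"{INTENSITY_PREFIX} {sid}"] = [
            _format_float(v) for v in table.intensities[:, j]
        ]
        cols[f"{MSMS_PREFIX} {sid}"] = table.msms_counts[:, j]
    for key, col in FLAG_COLUMNS.items():
        cols[col] = ["+" if v else "" for v in table.flags[key]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _parse_float(text: str) -> float:
    try:
        v = float(text)
    except ValueError:
        return 0.0
    return v if np.isfinite(v) else 0.0


def _format_float(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return np.format_float_positional(v, trim="0", unique=True)


def drop_flagged(table: QuantTable) -> QuantTable:
    """Remove contaminant / decoy / site-only rows, preserving row order."""
    keep = np.flatnonzero(~table.flagged_mask())
    return table.subset(keep)


# ---------------------------------------------------------------------------
# annotations

_INTERVAL_RE = re.compile(r"^(\d+)-(\d+)$")


def _parse_interval(text: str, context: str) -> tuple[int, int]:
    m = _INTERVAL_RE.match(text.strip())
    if not m:
        raise InputError(f"{context}: cannot parse interval '{text}'")
    start, end = int(m.group(1)), int(m.group(2))
    if end < start:
        raise InputError(f"{context}: interval end < start in '{text}'")
    return start, end


def _parse_optional_bool(text: str) -> Optional[bool]:
    text = text.strip()
    if text == "":
        return None
    return text not in {"0", "false", "False", "no"}


def read_annotations(path: str | Path) -> dict[str, ProteinAnnotation]:
    """Read the annotation TSV (TM segments, SP call, categories, literature).

    Expected columns: ``protein_id`` (required) and optionally
    ``tm_segments`` ("start-end;start-end"), ``signal_peptide`` (0/1),
    ``sp_region`` ("1-27"), ``categories`` (comma-separated),
    ``literature_imp``, ``literature_luminal``.
    Proteins absent from the file simply get no entry; use
    :func:`get_annotation` for an empty default.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "protein_id" not in df.columns:
        raise ConfigurationError("annotation file missing column 'protein_id'")
    out: dict[str, ProteinAnnotation] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid in out:
            raise InputError(f"duplicate annotation for '{pid}'")
        tm_raw = getattr(row, "tm_segments", "")
        tm = [
            _parse_interval(part, pid)
            for part in str(tm_raw).split(";")
            if part.strip()
        ]
        sp_raw = str(getattr(row, "sp_region", "")).strip()
        sp_region = _parse_interval(sp_raw, pid) if sp_raw else None
        has_sp_raw = str(getattr(row, "signal_peptide", "")).strip()
        has_sp = bool(sp_region) if has_sp_raw == "" else has_sp_raw not in {"0", ""}
        cats_raw = str(getattr(row, "categories", ""))
        categories = {c.strip() for c in cats_raw.split(",") if c.strip()}
        out[pid] = ProteinAnnotation(
            protein_id=pid,
            tm_segments=tm,
            has_signal_peptide=has_sp,
            sp_region=sp_region,
            categories=categories,
            literature_imp=_parse_optional_bool(str(getattr(row, "literature_imp", ""))),
            literature_luminal=_parse_optional_bool(
                str(getattr(row, "literature_luminal", ""))
            ),
        )
    return out


def get_annotation(
    annotations: Mapping[str, ProteinAnnotation], protein_id: str
) -> ProteinAnnotation:
    """Return the annotation for ``protein_id`` or an empty one."""
    if protein_id in annotations:
        return annotations[protein_id]
    return ProteinAnnotation(protein_id=protein_id)


def write_annotations(
    annotations: Mapping[str, ProteinAnnotation], path: str | Path
) -> None:
    rows = []
    for pid in annotations:
        a = annotations[pid]
        rows.append(
            {
                "protein_id": pid,
                "tm_segments": ";".join(f"{s}-{e}" for s, e in a.tm_segments),
                "signal_peptide": int(a.has_signal_peptide),
                "sp_region": f"{a.sp_region[0]}-{a.sp_region[1]}" if a.sp_region else "",
                "categories": ",".join(sorted(a.categories)),
                "literature_imp": "" if a.literature_imp is None else int(a.literature_imp),
                "literature_luminal": ""
                if a.literature_luminal is None
                else int(a.literature_luminal),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an accession -> upper-cased sequence map.

    The accession is the first whitespace-delimited token of the header.
    Non-standard residues are retained but reported in the log.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id
        if acc in out:
            raise InputError(f"duplicate FASTA accession '{acc}'")
        seq = str(record.seq).upper()
        odd = sorted(set(seq) - STANDARD_RESIDUES)
        if odd:
            logger.warning("%s: non-standard residues %s retained", acc, odd)
        out[acc] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
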