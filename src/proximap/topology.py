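"""Membrane/luminal classification and labelable-residue topology inference.

Classification (integral membrane protein vs luminal) follows the Venn logic
over transmembrane-segment and signal-peptide annotations, with the
single-TM/SP-overlap ambiguity resolved to luminal unless literature marks
the protein as an integral membrane protein.

Topology inference exploits the chemistry of peroxidase proximity labeling:
the phenoxyl radical tags electron-rich residues (Tyr, Trp, His, Cys, with
tyrosine dominant), and a luminal bait can only tag loops facing the lumen.
If every labelable residue of a membrane protein falls on one alternation
class of its loops, that side is inferred to face the lumen.  The rule is
strict: a single labelable residue on the opposite side, or none anywhere,
yields "ambiguous".

The Kyte-Doolittle TM and signal-peptide predictors here are explicitly
heuristic stand-ins for dedicated predictors; imported annotations are the
fidelity path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .quant_io import ProteinAnnotation

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_LABELABLE = frozenset("YWHC")


@dataclass(frozen=True)
class LabelableSet:
    """Residues a phenoxyl radical can tag; tyrosine-only mode restricts to
    the dominant site."""

    residues: frozenset[str] = DEFAULT_LABELABLE
    tyrosine_only_mode: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError("labelable residue set must be non-empty")

    @property
    def effective(self) -> frozenset[str]:
        return frozenset("Y") if self.tyrosine_only_mode else self.residues


class LocalizationClass(str, Enum):
    IMP = "IMP"
    LUMINAL_WITH_SP = "luminal_with_SP"
    LUMINAL_NO_SP_NO_TM = "luminal_no_SP_no_TM"


class Orientation(str, Enum):
    N_LUMEN = "N_lumen"   # N-terminal loop faces the lumen
    N_CYTO = "N_cyto"     # N-terminal loop faces the cytoplasm
    AMBIGUOUS = "ambiguous"


@dataclass
class LocalizationCall:
    protein_id: str
    loc_class: LocalizationClass
    basis: str  # multi_TM | single_TM_no_SP | SP_TM_overlap_resolved_literature
    #         | single_TM_disjoint_SP | SP_only | neither


@dataclass
class LoopEvidence:
    start: int  # 1-based inclusive; start > end encodes an empty terminal loop
    end: int
    parity: int  # alternation class: 0 for the N-terminal loop, 1 for the next
    labelable_count: int


@dataclass
class TopologyCall:
    protein_id: str
    loops: list[LoopEvidence]
    orientation: Orientation
    evidence_exclusive: bool

    def loop_sides(self) -> list[str]:
        """Per-loop side labels under the inferred orientation."""
        if self.orientation is Orientation.AMBIGUOUS:
            return ["?" for _ in self.loops]
        lumen_parity = 0 if self.orientation is Orientation.N_LUMEN else 1
        return [
            "lumen" if lp.parity == lumen_parity else "cyto" for lp in self.loops
        ]

    def serialize_loops(self) -> str:
        sides = self.loop_sides()
        return ";".join(
            f"{lp.start}-{lp.end}:{side}:{lp.labelable_count}"
            for lp, side in zip(self.loops, sides)
        )


# ---------------------------------------------------------------------------
# heuristic predictors


def _hydropathy(sequence: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence])


def heuristic_tm_predict(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 17,
    max_len: int = 35,
) -> list[tuple[int, int]]:
    """Kyte-Doolittle sliding-window transmembrane segment prediction.

    A window of ``window`` residues with mean hydropathy above ``threshold``
    seeds a segment; overlapping hot windows merge; merged segments are
    trimmed of hydrophilic (negative-KD) ends down to ``min_len`` and split
    near-equally when longer than ``max_len``.  Deterministic; returns
    1-based inclusive intervals.  Sequences shorter than the window give [].
    """
    L = len(sequence)
    if L < window:
        return []
    kd = _hydropathy(sequence)
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    hot = np.flatnonzero(means > threshold)  # 0-based window starts
    if hot.size == 0:
        return []
    # merge windows whose spans overlap
    merged: list[list[int]] = []
    for s in hot:
        e = s + window - 1
        if merged and s <= merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    segments: list[tuple[int, int]] = []
    for start, end in merged:
        while end - start + 1 > min_len and kd[start] < 0:
            start += 1
        while end - start + 1 > min_len and kd[end] < 0:
            end -= 1
        length = end - start + 1
        if length > max_len:
            n_parts = -(-length // max_len)  # ceil
            bounds = np.linspace(start, end + 1, n_parts + 1).round().astype(int)
            for a, b in zip(bounds[:-1], bounds[1:]):
                segments.append((int(a) + 1, int(b)))  # to 1-based inclusive
        else:
            segments.append((int(start) + 1, int(end) + 1))
    return segments


def heuristic_sp_predict(
    sequence: str,
    core_window: int = 10,
    threshold: float = 1.6,
    n_region_len: int = 5,
    core_limit: int = 35,
    cap: int = 40,
) -> Optional[tuple[int, int]]:
    """Heuristic N-terminal signal-peptide call.

    Requires a basic residue (K/R) within the first ``n_region_len`` residues
    and a hydrophobic core -- a ``core_window``-residue window of mean KD
    above ``threshold`` lying entirely within residues 1..``core_limit``.
    The region runs from residue 1 to the first small residue (G/A/S) after
    the core, capped at ``cap``.  Returns a 1-based inclusive region or None.
    """
    L = len(sequence)
    if L < core_window:
        return None
    if not any(aa in "KR" for aa in sequence[:n_region_len]):
        return None
    kd = _hydropathy(sequence)
    means = np.convolve(kd, np.ones(core_window) / core_window, mode="valid")
    core_start = None
    for s in range(min(len(means), core_limit - core_window + 1)):
        if means[s] > threshold:
            core_start = s  # 0-based
            break
    if core_start is None:
        return None
    core_end = core_start + core_window - 1
    region_end = min(cap, L)
    for i in range(core_end + 1, min(L, cap)):
        if sequence[i] in "GAS":
            region_end = i + 1  # 1-based position of the small residue
            break
    return (1, region_end)


# ---------------------------------------------------------------------------
# classification


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def classify_localization(
    annotation: ProteinAnnotation,
    overlap_default_imp: bool = False,
    assumed_sp_region: tuple[int, int] = (1, 40),
) -> LocalizationCall:
    """Total, deterministic IMP / luminal classification.

    Rules in order: >= 2 TM segments -> IMP; exactly one TM and no signal
    peptide -> IMP; one TM overlapping the signal-peptide region -> IMP only
    with literature support (configurable via ``overlap_default_imp``), else
    luminal; signal peptide only -> luminal; neither -> luminal without
    signal peptide.  One TM disjoint from the signal peptide (a case the
    rules above do not anticipate) is classified IMP with a warning.
    """
    n_tm = len(annotation.tm_segments)
    has_sp = annotation.has_signal_peptide
    pid = annotation.protein_id
    if n_tm >= 2:
        return LocalizationCall(pid, LocalizationClass.IMP, "multi_TM")
    if n_tm == 1 and not has_sp:
        return LocalizationCall(pid, LocalizationClass.IMP, "single_TM_no_SP")
    if n_tm == 1 and has_sp:
        sp = annotation.sp_region or assumed_sp_region
        if _overlaps(annotation.tm_segments[0], sp):
            if annotation.literature_imp or (
                annotation.literature_imp is None and overlap_default_imp
            ):
                return LocalizationCall(
                    pid, LocalizationClass.IMP, "SP_TM_overlap_resolved_literature"
                )
            return LocalizationCall(
                pid,
                LocalizationClass.LUMINAL_WITH_SP,
                "SP_TM_overlap_resolved_literature",
            )
        logger.warning("%s: single TM disjoint from signal peptide; calling IMP", pid)
        return LocalizationCall(pid, LocalizationClass.IMP, "single_TM_disjoint_SP")
    if has_sp:
        return LocalizationCall(pid, LocalizationClass.LUMINAL_WITH_SP, "SP_only")
    return LocalizationCall(pid, LocalizationClass.LUMINAL_NO_SP_NO_TM, "neither")


# ---------------------------------------------------------------------------
# topology inference


def _loops_from_segments(
    seq_len: int, tm_segments: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """N-terminal region, inter-TM loops, C-terminal region, in order.
    Terminal loops may be empty (start > end) when a TM abuts the terminus."""
    segs = sorted(tm_segments)
    loops = [(1, segs[0][0] - 1)]
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        loops.append((e1 + 1, s2 - 1))
    loops.append((segs[-1][1] + 1, seq_len))
    return loops


def infer_topology(
    sequence: str,
    tm_segments: Sequence[tuple[int, int]],
    labelable: Optional[LabelableSet] = None,
    protein_id: str = "",
) -> TopologyCall:
    """Infer membrane orientation from the loop-wise labelable-residue counts.

    Loops alternate sides of the membrane; if all labelable residues fall in
    loops of a single alternation class (and at least one such residue
    exists), that class is placed lumenal -- orientation ``N_lumen`` when it
    contains the N-terminal loop, ``N_cyto`` otherwise.  Any labelable
    residue on both sides, or none at all, yields ``ambiguous``.
    """
    labelable = labelable or LabelableSet()
    if not tm_segments:
        raise InputError("infer_topology requires >= 1 TM segment")
    segs = sorted(tm_segments)
    for start, end in segs:
        if start < 1 or end > len(sequence) or end < start:
            raise InputError(f"TM segment {start}-{end} outside sequence")
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        if s2 <= e1:
            raise InputError("overlapping TM segments")

    residues = labelable.effective
    loops = []
    for i, (start, end) in enumerate(_loops_from_segments(len(sequence), segs)):
        count = sum(1 for aa in sequence[start - 1 : end] if aa in residues)
        loops.append(LoopEvidence(start, end, i % 2, count))

    count0 = sum(lp.labelable_count for lp in loops if lp.parity == 0)
    count1 = sum(lp.labelable_count for lp in loops if lp.parity == 1)
    if count0 > 0 and count1 == 0:
        orientation, exclusive = Orientation.N_LUMEN, True
    elif count1 > 0 and count0 == 0:
        orientation, exclusive = Orientation.N_CYTO, True
    else:
        orientation, exclusive = Orientation.AMBIGUOUS, False
    return TopologyCall(
        protein_id=protein_id,
        loops=loops,
        orientation=orientation,
        evidence_exclusive=exclusive,
    )


def resolve_annotation(
    protein_id: str,
    annotation: Optional[ProteinAnnotation],
    sequence: Optional[str],
) -> ProteinAnnotation:
    """Resolve TM/SP fields, falling back to the heuristic predictors.

    An imported annotation is trusted as-is (an empty TM list there means the
    external predictor found none); the heuristics run only for proteins with
    no annotation record and an available sequence.
    """
    if annotation is not None:
        if annotation.sequence is None and sequence is not None:
            annotation.sequence = sequence
        return annotation
    if sequence is None:
        return ProteinAnnotation(protein_id=protein_id)
    sp_region = heuristic_sp_predict(sequence)
    return ProteinAnnotation(
        protein_id=protein_id,
        sequence=sequence,
        tm_segments=heuristic_tm_predict(sequence),
        has_signal_peptide=sp_region is not None,
        sp_region=sp_region,
    )
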