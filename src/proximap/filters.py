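"""Sequential multi-control filtering of the quantification table.

The pipeline applies a presence filter on the target group (detection in at
least ``min_target_replicates`` replicates and total MS/MS evidence of at
least ``min_msms_total``), then compares survivors against each negative
control in turn: a protein passes a stage when its target/control log2 ratio
reaches log2(fold_change) and the two-sample Student's t-test on log2
intensities gives p below ``p_cutoff``.  The final proximal set is the
intersection of the stage pass sets, so it is invariant to the control order
(with per-protein statistics; Benjamini-Hochberg, when enabled, breaks that
symmetry because each stage is corrected over its own survivor set).

Missing-data policy (defaults avoid inventing data):

* ``detected_only`` -- the test uses detected (intensity > 0) values only and
  needs >= 2 per side; otherwise p is NaN and the protein can pass only via
  the absent-in-control rule.
* ``impute`` -- Perseus-style per-sample imputation: missing log2 cells drawn
  from Normal(mean - 1.8 sd, 0.3 sd) of that sample's detected distribution.

Absent-in-control rule (either policy): a protein detected in every target
replicate and in no control replicate passes the stage with ratio +inf and a
NaN sentinel p-value.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .quant_io import CONTROL_GROUPS, Group, QuantTable, SampleDesign

logger = logging.getLogger(__name__)


@dataclass
class FilterThresholds:
    """Filter criteria.

    Defaults: detection in >= 2 target replicates, total MS/MS count > 1,
    p < 0.05, two-fold change, and the three controls in order no-substrate,
    wild-type, cytoplasmic bait.
    """

    min_target_replicates: int = 2
    min_msms_total: int = 2
    p_cutoff: float = 0.05
    fold_change: float = 2.0
    control_order: tuple[Group, ...] = CONTROL_GROUPS
    welch: bool = False
    missing_policy: str = "detected_only"  # or "impute"
    msms_rule: str = "summed"  # or "per_replicate"
    bh_correction: bool = False
    imputation_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ConfigurationError("p_cutoff must be in (0, 1)")
        if not self.fold_change > 1:
            raise ConfigurationError("fold_change must be > 1")
        if self.min_target_replicates < 1:
            raise ConfigurationError("min_target_replicates must be >= 1")
        if self.missing_policy not in {"detected_only", "impute"}:
            raise ConfigurationError(f"unknown missing_policy '{self.missing_policy}'")
        if self.msms_rule not in {"summed", "per_replicate"}:
            raise ConfigurationError(f"unknown msms_rule '{self.msms_rule}'")
        self.control_order = tuple(Group(g) for g in self.control_order)

    @property
    def log2_fc(self) -> float:
        return math.log2(self.fold_change)


@dataclass
class StageResult:
    """Per-protein outcome of one target-vs-control comparison.

    ``frame`` columns: protein_id, log2_ratio, p_value, n_target_detected,
    n_control_detected, passed.  NaN p marks proteins unquantifiable under the
    missing-data policy; they pass only via the absent-in-control rule.
    """

    control_group: Group
    frame: pd.DataFrame

    @property
    def passed_ids(self) -> set[str]:
        return set(self.frame.loc[self.frame["passed"], "protein_id"])


@dataclass
class FilterReport:
    n_input: int
    n_after_presence: int
    presence_ids: list[str]
    stages: list[StageResult]
    final_set: list[str]
    landmark_summary: Optional[dict] = None

    @property
    def stage_counts(self) -> list[int]:
        counts = []
        survivors = set(self.presence_ids)
        for stage in self.stages:
            survivors &= stage.passed_ids
            counts.append(len(survivors))
        return counts


# ---------------------------------------------------------------------------


def presence_filter(
    table: QuantTable,
    design: Sequence[SampleDesign],
    thresholds: Optional[FilterThresholds] = None,
) -> QuantTable:
    """Keep proteins with target-group detection and MS/MS evidence.

    A protein is retained when it has intensity > 0 in at least
    ``min_target_replicates`` target samples and its target MS/MS evidence
    meets ``min_msms_total`` (summed over target samples by default).
    """
    thresholds = thresholds or FilterThresholds()
    ti = table.sample_indices(design, Group.TARGET)
    if thresholds.min_target_replicates > len(ti):
        raise ConfigurationError(
            f"min_target_replicates={thresholds.min_target_replicates} exceeds "
            f"{len(ti)} target samples"
        )
    detected = table.intensities[:, ti] > 0
    enough_reps = detected.sum(axis=1) >= thresholds.min_target_replicates
    msms = table.msms_counts[:, ti]
    if thresholds.msms_rule == "summed":
        enough_msms = msms.sum(axis=1) >= thresholds.min_msms_total
    else:  # per_replicate: one replicate alone must carry the evidence
        enough_msms = msms.max(axis=1) >= thresholds.min_msms_total
    return table.subset(np.flatnonzero(enough_reps & enough_msms))


def _log2_detected(mat: np.ndarray) -> np.ndarray:
    out = np.full(mat.shape, np.nan)
    mask = mat > 0
    out[mask] = np.log2(mat[mask])
    return out


def _impute_downshift(
    x: np.ndarray, rng: np.random.Generator, width: float = 0.3, shift: float = 1.8
) -> np.ndarray:
    """Perseus-style imputation: per sample (column), missing cells drawn from
    a normal downshifted from the detected distribution.  Columns with < 2
    detected values are left as NaN (no distribution to estimate)."""
    out = x.copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        det = col[~np.isnan(col)]
        missing = np.isnan(col)
        if det.size < 2 or not missing.any():
            continue
        mu, sd = det.mean(), det.std(ddof=1)
        out[missing, j] = rng.normal(mu - shift * sd, width * sd, size=missing.sum())
    return out


def _masked_mean_var(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise count, mean and unbiased variance ignoring NaN, without
    warnings; mean is NaN for empty rows, var is NaN for rows with < 2."""
    n = np.sum(~np.isnan(x), axis=1)
    with np.errstate(invalid="ignore"):
        s = np.nansum(x, axis=1)
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        dev = x - mean[:, None]
        ss = np.nansum(dev * dev, axis=1)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


def compare_groups(
    table: QuantTable,
    design: Sequence[SampleDesign],
    target_group: Group,
    control_group: Group,
    thresholds: Optional[FilterThresholds] = None,
) -> StageResult:
    """Target-vs-control log2 ratios, t-test p-values and pass flags.

    The ratio is the difference of group means of log2 intensities (a
    geometric-mean fold change).  The p-value comes from the two-sample
    Student's t-test (pooled variance; Welch by flag) on the same log2
    values.  Zero variance on both sides with equal means is defined as p = 1
    (identical data are not evidence of change); unequal means with zero
    variance give p = 0.
    """
    thresholds = thresholds or FilterThresholds()
    ti = table.sample_indices(design, target_group)
    ci = table.sample_indices(design, control_group)
    raw_t = _log2_detected(table.intensities[:, ti])
    raw_c = _log2_detected(table.intensities[:, ci])
    n_target_detected = np.sum(~np.isnan(raw_t), axis=1)
    n_control_detected = np.sum(~np.isnan(raw_c), axis=1)

    if thresholds.missing_policy == "impute":
        rng = np.random.default_rng(thresholds.imputation_seed)
        vals_t = _impute_downshift(raw_t, rng)
        vals_c = _impute_downshift(raw_c, rng)
    else:
        vals_t, vals_c = raw_t, raw_c

    n1, m1, v1 = _masked_mean_var(vals_t)
    n2, m2, v2 = _masked_mean_var(vals_c)
    quantifiable = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        if thresholds.welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / np.maximum(n1 - 1, 1)
                + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
            )
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            df = (n1 + n2 - 2).astype(float)
        tstat = (m1 - m2) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(tstat), df)

    # zero variance on both sides: p := 1 when means agree, 0 otherwise
    zero_se = quantifiable & np.isclose(se2, 0.0)
    p = np.where(zero_se & np.isclose(m1, m2), 1.0, p)
    p = np.where(zero_se & ~np.isclose(m1, m2), 0.0, p)
    p = np.where(quantifiable, p, np.nan)

    log2_ratio = np.where((n1 > 0) & (n2 > 0), m1 - m2, np.nan)

    absent_rule = (n_target_detected == len(ti)) & (n_control_detected == 0)
    log2_ratio = np.where(absent_rule, np.inf, log2_ratio)

    p_for_cut = p.copy()
    if thresholds.bh_correction:
        ok = ~np.isnan(p)
        if ok.any():
            p_for_cut[ok] = stats.false_discovery_control(p[ok], method="bh")
    with np.errstate(invalid="ignore"):
        passed = (
            quantifiable
            & (p_for_cut < thresholds.p_cutoff)
            & (log2_ratio >= thresholds.log2_fc)
        ) | absent_rule

    frame = pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "n_target_detected": n_target_detected,
            "n_control_detected": n_control_detected,
            "passed": passed,
        }
    )
    return StageResult(control_group=control_group, frame=frame)


def sequential_filter(
    table: QuantTable,
    design: Sequence[SampleDesign],
    thresholds: Optional[FilterThresholds] = None,
) -> FilterReport:
    """Presence filter, then each control comparison on the survivors.

    Every stage's full per-protein statistics are recorded; the final set is
    the survivors of all stages.
    """
    thresholds = thresholds or FilterThresholds()
    present_groups = {s.group for s in design}
    missing = [g for g in thresholds.control_order if g not in present_groups]
    if missing:
        raise ConfigurationError(
            f"control group(s) not in design: {[g.value for g in missing]}"
        )
    filtered = presence_filter(table, design, thresholds)
    survivors = filtered
    stages: list[StageResult] = []
    for control in thresholds.control_order:
        stage = compare_groups(survivors, design, Group.TARGET, control, thresholds)
        stages.append(stage)
        keep = stage.frame["passed"].to_numpy()
        survivors = survivors.subset(np.flatnonzero(keep))
        logger.info(
            "stage vs %s: %d -> %d proteins", control.value, len(keep), survivors.n_proteins
        )
        if survivors.n_proteins == 0:
            logger.warning("survivor set empty after stage vs %s", control.value)
    return FilterReport(
        n_input=table.n_proteins,
        n_after_presence=filtered.n_proteins,
        presence_ids=list(filtered.protein_ids),
        stages=stages,
        final_set=list(survivors.protein_ids),
    )


def landmark_check(
    report: FilterReport, positives: Iterable[str], negatives: Iterable[str]
) -> dict:
    """Fractions of positive landmarks retained and negatives removed.

    Empty landmark sets score 1.0 by convention (and are logged)."""
    final = set(report.final_set)
    pos, neg = set(positives), set(negatives)
    if not pos:
        logger.info("empty positive landmark set; retained := 1.0")
    if not neg:
        logger.info("empty negative landmark set; removed := 1.0")
    retained = len(pos & final) / len(pos) if pos else 1.0
    removed = len(neg - final) / len(neg) if neg else 1.0
    summary = {
        "positives_retained": retained,
        "negatives_removed": removed,
        "n_positives": len(pos),
        "n_negatives": len(neg),
    }
    report.landmark_summary = summary
    return summary


def replicate_correlation(
    table: QuantTable,
    design: Sequence[SampleDesign],
    group: Group,
    min_codetected: int = 3,
) -> pd.DataFrame:
    """Pairwise R^2 (squared Pearson) of log2 intensities within a group.

    For each sample pair only proteins detected in both samples enter the
    correlation; pairs with fewer than ``min_codetected`` co-detected
    proteins get NaN.  The matrix is symmetric with unit diagonal.
    """
    idx = table.sample_indices(design, group)
    if len(idx) < 2:
        raise ConfigurationError(f"group {group.value} has < 2 samples")
    names = [table.sample_ids[i] for i in idx]
    log2 = _log2_detected(table.intensities[:, idx])
    k = len(idx)
    r2 = np.full((k, k), np.nan)
    np.fill_diagonal(r2, 1.0)
    for a, b in itertools.combinations(range(k), 2):
        both = ~np.isnan(log2[:, a]) & ~np.isnan(log2[:, b])
        if both.sum() < min_codetected:
            continue
        r = np.corrcoef(log2[both, a], log2[both, b])[0, 1]
        r2[a, b] = r2[b, a] = r * r
    return pd.DataFrame(r2, index=names, columns=names)
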