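"""Shared fixtures and independent oracles used across the test suite.

The oracles here deliberately re-derive results by brute force (plain loops,
scipy reference routines, exact integer arithmetic) and must stay independent
of the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from proximap.quant_io import Group, QuantTable, SampleDesign
from proximap.synthetic import default_design


@pytest.fixture
def design():
    return default_design()


def make_design(replicates: int = 3) -> list[SampleDesign]:
    return default_design(replicates)


def random_quant_table(
    rng: np.random.Generator,
    n_proteins: int = 50,
    design=None,
    p_zero: float = 0.3,
    with_flags: bool = False,
) -> QuantTable:
    """A random table with intensity-independent dropout (for oracle tests)."""
    design = design or default_design()
    m = len(design)
    log2_int = rng.normal(25.0, 2.0, size=(n_proteins, m))
    detected = rng.random((n_proteins, m)) >= p_zero
    intensities = np.where(detected, np.exp2(log2_int), 0.0)
    msms = np.where(detected, rng.poisson(2.0, size=(n_proteins, m)), 0)
    flags = pd.DataFrame(
        {
            "is_contaminant": rng.random(n_proteins) < (0.1 if with_flags else 0.0),
            "is_decoy": rng.random(n_proteins) < (0.05 if with_flags else 0.0),
            "only_by_site": np.zeros(n_proteins, dtype=bool),
        }
    )
    return QuantTable(
        protein_ids=[f"P{i:04d}" for i in range(n_proteins)],
        sample_ids=[s.sample_id for s in design],
        intensities=intensities,
        msms_counts=msms.astype(np.int64),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_presence_ids(table, design, min_reps=2, min_msms=2) -> set[str]:
    """Row-by-row scan applying both presence predicates."""
    ti = [table.sample_ids.index(s.sample_id) for s in design if s.group is Group.TARGET]
    keep = set()
    for i, pid in enumerate(table.protein_ids):
        n_det = sum(1 for j in ti if table.intensities[i, j] > 0)
        total_msms = sum(int(table.msms_counts[i, j]) for j in ti)
        if n_det >= min_reps and total_msms >= min_msms:
            keep.add(pid)
    return keep


def oracle_stage_pass_ids(
    table, design, control: Group, p_cutoff=0.05, fold_change=2.0
) -> set[str]:
    """Per-protein re-derivation of one control comparison.

    Uses scipy's ttest_ind (the reference route) on detected log2 values,
    the absent-in-control rule, and the documented zero-variance convention.
    """
    ti = [table.sample_ids.index(s.sample_id) for s in design if s.group is Group.TARGET]
    ci = [table.sample_ids.index(s.sample_id) for s in design if s.group is control]
    passed = set()
    for i, pid in enumerate(table.protein_ids):
        tvals = [math.log2(v) for v in table.intensities[i, ti] if v > 0]
        cvals = [math.log2(v) for v in table.intensities[i, ci] if v > 0]
        if len(tvals) == len(ti) and len(cvals) == 0:
            passed.add(pid)
            continue
        if len(tvals) < 2 or len(cvals) < 2:
            continue
        ratio = np.mean(tvals) - np.mean(cvals)
        if np.std(tvals) == 0 and np.std(cvals) == 0:
            p = 1.0 if np.mean(tvals) == np.mean(cvals) else 0.0
        else:
            p = st.ttest_ind(tvals, cvals, equal_var=True).pvalue
        if p < p_cutoff and ratio >= math.log2(fold_change):
            passed.add(pid)
    return passed


def oracle_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k) by direct enumeration with integer combs."""
    num = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(max(k, 0), min(n, K) + 1)
        if 0 <= n - j <= N - K
    )
    return num / math.comb(N, n)


def oracle_orientation(seq: str, segments, labelable=frozenset("YWHC")) -> str:
    """Direct evaluation of the exclusive-side labeling rule."""
    segs = sorted(segments)
    loops = []
    prev_end = 0
    for s, e in segs:
        loops.append((prev_end + 1, s - 1))
        prev_end = e
    loops.append((prev_end + 1, len(seq)))
    sides_hit = set()
    for idx, (a, b) in enumerate(loops):
        for pos in range(a, b + 1):
            if seq[pos - 1] in labelable:
                sides_hit.add(idx % 2)
    if sides_hit == {0}:
        return "N_lumen"
    if sides_hit == {1}:
        return "N_cyto"
    return "ambiguous"


def oracle_tm_segments(seq: str, window=19, threshold=1.6, min_len=17, max_len=35):
    """Plain-loop re-derivation of the hydropathy-window TM rule."""
    from proximap.topology import KYTE_DOOLITTLE

    kd = [KYTE_DOOLITTLE.get(a, 0.0) for a in seq]
    if len(seq) < window:
        return []
    hot = []
    for s in range(len(seq) - window + 1):
        if sum(kd[s : s + window]) / window > threshold:
            hot.append((s, s + window - 1))
    merged = []
    for s, e in hot:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        while e - s + 1 > min_len and kd[s] < 0:
            s += 1
        while e - s + 1 > min_len and kd[e] < 0:
            e -= 1
        length = e - s + 1
        if length > max_len:
            n_parts = math.ceil(length / max_len)
            bounds = np.linspace(s, e + 1, n_parts + 1).round().astype(int)
            for a, b in zip(bounds[:-1], bounds[1:]):
                out.append((int(a) + 1, int(b)))
        else:
            out.append((s + 1, e + 1))
    return out
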