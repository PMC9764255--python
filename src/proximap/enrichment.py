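"""Category enrichment of the proximal set by one-sided Fisher's exact test.

For a category with K members among the N background proteins and k members
among the n selected proteins, the enrichment factor is (k/n)/(K/N) and the
p-value is the hypergeometric upper tail P(X >= k) -- the one-sided
(over-representation) Fisher exact test.  A category is called significant
when the enrichment factor exceeds ``ef_cutoff`` AND p is below ``p_cutoff``
(defaults 2 and 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError


@dataclass
class EnrichmentResult:
    category: str
    k: int  # selected ∩ category
    n: int  # selected
    K: int  # background ∩ category
    N: int  # background
    enrichment_factor: float
    p_value: float
    significant: bool


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    selected: Iterable[str],
    background: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    ef_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every category with at least one background member.

    ``category_map`` assigns each protein zero or more category labels;
    proteins outside the background are ignored.  Results are sorted by
    p-value (ties by category label for determinism).

    Raises
    ------
    InputError
        If ``selected`` is not a subset of ``background``.
    """
    sel = set(selected)
    bg = set(background)
    stray = sel - bg
    if stray:
        raise InputError(f"selected proteins not in background: {sorted(stray)[:5]}")
    n, N = len(sel), len(bg)

    members: dict[str, set[str]] = {}
    for pid, cats in category_map.items():
        if pid not in bg:
            continue
        for cat in cats:
            members.setdefault(cat, set()).add(pid)

    results = []
    for cat in sorted(members):
        K = len(members[cat])
        if K == 0:
            continue
        k = len(members[cat] & sel)
        ef = (k / n) / (K / N) if n > 0 else float("nan")
        p = hypergeom_upper_tail(k, n, K, N)
        results.append(
            EnrichmentResult(
                category=cat,
                k=k,
                n=n,
                K=K,
                N=N,
                enrichment_factor=ef,
                p_value=p,
                significant=bool(ef > ef_cutoff and p < p_cutoff),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.category))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "enrichment_factor": [r.enrichment_factor for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def read_categories(path: str | Path) -> dict[str, set[str]]:
    """Read a category TSV (protein_id, category[, source]) into a map."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("protein_id", "category"):
        if col not in df.columns:
            raise ConfigurationError(f"category file missing column '{col}'")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        if row.category:
            out.setdefault(row.protein_id, set()).add(row.category)
    return out
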