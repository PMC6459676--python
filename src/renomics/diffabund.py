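"""Two-group differential abundance: Mann-Whitney U, BH correction, fold change.

A contrast (A vs B) tests every compound with a two-sided Mann-Whitney U
test, corrects across the compounds of that contrast with Benjamini-
Hochberg, and reports the ratio of group summaries (means by default) as
the fold change.  Hits are compounds with q below a cutoff and at least a
minimum fold change in either direction; the CCPAP-specific set is the
intersection of the vs-ccRCC and vs-normal hit sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import MetaboliteMatrix

__all__ = [
    "mann_whitney",
    "bh_correct",
    "fold_change",
    "run_contrast",
    "select_differential",
    "DifferentialTable",
]


@dataclass
class DifferentialTable:
    """Per-compound differential-abundance results for one contrast."""

    contrast: tuple  # (groupA, groupB)
    table: pd.DataFrame  # index compound; fold_change, log2_fold_change, p_value, q_value

    def hits(self, q_max: float = 0.1, min_fold: float = 2.0) -> set:
        t = self.table
        sel = (t["q_value"] < q_max) & (
            (t["fold_change"] > min_fold) | (t["fold_change"] < 1.0 / min_fold)
        )
        return set(t.index[sel])


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U statistic of a, p value).

    The exact null distribution is enumerated when both groups have at most
    8 observations and there are no ties; otherwise the normal approximation
    with mid-ranks and tie-corrected variance (continuity corrected) is used.
    Identical pooled values give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(a: Sequence[float], b: Sequence[float], method: str = "mean-ratio") -> float:
    """Ratio of group summaries, A over B (positive abundances assumed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "mean-ratio":
        num, den = a.mean(), b.mean()
    elif method == "median-ratio":
        num, den = np.median(a), np.median(b)
    else:
        raise ValueError(f"unknown fold-change method: {method!r}")
    if den == 0:
        raise ZeroDivisionError("zero group summary in denominator")
    return float(num / den)


def run_contrast(
    m: MetaboliteMatrix,
    group_a: str,
    group_b: str,
    fc_method: str = "mean-ratio",
    exclude_samples: Iterable[str] = (),
) -> DifferentialTable:
    """Differential abundance of every compound for group_a vs group_b.

    ``exclude_samples`` drops named samples before testing (e.g. the
    atypical high-sorbitol ccRCC samples).  BH correction spans all
    compounds of this contrast.
    """
    exclude = set(exclude_samples)
    sa = [s for s in m.group_samples(group_a) if s not in exclude]
    sb = [s for s in m.group_samples(group_b) if s not in exclude]
    if not sa:
        raise ValueError(f"group not present in matrix: {group_a!r}")
    if not sb:
        raise ValueError(f"group not present in matrix: {group_b!r}")
    rows = []
    for compound, row in m.abundances.iterrows():
        a = row[sa].dropna().to_numpy()
        b = row[sb].dropna().to_numpy()
        _, p = mann_whitney(a, b)
        fc = fold_change(a, b, fc_method)
        rows.append((compound, fc, np.log2(fc) if fc > 0 else np.nan, p))
    tab = pd.DataFrame(
        rows, columns=["compound", "fold_change", "log2_fold_change", "p_value"]
    ).set_index("compound")
    tab["q_value"] = bh_correct(tab["p_value"].to_numpy())
    return DifferentialTable((group_a, group_b), tab)


def select_differential(
    tables: Mapping[str, DifferentialTable],
    q_max: float = 0.1,
    min_fold: float = 2.0,
) -> tuple[dict, set]:
    """Per-contrast hit sets and their intersection.

    All tables must cover the same compound universe so the intersection is
    well defined.
    """
    universes = {name: frozenset(t.table.index) for name, t in tables.items()}
    if len(set(universes.values())) > 1:
        raise ValueError("contrasts cover different compound universes")
    hit_sets = {name: t.hits(q_max, min_fold) for name, t in tables.items()}
    inter = set.intersection(*hit_sets.values()) if hit_sets else set()
    return hit_sets, inter
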