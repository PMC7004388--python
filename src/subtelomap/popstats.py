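"""Population-level block frequencies and ANOVA with Bonferroni correction.

Block presence is one 0/1 indicator per genome per arm (diploid double
carriers count once).  Frequencies are carriers divided by the genomes
with an anchored map for that arm in that super-population.  For each
block, a one-way ANOVA across the five super-populations is run per arm
and the per-arm p-values are Bonferroni-corrected across the family of
arms tested for that block (the correction family is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaResult", "block_frequency_table", "anova_by_superpop",
           "bonferroni_adjust", "block_anova_scan"]


@dataclass(frozen=True)
class AnovaResult:
    block: str
    arm: str
    f_statistic: float
    p_value: float
    adjusted_p: float | None = None
    n_per_group: tuple[int, ...] = ()
    significant: bool = False
    degenerate: bool = False  # zero variance within and between groups


def block_frequency_table(presence: pd.DataFrame,
                          superpop: Mapping[str, str],
                          block: str) -> pd.DataFrame:
    """Frequency of ``block`` per arm (rows) per super-population (columns).

    ``presence`` is the genome x (arm, block) matrix from
    :func:`subtelomap.blocks.presence_matrix`; NaN marks genomes without an
    anchored map on the arm, which drop out of the denominator.  Cells are
    fractions; the raw numerators and denominators come along as extra
    column levels.
    """
    pops = sorted(set(superpop.values()))
    arms = sorted({arm for arm, b in presence.columns if b == block})
    rows = []
    for arm in arms:
        col = presence[(arm, block)]
        rec: dict = {"arm": arm}
        for pop in pops:
            members = [g for g in presence.index if superpop[g] == pop]
            values = col.loc[members].dropna()
            carriers = int(sum(bool(v) for v in values))
            total = int(len(values))
            rec[(pop, "frequency")] = carriers / total if total else np.nan
            rec[(pop, "carriers")] = carriers
            rec[(pop, "total")] = total
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("arm")
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


def anova_by_superpop(values_by_group: Mapping[str, Sequence[float]],
                      block: str = "", arm: str = "") -> AnovaResult:
    """One-way ANOVA of 0/1 presence indicators across super-populations."""
    groups = [np.asarray(values_by_group[k], dtype=float)
              for k in sorted(values_by_group)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups with observations")
    pooled = np.concatenate(groups)
    n_per_group = tuple(int(g.size) for g in groups)
    if np.allclose(pooled, pooled[0]):
        return AnovaResult(block=block, arm=arm, f_statistic=float("nan"),
                           p_value=float("nan"), n_per_group=n_per_group,
                           degenerate=True)
    f_stat, p = stats.f_oneway(*groups)
    return AnovaResult(block=block, arm=arm, f_statistic=float(f_stat),
                       p_value=float(p), n_per_group=n_per_group)


def bonferroni_adjust(results: Sequence[AnovaResult],
                      m: int | None = None,
                      alpha: float = 0.05) -> list[AnovaResult]:
    """Adjusted p = min(1, p*m); m defaults to the number of tests given."""
    m = m if m is not None else len([r for r in results if not r.degenerate])
    out = []
    for r in results:
        if r.degenerate or np.isnan(r.p_value):
            out.append(replace(r, adjusted_p=None, significant=False))
            continue
        adj = min(1.0, r.p_value * max(m, 1))
        out.append(replace(r, adjusted_p=adj, significant=adj < alpha))
    return out


def block_anova_scan(presence: pd.DataFrame, superpop: Mapping[str, str],
                     block: str, alpha: float = 0.05) -> list[AnovaResult]:
    """Per-arm ANOVA for one block, Bonferroni-corrected across those arms."""
    arms = sorted({arm for arm, b in presence.columns if b == block})
    results = []
    for arm in arms:
        col = presence[(arm, block)]
        by_group: dict[str, list[float]] = {}
        for genome, value in col.items():
            if pd.isna(value):
                continue
            by_group.setdefault(superpop[genome], []).append(float(bool(value)))
        by_group = {k: v for k, v in by_group.items() if len(v) >= 2}
        if len(by_group) < 2:
            continue
        results.append(anova_by_superpop(by_group, block=block, arm=arm))
    return bonferroni_adjust(results, alpha=alpha)
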