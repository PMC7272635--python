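"""Nonparametric comparison of treatment groups against a control.

The experimental readout (per-experiment parallel-minus-perpendicular ratio
difference) is not normally distributed, so groups are compared with the
Kruskal-Wallis one-way analysis of variance on ranks, followed by Dunn's
multiple comparisons versus the control group: rank-sum z statistics with
tie correction and a Bonferroni-style multiplicity adjustment over the k-1
comparisons, gated on a significant omnibus test.  Significance is declared
at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["DunnComparison", "KruskalDunnResult", "kruskal_dunn"]

ALPHA = 0.05


@dataclass(frozen=True)
class DunnComparison:
    """One Dunn comparison of a treatment group against the control."""

    group: str
    z: float
    p_unadjusted: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class KruskalDunnResult:
    """Omnibus Kruskal-Wallis result plus Dunn comparisons versus control."""

    H: float
    df: int
    p: float
    comparisons: tuple[DunnComparison, ...]

    @property
    def flagged(self) -> tuple[str, ...]:
        return tuple(c.group for c in self.comparisons if c.significant)


def kruskal_dunn(
    control: Sequence[float],
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
) -> KruskalDunnResult:
    """Kruskal-Wallis on ranks with Dunn's comparisons versus control.

    ``control`` and each entry of ``groups`` are independent samples (one
    value per experiment).  The omnibus H uses the standard tie correction;
    each group is then compared to the control with Dunn's rank-sum z, the
    per-comparison p doubled for two sides and multiplied by the number of
    comparisons (classic Dunn familywise control), and flagged significant
    only when the omnibus test is also significant at ``alpha``.

    Raises
    ------
    ValueError
        For fewer than one treatment group, any group with n < 3, or
        all-identical data (ranks degenerate, H undefined).
    """
    control = np.asarray(control, dtype=float)
    if len(groups) < 1:
        raise ValueError("need at least one treatment group besides the control")
    samples = {"control": control, **{k: np.asarray(v, float) for k, v in groups.items()}}
    for name, s in samples.items():
        if len(s) < 3:
            raise ValueError(f"group {name!r} has n={len(s)} < 3")
    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; ranks are degenerate and H undefined")

    H, p = sps.kruskal(*samples.values())
    k = len(samples)

    # Dunn: mean ranks over the pooled sample, tie-corrected variance
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (N - 1)))
    splits = np.cumsum([len(s) for s in samples.values()])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_rank = {name: rg.mean() for name, rg in zip(samples, rank_groups)}
    n_of = {name: len(s) for name, s in samples.items()}

    n_comp = k - 1
    comps = []
    for name in groups:
        var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / n_of[name] + 1.0 / n_of["control"])
        z = abs(mean_rank[name] - mean_rank["control"]) / np.sqrt(var)
        p_un = 2.0 * sps.norm.sf(z)
        p_adj = min(1.0, p_un * n_comp)
        comps.append(DunnComparison(
            group=name,
            z=float(z),
            p_unadjusted=float(p_un),
            p_adjusted=float(p_adj),
            significant=bool(p < alpha and p_adj < alpha),
        ))
    return KruskalDunnResult(H=float(H), df=k - 1, p=float(p),
                             comparisons=tuple(comps))
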