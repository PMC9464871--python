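"""Significance machinery: one-way ANOVA with Holm-corrected post-hoc t-tests.

The workflow mirrors common practice for comparing per-slide accuracy
distributions across quality grades or source sites: a one-way fixed-effects
ANOVA over all groups, followed by all pairwise two-sample t-tests with the
Holm step-down adjustment of p-values at a family-wise alpha of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "one_way_anova",
    "holm_adjust",
    "pairwise_t_holm",
    "PosthocResult",
    "PairResult",
]


def _check_groups(groups: Mapping[str, Sequence[float]], min_obs: int = 2) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_obs:
            raise ValueError(
                f"group {name!r} has {arr.size} observations; need >= {min_obs}"
            )
        out[name] = arr
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA; returns (F, p).

    F = MS_between / MS_within on (k-1, N-k) degrees of freedom, with p from
    the upper tail of the F distribution.
    """
    g = _check_groups(groups)
    if all(np.var(a) == 0 for a in g.values()):
        raise ValueError("degenerate ANOVA: zero within-group variance in all groups")
    f, p = sps.f_oneway(*g.values())
    return float(f), float(p)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sort ascending, multiply p_(i) by (m - i + 1), take the running maximum,
    clip at 1; ordering of the input is preserved in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class PairResult:
    group_i: str
    group_j: str
    t_stat: float
    raw_p: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class PosthocResult:
    """ANOVA F/p plus all pairwise Holm-adjusted comparisons."""

    anova_f: float
    anova_p: float
    alpha: float
    pairs: tuple[PairResult, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.__dict__ for p in self.pairs])

    def format_matrix(self) -> str:
        """Pairwise adjusted-p matrix with significance stars."""
        names = sorted({p.group_i for p in self.pairs} | {p.group_j for p in self.pairs})
        cell = {}
        for p in self.pairs:
            text = f"{p.adjusted_p:.4g}" + ("*" if p.significant else "")
            cell[(p.group_i, p.group_j)] = text
            cell[(p.group_j, p.group_i)] = text
        width = max(8, max(len(n) for n in names) + 1)
        lines = ["".rjust(width) + "".join(n.rjust(width) for n in names)]
        for a in names:
            row = [a.rjust(width)]
            for b in names:
                row.append(("-" if a == b else cell.get((a, b), "")).rjust(width))
            lines.append("".join(row))
        return "\n".join(lines)


def pairwise_t_holm(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> PosthocResult:
    """All k(k-1)/2 pairwise two-sided t-tests with Holm adjustment.

    Pooled-variance t-tests by default (the classical post-hoc after ANOVA);
    set ``equal_var=False`` for Welch tests.  A pair is significant iff its
    adjusted p-value is below ``alpha``.
    """
    g = _check_groups(groups)
    anova_f, anova_p = one_way_anova(groups)
    names = sorted(g)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw = []
    tstats = []
    for a, b in pairs:
        t, p = sps.ttest_ind(g[a], g[b], equal_var=equal_var)
        tstats.append(float(t))
        raw.append(float(p))
    adj = holm_adjust(raw)
    results = tuple(
        PairResult(
            group_i=a,
            group_j=b,
            t_stat=t,
            raw_p=p,
            adjusted_p=float(q),
            significant=bool(q < alpha),
        )
        for (a, b), t, p, q in zip(pairs, tstats, raw, adj)
    )
    return PosthocResult(anova_f=anova_f, anova_p=anova_p, alpha=alpha, pairs=results)
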