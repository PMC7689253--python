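"""Group comparisons: one-way ANOVA with compact letter display, and
labeled-vs-control pairwise tests.

Depth effects on the potentials are assessed by classical fixed-effects
one-way ANOVA; post-hoc pairwise separation uses Tukey's HSD (the
standard choice for a balanced n=3 design; Fisher's LSD is available for
sensitivity), summarized as a compact letter display (CLD): groups
sharing a letter do not differ at alpha.  Labeled-vs-control contrasts
use Welch's unequal-variance t-test, which does not assume equal
replicate variance between treatments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedValues",
    "LetterDisplay",
    "one_way_anova",
    "tukey_letters",
    "pairwise_welch",
    "compact_letter_display",
    "stats_summary",
]

GroupedValues = Mapping[str, Sequence[float]]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class LetterDisplay:
    letters: dict[str, str]  # group -> sorted letter string, e.g. "ab"
    alpha: float
    pairwise_p: dict[tuple[str, str], float]


def _validate_groups(groups: GroupedValues) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 replicates")
        arrays[str(name)] = arr
    return arrays


def one_way_anova(groups: GroupedValues) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA: F = MSB/MSW.

    All-identical data (zero between- and within-group variance) is
    reported as F = 0, p = 1 rather than NaN.
    """
    arrays = _validate_groups(groups)
    k = len(arrays)
    n = sum(a.size for a in arrays.values())
    df_between, df_within = k - 1, n - k
    f, p = stats.f_oneway(*arrays.values())
    if not math.isfinite(f):  # constant input degenerate case
        f, p = 0.0, 1.0
    return AnovaResult(float(f), float(p), df_between, df_within)


def _tukey_pairwise_p(arrays: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    names = list(arrays)
    res = stats.tukey_hsd(*[arrays[g] for g in names])
    out = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        if math.isnan(p):  # zero pooled variance: identical -> 1, else 0
            p = 1.0 if np.allclose(arrays[names[i]].mean(), arrays[names[j]].mean()) else 0.0
        out[(names[i], names[j])] = p
    return out


def _lsd_pairwise_p(arrays: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Fisher's LSD: unadjusted pairwise t-tests on the pooled MSW."""
    names = list(arrays)
    n = sum(a.size for a in arrays.values())
    df_w = n - len(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    msw = ssw / df_w
    out = {}
    for gi, gj in itertools.combinations(names, 2):
        a, b = arrays[gi], arrays[gj]
        se = math.sqrt(msw * (1 / a.size + 1 / b.size))
        if se == 0:
            out[(gi, gj)] = 1.0 if a.mean() == b.mean() else 0.0
            continue
        t = (a.mean() - b.mean()) / se
        out[(gi, gj)] = float(2 * stats.t.sf(abs(t), df_w))
    return out


def compact_letter_display(
    group_names: Sequence[str],
    pairwise_p: Mapping[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Insert–absorb compact letter display.

    Starts from one letter column containing all groups; every
    significant pair splits the columns it shares until the
    sharing-a-letter relation exactly mirrors non-significance; absorbed
    (subset) columns are removed.  Letters are assigned a, b, c, ... in
    order of first use.
    """
    names = list(group_names)
    sig = {
        frozenset(pair) for pair, p in pairwise_p.items() if p < alpha
    }
    columns: list[set[str]] = [set(names)]
    for pair in sorted(sig, key=sorted):
        a, b = sorted(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            col_a, col_b = col - {b}, col - {a}
            for new in (col_a, col_b):
                # absorb: keep only maximal columns
                if not any(new <= other for other in columns):
                    columns = [c for c in columns if not (c < new)] + [new]
    columns.sort(key=lambda c: min(names.index(g) for g in c))
    letters = {g: "" for g in names}
    for letter, col in zip(_letter_stream(), columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def _letter_stream():
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)


def tukey_letters(
    groups: GroupedValues, alpha: float = 0.05, method: str = "tukey"
) -> LetterDisplay:
    """Compact letter display over Tukey-adjusted (or LSD) pairwise p values."""
    arrays = _validate_groups(groups)
    if method == "tukey":
        pairwise = _tukey_pairwise_p(arrays)
    elif method == "lsd":
        pairwise = _lsd_pairwise_p(arrays)
    else:
        raise ValueError(f"method must be tukey|lsd, got {method!r}")
    letters = compact_letter_display(list(arrays), pairwise, alpha)
    return LetterDisplay(letters=letters, alpha=alpha, pairwise_p=pairwise)


def pairwise_welch(labeled: Sequence[float], control: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test p value.

    The degenerate case — zero variance on both sides with equal means —
    returns p = 1.
    """
    a = np.asarray(list(labeled), dtype=float)
    b = np.asarray(list(control), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each side needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def stats_summary(
    values: pd.DataFrame,
    value_col: str,
    group_col: str = "depth_label",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group means ± sd with ANOVA F/p and Tukey letters, one row per group."""
    groups = {
        str(g): grp[value_col].to_numpy()
        for g, grp in values.groupby(group_col, sort=False)
    }
    anova = one_way_anova(groups)
    display = tukey_letters(groups, alpha=alpha)
    rows = []
    for g, arr in groups.items():
        arr = np.asarray(arr, dtype=float)
        rows.append(
            {
                group_col: g,
                "variable": value_col,
                "mean": arr.mean(),
                "sd": arr.std(ddof=1),
                "n": arr.size,
                "letters": display.letters[g],
                "anova_F": anova.f_statistic,
                "anova_p": anova.p_value,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)
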