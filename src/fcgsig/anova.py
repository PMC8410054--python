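"""Three-way factorial ANOVA with Type III sums of squares and
Sidak-adjusted pairwise comparisons.

Type III SS are computed as full-versus-reduced residual-sum-of-squares
differences under sum-to-zero effect coding, which reduces to the classical
balanced-design formulas when cells are balanced and remains well defined
for the unbalanced n=5-6 cell sizes of phenotype experiments.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

TERMS = ("treatment", "chromosomal_sex", "gonadal_sex",
         "treatment:chromosomal_sex", "treatment:gonadal_sex",
         "chromosomal_sex:gonadal_sex",
         "treatment:chromosomal_sex:gonadal_sex")


def _effect_column(labels: pd.Series) -> np.ndarray:
    """Sum-to-zero (+1/-1) coding for a two-level factor."""
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"factor must have exactly 2 levels, got {levels}")
    return np.where(labels == levels[0], 1.0, -1.0)


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def three_way_anova(values, factors: pd.DataFrame) -> pd.DataFrame:
    """Type III three-way ANOVA table for a 2x2x2 design.

    ``factors`` must contain columns treatment, chromosomal_sex and
    gonadal_sex (two levels each). Returns a table with sum_sq, df, F and p
    per term plus a Residual row.
    """
    y = np.asarray(values, dtype=float)
    if len(y) != len(factors):
        raise ValueError("values and factors lengths differ")
    needed = ("treatment", "chromosomal_sex", "gonadal_sex")
    missing = [c for c in needed if c not in factors.columns]
    if missing:
        raise ValueError(f"factors table is missing {missing}")

    main = {name: _effect_column(factors[name]) for name in needed}

    observed = set(map(tuple, factors[list(needed)].itertuples(index=False)))
    levels = [sorted(factors[name].unique()) for name in needed]
    expected = set(itertools.product(*levels))
    empty = sorted(expected - observed)
    if empty:
        raise ValueError(f"empty design cell(s): {empty}; the "
                         "three-way interaction is not estimable")
    columns: dict[str, np.ndarray] = {}
    for order in (1, 2, 3):
        for combo in itertools.combinations(needed, order):
            col = np.ones(len(y))
            for name in combo:
                col = col * main[name]
            columns[":".join(combo)] = col

    full = np.column_stack([np.ones(len(y))] + [columns[t] for t in TERMS])
    rss_full = _rss(full, y)
    df_res = len(y) - full.shape[1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = rss_full / df_res

    rows = []
    for term in TERMS:
        reduced = np.column_stack(
            [np.ones(len(y))] + [columns[t] for t in TERMS if t != term])
        ss = max(_rss(reduced, y) - rss_full, 0.0)
        f = (ss / 1.0) / ms_res if ms_res > 0 else np.inf if ss > 0 else 0.0
        p = stats.f.sf(f, 1, df_res) if np.isfinite(f) else 0.0
        rows.append({"term": term, "sum_sq": ss, "df": 1.0, "F": f, "p": p})
    rows.append({"term": "Residual", "sum_sq": rss_full,
                 "df": float(df_res), "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


def sidak_adjust(p, m: int):
    """Sidak family-wise adjustment: 1 - (1-p)^m, clipped to 1."""
    if m < 1:
        raise ValueError("m must be at least 1")
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.minimum(1.0 - (1.0 - p_arr) ** m, 1.0)
    return float(adjusted) if np.isscalar(p) else adjusted


def pairwise_posthoc(values, groups, comparisons) -> pd.DataFrame:
    """Pairwise comparisons on the pooled within-group error.

    ``comparisons`` is a list of (group_a, group_b) label pairs; all pairs in
    the request form one Sidak family (m = number of comparisons).
    """
    y = np.asarray(values, dtype=float)
    groups = pd.Series(list(groups))
    if len(y) != len(groups):
        raise ValueError("values and groups lengths differ")
    known = set(groups)
    for a, b in comparisons:
        for label in (a, b):
            if label not in known:
                raise ValueError(f"unknown group label {label!r}")

    stats_by_group = {}
    ss_within = 0.0
    for label in known:
        vals = y[groups.to_numpy() == label]
        stats_by_group[label] = (len(vals), vals.mean())
        ss_within += ((vals - vals.mean()) ** 2).sum()
    df_res = len(y) - len(known)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom for pooled error")
    mse = ss_within / df_res

    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        na, ma = stats_by_group[a]
        nb, mb = stats_by_group[b]
        diff = ma - mb
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p = 2.0 * stats.t.sf(abs(t), df_res) if np.isfinite(t) else 0.0
        rows.append({"group_a": a, "group_b": b, "mean_diff": diff,
                     "t": t, "p": p, "p_sidak": sidak_adjust(p, m), "m": m})
    return pd.DataFrame(rows)
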