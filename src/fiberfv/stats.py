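"""Group comparisons for fiber contractile properties.

Implements the three analyses used to compare species × fiber-type groups:

* two-way fixed-effects ANOVA (species, fiber type, interaction) with
  Type III (default) or Type II sums of squares, computed by explicit
  nested-linear-model SSE comparisons under sum-to-zero factor coding —
  Type III is the convention of mainstream commercial packages for
  unbalanced designs;
* Bonferroni-corrected pairwise post-hoc contrasts between design cells,
  performed when the interaction is of interest;
* forward stepwise linear regression with a partial-F entry test
  (default entry threshold p < 0.10), reporting the adjusted-R² trajectory.

All model fitting is ordinary least squares via numpy's lstsq; p-values come
from scipy's F and t distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "AnovaResult",
    "EffectResult",
    "PosthocContrast",
    "StepwiseResult",
    "two_way_anova",
    "one_way_f",
    "bonferroni_posthoc",
    "stepwise_regression",
    "encode_binary",
]

# condition-number bound above which a stepwise candidate is skipped
COLLINEARITY_BOUND = 1e8


@dataclass(frozen=True)
class EffectResult:
    ss: float
    df: int
    f: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict  # name -> EffectResult for species, fiber_type, interaction
    residual_ss: float
    residual_df: int
    ss_type: int
    response: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": k, "ss": e.ss, "df": e.df, "F": e.f, "p": e.p}
            for k, e in self.effects.items()
        ]
        rows.append(
            {"effect": "residual", "ss": self.residual_ss,
             "df": self.residual_df, "F": np.nan, "p": np.nan}
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PosthocContrast:
    cell_a: tuple
    cell_b: tuple
    mean_a: float
    mean_b: float
    t: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class StepwiseResult:
    steps: list  # (name, entry_p, r2_adj after entry)
    coefficients: dict  # final OLS coefficients incl. intercept
    entry_alpha: float
    skipped: tuple = field(default_factory=tuple)  # collinear candidates

    @property
    def entered(self) -> list:
        return [s[0] for s in self.steps]


def _sse(y: np.ndarray, x: np.ndarray) -> float:
    """Residual sum of squares of y on the columns of x (OLS)."""
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def encode_binary(values: pd.Series) -> np.ndarray:
    """0/1-code a two-level factor, levels in sorted order (e.g. human=1
    after bonobo=0, I=0 before II=1)."""
    levels = sorted(pd.unique(values))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 levels, got {levels}")
    return (np.asarray(values) == levels[1]).astype(float)


def _design_columns(table: pd.DataFrame, factor_a: str, factor_b: str):
    """Sum-to-zero (±1) codes for the two factors and their product."""
    a_levels = sorted(pd.unique(table[factor_a]))
    b_levels = sorted(pd.unique(table[factor_b]))
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("two_way_anova requires two levels per factor")
    a = np.where(np.asarray(table[factor_a]) == a_levels[0], 1.0, -1.0)
    b = np.where(np.asarray(table[factor_b]) == b_levels[0], 1.0, -1.0)
    return a, b, a * b


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str = "species",
    factor_b: str = "fiber_type",
    ss_type: int = 3,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA via nested-model SSE comparisons.

    With Type III sums of squares each effect's SS is the SSE increase from
    dropping that effect's column from the full (sum-coded) model; Type II
    drops main effects from the main-effects-only model.  Requires all four
    cells non-empty for Type III.
    """
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    data = table.dropna(subset=[response])
    y = np.asarray(data[response], dtype=float)
    n = y.size
    a, b, ab = _design_columns(data, factor_a, factor_b)

    cells = data.groupby([factor_a, factor_b], observed=True).size()
    if ss_type == 3 and len(cells) < 4:
        present = set(cells.index)
        all_cells = {
            (x, z)
            for x in pd.unique(data[factor_a])
            for z in pd.unique(data[factor_b])
        }
        missing = sorted(all_cells - present)
        raise ValueError(f"empty design cell(s) for Type III ANOVA: {missing}")

    ones = np.ones(n)
    full = np.column_stack([ones, a, b, ab])
    sse_full = _sse(y, full)
    df_res = n - 4
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    if ss_type == 3:
        ss_a = _sse(y, np.column_stack([ones, b, ab])) - sse_full
        ss_b = _sse(y, np.column_stack([ones, a, ab])) - sse_full
        ss_ab = _sse(y, np.column_stack([ones, a, b])) - sse_full
    else:  # Type II
        sse_main = _sse(y, np.column_stack([ones, a, b]))
        ss_a = _sse(y, np.column_stack([ones, b])) - sse_main
        ss_b = _sse(y, np.column_stack([ones, a])) - sse_main
        ss_ab = sse_main - sse_full

    mse = sse_full / df_res
    effects = {}
    for name, ss in ((factor_a, ss_a), (factor_b, ss_b), ("interaction", ss_ab)):
        ss = max(ss, 0.0)
        f = ss / mse if mse > 0 else np.inf
        p = float(_sps.f.sf(f, 1, df_res))
        effects[name] = EffectResult(ss=ss, df=1, f=float(f), p=p)
    return AnovaResult(
        effects=effects,
        residual_ss=sse_full,
        residual_df=df_res,
        ss_type=ss_type,
        response=response,
    )


def one_way_f(table: pd.DataFrame, response: str, factor: str) -> EffectResult:
    """Single-factor (two-level) ANOVA F test via the same nested-SSE route.

    For two groups this F equals the square of the pooled two-sample t
    statistic — a useful identity check on the machinery.
    """
    data = table.dropna(subset=[response])
    y = np.asarray(data[response], dtype=float)
    x = encode_binary(data[factor])
    n = y.size
    ones = np.ones(n)
    sse0 = _sse(y, ones[:, None])
    sse1 = _sse(y, np.column_stack([ones, x]))
    df_res = n - 2
    f = (sse0 - sse1) / (sse1 / df_res)
    return EffectResult(ss=sse0 - sse1, df=1, f=float(f),
                        p=float(_sps.f.sf(f, 1, df_res)))


DEFAULT_CONTRASTS = (
    (("bonobo", "I"), ("human", "I")),
    (("bonobo", "II"), ("human", "II")),
    (("bonobo", "I"), ("bonobo", "II")),
    (("human", "I"), ("human", "II")),
)


def bonferroni_posthoc(
    table: pd.DataFrame,
    response: str,
    contrasts=DEFAULT_CONTRASTS,
    factor_a: str = "species",
    factor_b: str = "fiber_type",
) -> list:
    """Pairwise two-sample t-tests between design cells, Bonferroni-adjusted.

    The adjusted p-value is the raw p multiplied by the number of contrasts,
    capped at 1.  Contrasts referencing an absent cell raise.
    """
    m = len(contrasts)
    groups = {
        key: np.asarray(sub[response].dropna(), dtype=float)
        for key, sub in table.groupby([factor_a, factor_b], observed=True)
    }
    out = []
    for cell_a, cell_b in contrasts:
        for cell in (cell_a, cell_b):
            if tuple(cell) not in groups:
                raise ValueError(f"contrast references absent cell {cell}")
        ya, yb = groups[tuple(cell_a)], groups[tuple(cell_b)]
        t, p_raw = _sps.ttest_ind(ya, yb, equal_var=True)
        out.append(
            PosthocContrast(
                cell_a=tuple(cell_a),
                cell_b=tuple(cell_b),
                mean_a=float(ya.mean()),
                mean_b=float(yb.mean()),
                t=float(t),
                p_raw=float(p_raw),
                p_adjusted=float(min(1.0, m * p_raw)),
            )
        )
    return out


def _r2_adj(y: np.ndarray, x: np.ndarray) -> float:
    n, p = x.shape  # p includes the intercept column
    sse = _sse(y, x)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0 or n - p <= 0:
        return float("nan")
    return 1.0 - (sse / (n - p)) / (sst / (n - 1))


def stepwise_regression(
    table: pd.DataFrame,
    response: str,
    candidates=("species", "fiber_type", "specific_tension", "vmax", "a_over_po"),
    entry_alpha: float = 0.10,
) -> StepwiseResult:
    """Forward stepwise OLS with a partial-F entry rule.

    At each round the remaining candidate with the smallest partial-F
    p-value enters, provided p < ``entry_alpha``; the search stops when no
    candidate qualifies.  Two-level string factors are 0/1 coded.  A
    candidate whose addition makes the design numerically collinear
    (condition number above 1e8) is skipped with a warning.
    """
    data = table.dropna(subset=[response, *candidates])
    y = np.asarray(data[response], dtype=float)
    n = y.size
    if n <= len(candidates) + 2:
        raise ValueError("need n > number of candidates + 2")

    cols = {}
    for c in candidates:
        v = data[c]
        if v.dtype == object or str(v.dtype) == "category":
            cols[c] = encode_binary(v)
        else:
            cols[c] = np.asarray(v, dtype=float)

    entered: list[str] = []
    skipped: list[str] = []
    steps = []
    x_cur = np.ones((n, 1))
    sse_cur = _sse(y, x_cur)
    while True:
        best = None
        df_full = n - (x_cur.shape[1] + 1)
        if df_full < 1:
            break
        for c in candidates:
            if c in entered or c in skipped:
                continue
            x_try = np.column_stack([x_cur, cols[c]])
            if np.linalg.cond(x_try) > COLLINEARITY_BOUND:
                warnings.warn(f"candidate {c!r} is collinear; skipped",
                              stacklevel=2)
                skipped.append(c)
                continue
            sse_try = _sse(y, x_try)
            f = (sse_cur - sse_try) / (sse_try / df_full) if sse_try > 0 else np.inf
            p = float(_sps.f.sf(f, 1, df_full))
            if best is None or p < best[1]:
                best = (c, p, x_try, sse_try)
        if best is None or not best[1] < entry_alpha:
            break
        c, p, x_cur, sse_cur = best
        entered.append(c)
        steps.append((c, p, _r2_adj(y, x_cur)))

    beta, _, _, _ = np.linalg.lstsq(x_cur, y, rcond=None)
    coefficients = {"intercept": float(beta[0])}
    for i, c in enumerate(entered, start=1):
        coefficients[c] = float(beta[i])
    return StepwiseResult(
        steps=steps,
        coefficients=coefficients,
        entry_alpha=entry_alpha,
        skipped=tuple(skipped),
    )
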