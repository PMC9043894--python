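"""Split-plot repeated-measures ANOVA for the factorial time-course design.

The design has one within-subject factor (sampling time, ``k`` levels)
and one or more crossed between-subject factors (soil site, water
content, temperature, or sterilization).  A "subject" is one replicate
series within a condition: replicate ``r``'s measurements across all time
levels form one series.

Decomposition (balanced design):

* between-subject effects are tested on the time-averaged responses
  against the subject-within-cells error (this equals the standard
  factorial ANOVA of the subject means);
* the time main effect and every time x between-factor interaction are
  tested against the subject x time residual;
* a single Greenhouse-Geisser epsilon, computed from the pooled
  within-cell covariance of the time levels, rescales the degrees of
  freedom of every within-subject test;
* orthonormal polynomial contrasts over the time levels (rank-spaced by
  default, metric-spaced by actual days as an option) give one
  single-degree-of-freedom F per polynomial order.

Factorial sums of squares are computed by inclusion-exclusion over
marginal means, which is exact for balanced designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectSeries",
    "RmAnovaResult",
    "DesignError",
    "subject_series",
    "rm_anova",
    "polynomial_time_contrasts",
    "polynomial_contrast_matrix",
]


class DesignError(ValueError):
    """The between-subject design is empty, unbalanced, or underpowered."""


@dataclass
class SubjectSeries:
    """One replicate's complete ordered response series across time levels."""

    subject_id: tuple
    levels: dict
    responses: np.ndarray


@dataclass
class RmAnovaResult:
    """Between, within, and polynomial-contrast tables of one analysis."""

    between: pd.DataFrame
    within: pd.DataFrame
    contrasts: pd.DataFrame
    gg_epsilon: float
    n_subjects: int
    n_cells: int
    n_time_levels: int
    times: np.ndarray
    degenerate: bool = False


def _pivot(
    table: pd.DataFrame,
    between: list[str],
    time_col: str,
    response_col: str,
    subject_cols: tuple[str, ...],
):
    """Wide subject x time matrix plus per-subject between-factor levels."""
    for col in [*between, time_col, response_col, *subject_cols]:
        if col not in table.columns:
            raise KeyError(f"column {col!r} missing from measurement table")
    wide = table.pivot_table(
        index=[*subject_cols, *between],
        columns=time_col,
        values=response_col,
        aggfunc="mean",
    )
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        dropped = [str(ix) for ix in wide.index[incomplete]]
        warnings.warn(
            f"excluding {len(dropped)} incomplete subject series: "
            + ", ".join(dropped[:5])
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=3,
        )
        wide = wide.loc[~incomplete]
    if wide.empty:
        raise DesignError("no complete subject series")
    y = wide.to_numpy(dtype=float)
    times = np.asarray(wide.columns, dtype=float)
    levels = wide.index.to_frame(index=False)
    return y, times, levels[list(between)].reset_index(drop=True), levels


def subject_series(
    table: pd.DataFrame,
    between: list[str],
    *,
    time_col: str = "time_days",
    response_col: str = "concentration_ng_per_g",
    subject_cols: tuple[str, ...] = ("condition_id", "replicate"),
) -> list[SubjectSeries]:
    """Assemble complete per-subject response series from a long table."""
    y, _, lv, full = _pivot(table, between, time_col, response_col, subject_cols)
    out = []
    for i in range(y.shape[0]):
        sid = tuple(full.iloc[i][list(subject_cols)])
        out.append(
            SubjectSeries(
                subject_id=sid, levels=dict(lv.iloc[i]), responses=y[i].copy()
            )
        )
    return out


def _check_cells(levels: pd.DataFrame, between: list[str]) -> pd.Series:
    cell = levels.apply(tuple, axis=1) if between else pd.Series(
        [()] * len(levels)
    )
    counts = cell.value_counts()
    n_expected = int(np.prod([levels[f].nunique() for f in between])) if between else 1
    if counts.size != n_expected:
        raise DesignError(
            f"empty design cells: expected {n_expected} cells, found {counts.size}"
        )
    if (counts < 2).any():
        raise DesignError("each between-subject cell needs >= 2 subjects")
    return cell


def _term_effect(values: np.ndarray, levels: pd.DataFrame, term: tuple[str, ...]):
    """Per-row inclusion-exclusion effect estimate for one factorial term."""
    n = values.size
    eff = np.zeros(n)
    series = pd.Series(values)
    for r in range(len(term) + 1):
        for sub in combinations(term, r):
            sign = (-1) ** (len(term) - len(sub))
            if sub:
                marg = series.groupby(
                    [levels[c] for c in sub], sort=False
                ).transform("mean").to_numpy()
            else:
                marg = np.full(n, values.mean())
            eff += sign * marg
    return eff


def _effect_terms(factors: list[str]) -> list[tuple[str, ...]]:
    terms = []
    for r in range(1, len(factors) + 1):
        terms.extend(combinations(factors, r))
    return terms


def _gg_epsilon(y: np.ndarray, cell: pd.Series) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-cell covariance."""
    n, k = y.shape
    n_cells = cell.nunique()
    resid = np.empty_like(y)
    for c in cell.unique():
        mask = (cell == c).to_numpy()
        resid[mask] = y[mask] - y[mask].mean(axis=0)
    dof = n - n_cells
    if dof < 1:
        return 1.0
    s = resid.T @ resid / dof
    s_dc = s - s.mean(axis=0)[None, :] - s.mean(axis=1)[:, None] + s.mean()
    denom = (k - 1) * float((s_dc**2).sum())
    if denom <= 0:
        return 1.0
    eps = float(np.trace(s_dc) ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _f_row(ss: float, df: int, ms_err: float, df_err: int):
    if df < 1 or df_err < 1 or ms_err <= 0:
        return np.nan, np.nan
    f_stat = (ss / df) / ms_err
    return f_stat, float(stats.f.sf(f_stat, df, df_err))


def polynomial_contrast_matrix(
    k: int, max_order: int, spacing: np.ndarray | None = None
) -> np.ndarray:
    """Orthonormal polynomial contrast vectors, one column per order.

    ``spacing=None`` uses equally spaced level ranks (SPSS default);
    otherwise the actual time values are used as the metric.  Columns are
    mutually orthogonal, unit norm, and orthogonal to the constant.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if max_order >= k:
        raise ValueError(
            f"polynomial order {max_order} needs more than {k} time levels"
        )
    x = np.arange(k, dtype=float) if spacing is None else np.asarray(
        spacing, dtype=float
    )
    if x.size != k:
        raise ValueError("spacing length must equal the number of time levels")
    # centre and scale for numerical stability before orthogonalization
    xs = (x - x.mean()) / (x.max() - x.min())
    v = np.vander(xs, N=max_order + 1, increasing=True)
    q, r = np.linalg.qr(v)
    q = q * np.sign(np.diag(r))[None, :]
    return q[:, 1:]


def _contrast_table(
    y: np.ndarray,
    cell: pd.Series,
    times: np.ndarray,
    max_order: int,
    spacing: str,
) -> pd.DataFrame:
    n, k = y.shape
    n_cells = cell.nunique()
    sp = None if spacing == "rank" else times
    cmat = polynomial_contrast_matrix(k, max_order, spacing=sp)
    names = ["linear", "quadratic", "cubic"]
    rows = []
    for order in range(1, max_order + 1):
        scores = y @ cmat[:, order - 1]
        ss_eff = n * float(scores.mean() ** 2)
        ss_err = 0.0
        for c in cell.unique():
            sc = scores[(cell == c).to_numpy()]
            ss_err += float(((sc - sc.mean()) ** 2).sum())
        df_err = n - n_cells
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        f_stat, p = _f_row(ss_eff, 1, ms_err, df_err)
        rows.append(
            {
                "order": order,
                "name": names[order - 1] if order <= 3 else f"order{order}",
                "ss": ss_eff,
                "df": 1,
                "ss_error": ss_err,
                "df_error": df_err,
                "F": f_stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def rm_anova(
    table: pd.DataFrame,
    between: list[str],
    *,
    time_col: str = "time_days",
    response_col: str = "concentration_ng_per_g",
    subject_cols: tuple[str, ...] = ("condition_id", "replicate"),
    max_poly_order: int = 3,
    poly_spacing: str = "rank",
) -> RmAnovaResult:
    """Run the split-plot repeated-measures ANOVA on a long-format table.

    Parameters
    ----------
    table:
        Long-format measurements; one row per (subject, time).
    between:
        Between-subject factor column names (crossed, balanced).
    poly_spacing:
        ``"rank"`` (equally spaced level codes) or ``"metric"``
        (actual day values) for the polynomial contrasts.

    Returns a :class:`RmAnovaResult` whose ``within`` table carries both
    uncorrected and Greenhouse-Geisser-corrected p-values.
    """
    if poly_spacing not in ("rank", "metric"):
        raise ValueError("poly_spacing must be 'rank' or 'metric'")
    y, times, levels, _ = _pivot(
        table, list(between), time_col, response_col, subject_cols
    )
    n, k = y.shape
    cell = _check_cells(levels, list(between))
    n_cells = cell.nunique()

    # ---- between-subject part: factorial ANOVA of the subject means ----
    m = y.mean(axis=1)
    cell_means = pd.Series(m).groupby(cell, sort=False).transform("mean").to_numpy()
    ss_subj = float(((m - cell_means) ** 2).sum())
    df_subj = n - n_cells
    ms_subj = ss_subj / df_subj if df_subj > 0 else 0.0

    between_rows = []
    for term in _effect_terms(list(between)):
        eff = _term_effect(m, levels, term)
        ss = float((eff**2).sum())
        df = int(np.prod([levels[f].nunique() - 1 for f in term]))
        f_stat, p = _f_row(ss, df, ms_subj, df_subj)
        between_rows.append(
            {
                "effect": ":".join(term),
                "ss": ss,
                "df": df,
                "ms": ss / df if df else np.nan,
                "F": f_stat,
                "p": p,
            }
        )
    between_rows.append(
        {
            "effect": "subjects(within cells)",
            "ss": ss_subj,
            "df": df_subj,
            "ms": ms_subj,
            "F": np.nan,
            "p": np.nan,
        }
    )
    between_tbl = pd.DataFrame(between_rows)

    # ---- within-subject part on subject-centred responses ----
    z = y - m[:, None]
    z_flat = z.ravel()
    long_levels = pd.DataFrame(
        {f: np.repeat(levels[f].to_numpy(), k) for f in between}
    )
    long_levels["__time__"] = np.tile(np.arange(k), n)

    within_rows = []
    ss_within_total = float((z_flat**2).sum())
    ss_model = 0.0
    eps = _gg_epsilon(y, cell)
    df_err = (n - n_cells) * (k - 1)

    within_terms = [("__time__",)] + [
        ("__time__",) + term for term in _effect_terms(list(between))
    ]
    term_ss = {}
    for term in within_terms:
        eff = _term_effect(z_flat, long_levels, term)
        term_ss[term] = float((eff**2).sum())
        ss_model += term_ss[term]
    ss_err = max(0.0, ss_within_total - ss_model)
    ms_err = ss_err / df_err if df_err > 0 else 0.0

    for term in within_terms:
        ss = term_ss[term]
        df = k - 1
        for f in term[1:]:
            df *= levels[f].nunique() - 1
        f_stat, p = _f_row(ss, df, ms_err, df_err)
        if np.isfinite(f_stat):
            p_gg = float(stats.f.sf(f_stat, eps * df, eps * df_err))
        else:
            p_gg = np.nan
        label = ":".join(("time",) + term[1:])
        within_rows.append(
            {
                "effect": label,
                "ss": ss,
                "df": df,
                "ms": ss / df if df else np.nan,
                "F": f_stat,
                "p_uncorrected": p,
                "gg_epsilon": eps,
                "p_gg": p_gg,
            }
        )
    within_rows.append(
        {
            "effect": "error(time x subjects)",
            "ss": ss_err,
            "df": df_err,
            "ms": ms_err,
            "F": np.nan,
            "p_uncorrected": np.nan,
            "gg_epsilon": eps,
            "p_gg": np.nan,
        }
    )
    within_tbl = pd.DataFrame(within_rows)

    contrasts = _contrast_table(
        y, cell, times, min(max_poly_order, k - 1), poly_spacing
    )
    degenerate = ss_within_total == 0.0 and ss_subj == 0.0
    return RmAnovaResult(
        between=between_tbl,
        within=within_tbl,
        contrasts=contrasts,
        gg_epsilon=eps,
        n_subjects=n,
        n_cells=n_cells,
        n_time_levels=k,
        times=times,
        degenerate=degenerate,
    )


def polynomial_time_contrasts(
    table: pd.DataFrame,
    between: list[str],
    *,
    time_col: str = "time_days",
    response_col: str = "concentration_ng_per_g",
    subject_cols: tuple[str, ...] = ("condition_id", "replicate"),
    max_order: int = 3,
    spacing: str = "rank",
) -> pd.DataFrame:
    """Polynomial trend tests of the time effect (one F and p per order)."""
    if spacing not in ("rank", "metric"):
        raise ValueError("spacing must be 'rank' or 'metric'")
    y, times, levels, _ = _pivot(
        table, list(between), time_col, response_col, subject_cols
    )
    cell = _check_cells(levels, list(between))
    return _contrast_table(y, cell, times, max_order, spacing)
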