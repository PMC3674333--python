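"""Fully within-subject factorial repeated-measures ANOVA and Fisher LSD.

Model.  Every factor is within-subject and the design is complete and
balanced: exactly one observation per subject per cell.  The classical
univariate decomposition treats subject as a random blocking factor crossed
with all treatment factors.  For an effect E (any main effect or
interaction),

    SS_E        from the marginal cell means of E,
    SS_error(E) = the E x subject interaction sum of squares,
    df_E        = prod over factors in E of (levels - 1),
    df_error(E) = df_E * (n_subjects - 1),
    F           = MS_E / MS_error(E),
    partial eta^2 = SS_E / (SS_E + SS_error(E)).

Sums of squares are computed by the finite Moebius (Yates) expansion over
marginal means; by orthogonality of the expansion the SS of all effects, all
error strata and the subject stratum add up to the total SS, which
:func:`rm_anova` verifies and records.

No sphericity correction is applied by default (the reported statistics use
uncorrected degrees of freedom); a Greenhouse-Geisser epsilon per effect is
available as an advisory column behind the ``gg`` flag.

Fisher's LSD post-hoc comparisons use the error stratum of the effect whose
cells are compared (standard repeated-measures LSD convention) and apply no
multiplicity adjustment.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, ParameterError

#: factor structures of the two reported models
MAIN_MODEL_FACTORS = ("condition", "movement", "tdcs", "hemisphere")
SURROUND_MODEL_FACTORS = ("condition", "movement", "tdcs", "electrodes")


def _pivot(
    data: pd.DataFrame, dv: str, subject: str, within: Sequence[str]
) -> Tuple[np.ndarray, List, Dict[str, List]]:
    """Reshape long-format data to (subjects, l1, ..., lk); error on
    unbalance, duplicates or missing cells."""
    for col in (dv, subject, *within):
        if col not in data.columns:
            raise DesignError(f"column {col!r} not in data")
    subjects = list(pd.unique(data[subject]))
    levels = {f: list(pd.unique(data[f])) for f in within}
    idx = pd.MultiIndex.from_product(
        [subjects] + [levels[f] for f in within], names=[subject, *within]
    )
    try:
        series = data.set_index([subject, *within])[dv]
    except KeyError as exc:  # pragma: no cover
        raise DesignError(str(exc)) from exc
    if series.index.duplicated().any():
        dupes = series.index[series.index.duplicated()].unique().tolist()[:5]
        raise DesignError(f"more than one observation per cell, e.g. {dupes}")
    series = series.reindex(idx)
    if series.isna().any():
        missing = series.index[series.isna()].tolist()[:5]
        raise DesignError(f"missing cells (no imputation is performed): {missing}")
    shape = (len(subjects), *[len(levels[f]) for f in within])
    return series.to_numpy().reshape(shape), subjects, levels


def _stratum_ss(arr: np.ndarray) -> Dict[frozenset, float]:
    """SS for every non-empty subset of axes (axis 0 = subject) via the
    Moebius expansion of marginal means."""
    n_axes = arr.ndim
    axes = tuple(range(n_axes))
    means: Dict[frozenset, np.ndarray] = {}
    for mask in range(2**n_axes):
        keep = frozenset(a for a in axes if mask & (1 << a))
        drop = tuple(a for a in axes if a not in keep)
        means[keep] = arr.mean(axis=drop, keepdims=True) if drop else arr.astype(float)
    ss: Dict[frozenset, float] = {}
    for mask in range(1, 2**n_axes):
        T = frozenset(a for a in axes if mask & (1 << a))
        effect = np.zeros((1,) * n_axes)
        for sub_mask in range(mask + 1):
            if sub_mask & ~mask:
                continue
            U = frozenset(a for a in axes if sub_mask & (1 << a))
            sign = (-1) ** (len(T) - len(U))
            effect = effect + sign * means[U]
        scale = arr.size / effect.size
        ss[T] = float(scale * np.sum(effect**2))
    return ss


def _effect_label(effect_factors: Sequence[str]) -> str:
    return ":".join(effect_factors)


def rm_anova(
    data: pd.DataFrame,
    dv: str = "erd",
    subject: str = "subject",
    within: Sequence[str] = MAIN_MODEL_FACTORS,
    gg: bool = False,
) -> pd.DataFrame:
    """Within-subject factorial ANOVA table for a balanced complete design.

    Returns one row per main effect and interaction with columns
    ``ss_effect, df_effect, ss_error, df_error, ms_effect, ms_error, F, p,
    partial_eta_sq`` (plus ``gg_epsilon`` when requested).  Table attrs carry
    the total SS, the subject-stratum SS and the decomposition residual.

    When an effect's error SS is exactly zero with a non-zero effect SS, F is
    reported as +inf with p = 0 (degenerate but well-defined limit).
    """
    within = list(within)
    if len(within) < 1:
        raise DesignError("need at least one within-subject factor")
    arr, subjects, levels = _pivot(data, dv, subject, within)
    n_subj = len(subjects)
    if n_subj < 2:
        raise DesignError("need at least 2 subjects")
    ss = _stratum_ss(arr)

    rows = []
    factor_axes = {f: i + 1 for i, f in enumerate(within)}
    for k in range(1, len(within) + 1):
        for combo in combinations(within, k):
            T = frozenset(factor_axes[f] for f in combo)
            ss_eff = ss[T]
            ss_err = ss[T | {0}]
            df_eff = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df_err = df_eff * (n_subj - 1)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            if ms_err > 0:
                F = ms_eff / ms_err
                p = float(sps.f.sf(F, df_eff, df_err))
            elif ss_eff > 0:
                F, p = np.inf, 0.0
            else:
                F, p = np.nan, np.nan
            pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            row = {
                "effect": _effect_label(combo),
                "ss_effect": ss_eff,
                "df_effect": df_eff,
                "ss_error": ss_err,
                "df_error": df_err,
                "ms_effect": ms_eff,
                "ms_error": ms_err,
                "F": F,
                "p": p,
                "partial_eta_sq": pes,
            }
            if gg:
                row["gg_epsilon"] = _gg_epsilon(arr, [factor_axes[f] for f in combo], levels, within)
            rows.append(row)

    table = pd.DataFrame(rows).set_index("effect")
    grand = arr.mean()
    ss_total = float(np.sum((arr - grand) ** 2))
    table.attrs["ss_total"] = ss_total
    table.attrs["ss_subject"] = ss[frozenset({0})]
    table.attrs["n_subjects"] = n_subj
    table.attrs["levels"] = {f: list(levels[f]) for f in within}
    table.attrs["decomposition_residual"] = ss_total - sum(ss.values())
    return table


def _helmert(n: int) -> np.ndarray:
    """(n-1) x n orthonormal contrast matrix."""
    m = np.zeros((n - 1, n))
    for i in range(n - 1):
        m[i, : i + 1] = 1.0
        m[i, i + 1] = -(i + 1)
        m[i] /= np.linalg.norm(m[i])
    return m


def _gg_epsilon(
    arr: np.ndarray, effect_axes: Sequence[int], levels: Dict[str, List], within: Sequence[str]
) -> float:
    """Greenhouse-Geisser epsilon of one effect (advisory only)."""
    drop = tuple(a for a in range(1, arr.ndim) if a not in effect_axes)
    marg = arr.mean(axis=drop) if drop else arr  # (n_subj, levels of effect...)
    n_subj = marg.shape[0]
    flat = marg.reshape(n_subj, -1)
    contrast = None
    for a in sorted(effect_axes):
        h = _helmert(arr.shape[a])
        contrast = h if contrast is None else np.kron(contrast, h)
    scores = flat @ contrast.T
    d = scores.shape[1]
    if d == 1:
        return 1.0
    cov = np.cov(scores, rowvar=False)
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0, None)
    denom = d * np.sum(eig**2)
    return float((np.sum(eig) ** 2) / denom) if denom > 0 else 1.0


def eta_sq_from_f(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2).

    Algebraically identical to SS_effect/(SS_effect + SS_error) for any
    single-error-stratum effect, so it reproduces effect sizes from reported
    F values and degrees of freedom alone.
    """
    if F < 0 or df1 < 1 or df2 < 1:
        raise ParameterError("need F >= 0 and dfs >= 1")
    return (F * df1) / (F * df1 + df2)


def fisher_lsd(
    data: pd.DataFrame,
    dv: str = "erd",
    subject: str = "subject",
    within: Sequence[str] = MAIN_MODEL_FACTORS,
    effect: Optional[Sequence[str]] = None,
    error_term: Optional[Sequence[str]] = None,
    anova: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Fisher LSD pairwise comparisons for the cells of one effect.

    Cells are the level combinations of ``effect`` (default: all factors),
    averaged over the remaining factors and compared pairwise with

        SE = sqrt(2 * MS_error / n_obs),  df = df_error,

    where ``n_obs`` is the number of observations each cell mean averages
    (subjects x levels of the factors not in the effect) and the error term
    is the stratum of ``effect`` itself (override with ``error_term`` to use
    another stratum, e.g. the full interaction's).  Two-sided p values, no
    multiplicity adjustment.
    """
    within = list(within)
    effect = list(effect) if effect is not None else list(within)
    unknown = [f for f in effect if f not in within]
    if unknown:
        raise ParameterError(f"effect factors {unknown} not in the design {within}")
    effect = [f for f in within if f in effect]  # canonical factor order
    if error_term is not None:
        error_term = [f for f in within if f in error_term]
    if anova is None:
        anova = rm_anova(data, dv=dv, subject=subject, within=within)
    err_label = _effect_label(error_term if error_term is not None else effect)
    if err_label not in anova.index:
        raise ParameterError(f"error term {err_label!r} is not an effect of the design")
    ms_err = float(anova.loc[err_label, "ms_error"])
    df_err = int(anova.loc[err_label, "df_error"])

    n_subj = int(anova.attrs["n_subjects"])
    levels = anova.attrs["levels"]
    n_obs = n_subj * int(np.prod([len(levels[f]) for f in within if f not in effect]))

    cell_means = data.groupby(effect, sort=False)[dv].mean()
    cells = list(cell_means.index)
    rows = []
    for a, b in combinations(cells, 2):
        diff = float(cell_means.loc[a] - cell_means.loc[b])
        se = np.sqrt(2.0 * ms_err / n_obs)
        if se > 0:
            t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), df_err))
        else:
            t = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        rows.append(
            {
                "cell_a": a if isinstance(a, tuple) else (a,),
                "cell_b": b if isinstance(b, tuple) else (b,),
                "mean_diff": diff,
                "se": se,
                "t": t,
                "df": df_err,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["effect"] = _effect_label(effect)
    out.attrs["error_term"] = err_label
    out.attrs["n_obs_per_cell"] = n_obs
    return out


def erd_table_to_design(
    erd_table: pd.DataFrame, model: str = "main"
) -> pd.DataFrame:
    """Restrict an ERD table to one of the two reported models.

    ``main``: units C3/C4 -> factor ``hemisphere``;
    ``surround``: units surroundC3/surroundC4/Cz -> factor ``electrodes``.
    Factor columns are renamed to the model's factor names
    (condition = task, movement, tdcs = session).
    """
    if model == "main":
        units, factor = ["C3", "C4"], "hemisphere"
    elif model == "surround":
        units, factor = ["surroundC3", "surroundC4", "Cz"], "electrodes"
    else:
        raise ParameterError(f"unknown model {model!r}; expected 'main' or 'surround'")
    sub = erd_table[erd_table["unit"].isin(units)].copy()
    if sub.empty:
        raise DesignError(f"ERD table has no rows for units {units}")
    sub = sub.rename(columns={"task": "condition", "session": "tdcs", "unit": factor})
    return sub[["subject", "condition", "movement", "tdcs", factor, "erd"]]


def format_anova_report(table: pd.DataFrame, title: str = "") -> str:
    """Human-readable summary in the field's reporting style
    (F(df1, df2) = x.xx; p = ...; partial eta^2 rounded); machine outputs keep
    full precision."""
    lines = [title] if title else []
    for effect, r in table.iterrows():
        lines.append(
            f"  {effect}: F({int(r.df_effect)}, {int(r.df_error)}) = {r.F:.2f}; "
            f"p = {r.p:.3g}; eta2p = {r.partial_eta_sq:.2f}"
        )
    return "\n".join(lines)
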