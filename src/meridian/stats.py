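"""Split-plot repeated-measures statistics for the two-group study design.

Implements the mixed ANOVA for one between-subject factor (refractive
group) crossed with one or two within-subject factors (spatial
frequency, grating orientation), including Mauchly's sphericity test,
the Greenhouse-Geisser epsilon and corrected p-values, and partial
eta-squared effect sizes; plus simple-main-effects analyses with
stratum-specific error terms, Holm-Bonferroni (and plain Bonferroni)
p-value adjustment, paired/unpaired t-tests and Pearson correlation.

All sums of squares use the balanced split-plot decomposition from cell
and marginal means (Types I-III coincide for balanced data); unbalanced
or incomplete tables are rejected rather than approximated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "mixed_anova",
    "splitplot_anova_array",
    "mauchly",
    "gg_epsilon",
    "holm",
    "bonferroni",
    "simple_main_effects",
    "paired_t",
    "unpaired_t",
    "unpaired_t_from_stats",
    "pearson",
]

ANOVA_COLUMNS = [
    "effect", "SS", "df", "MS", "F", "p",
    "gg_epsilon", "gg_p", "eta2p",
    "mauchly_W", "mauchly_p",
    "error_SS", "error_df", "p_report",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_raw: float
    method: str
    p_adjusted: Optional[float] = None


# ---------------------------------------------------------------------------
# core split-plot decomposition on a (groups, subjects, A, B) array
# ---------------------------------------------------------------------------

def splitplot_anova_array(y: np.ndarray) -> Dict[str, Tuple[float, int]]:
    """Sums of squares and dfs of the balanced split-plot design.

    ``y`` has shape (g, n, a, b): g groups of n subjects, measured on an
    a x b within-subject grid (use b = 1 for a single within factor).
    Returns ``{term: (SS, df)}`` with terms G, S(G), A, GA, AS(G), and --
    when b > 1 -- B, GB, BS(G), AB, GAB, ABS(G).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 4:
        raise ValueError(f"expected a (g, n, a, b) array, got shape {y.shape}")
    g, n, a, b = y.shape
    if g < 1 or n < 2:
        raise ValueError("need at least one group and two subjects per group")
    m = y.mean()
    out: Dict[str, Tuple[float, int]] = {}

    subj = y.mean(axis=(2, 3))          # (g, n)
    grp = subj.mean(axis=1)             # (g,)
    ss_subj_tot = a * b * ((subj - m) ** 2).sum()
    ss_g = n * a * b * ((grp - m) ** 2).sum()
    out["G"] = (ss_g, g - 1)
    out["S(G)"] = (max(ss_subj_tot - ss_g, 0.0), g * (n - 1))

    ga = y.mean(axis=(1, 3))            # (g, a)
    a_marg = ga.mean(axis=0)            # (a,)
    ss_a = g * n * b * ((a_marg - m) ** 2).sum()
    ss_ga = max(n * b * ((ga - m) ** 2).sum() - ss_g - ss_a, 0.0)
    isa = y.mean(axis=3)                # (g, n, a)
    ss_as = max(
        b * ((isa - m) ** 2).sum() - ss_subj_tot - ss_a - ss_ga, 0.0
    )
    out["A"] = (ss_a, a - 1)
    out["GA"] = (ss_ga, (g - 1) * (a - 1))
    out["AS(G)"] = (ss_as, g * (n - 1) * (a - 1))

    if b > 1:
        gb = y.mean(axis=(1, 2))        # (g, b)
        b_marg = gb.mean(axis=0)
        ss_b = g * n * a * ((b_marg - m) ** 2).sum()
        ss_gb = max(n * a * ((gb - m) ** 2).sum() - ss_g - ss_b, 0.0)
        isb = y.mean(axis=2)            # (g, n, b)
        ss_bs = max(
            a * ((isb - m) ** 2).sum() - ss_subj_tot - ss_b - ss_gb, 0.0
        )
        out["B"] = (ss_b, b - 1)
        out["GB"] = (ss_gb, (g - 1) * (b - 1))
        out["BS(G)"] = (ss_bs, g * (n - 1) * (b - 1))

        gab = y.mean(axis=1)            # (g, a, b)
        ab_marg = gab.mean(axis=0)      # (a, b)
        ss_ab = max(g * n * ((ab_marg - m) ** 2).sum() - ss_a - ss_b, 0.0)
        ss_gab = max(
            n * ((gab - m) ** 2).sum()
            - ss_g - ss_a - ss_b - ss_ga - ss_gb - ss_ab,
            0.0,
        )
        ss_total = ((y - m) ** 2).sum()
        ss_abs = max(ss_total - sum(v[0] for v in out.values()) - ss_ab - ss_gab, 0.0)
        out["AB"] = (ss_ab, (a - 1) * (b - 1))
        out["GAB"] = (ss_gab, (g - 1) * (a - 1) * (b - 1))
        out["ABS(G)"] = (ss_abs, g * (n - 1) * (a - 1) * (b - 1))
    return out


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _sphericity_from_scores(scores: np.ndarray, groups: np.ndarray):
    """Mauchly W, chi2 p, and GG epsilon from per-subject contrast scores.

    ``scores`` is (n_subjects, m) with m orthonormal contrast variables;
    the covariance is pooled within groups (error df = n_subjects -
    n_groups).
    """
    n_subj, m = scores.shape
    if m == 1:
        return 1.0, 1.0, 1.0
    centered = scores.copy()
    labels = np.unique(groups)
    for lab in labels:
        mask = groups == lab
        centered[mask] -= centered[mask].mean(axis=0)
    d = n_subj - len(labels)
    if d <= m:
        warnings.warn(
            f"too few subjects ({n_subj}) for a {m}-dimensional sphericity "
            "test; Mauchly W undefined", stacklevel=3,
        )
        t = centered.T @ centered / max(d, 1)
        eps = _gg_from_contrast_cov(t)
        return math.nan, math.nan, eps
    t = centered.T @ centered / d
    eps = _gg_from_contrast_cov(t)
    det = np.linalg.det(t)
    tr = np.trace(t)
    if det <= 0 or tr <= 0:
        warnings.warn("singular contrast covariance; Mauchly W undefined",
                      stacklevel=3)
        return math.nan, math.nan, eps
    w = det / (tr / m) ** m
    chi2 = -(d - (2 * m * m + m + 2) / (6.0 * m)) * math.log(w)
    df = m * (m + 1) // 2 - 1
    p = float(_sps.chi2.sf(chi2, df))
    return float(w), p, eps


def _gg_from_contrast_cov(t: np.ndarray) -> float:
    m = t.shape[0]
    tr = np.trace(t)
    denom = m * np.trace(t @ t)
    if denom <= 0:
        return 1.0
    return float(min(max(tr * tr / denom, 1.0 / m), 1.0))


def mauchly(data: np.ndarray, groups: Optional[np.ndarray] = None):
    """Mauchly's sphericity test for an (n_subjects, k) within-level matrix.

    Returns ``(W, p)``.  With ``groups`` given, the contrast covariance is
    pooled within groups, as in a mixed design.  k = 2 gives W = 1, p = 1
    (a single contrast is trivially spherical).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an (n_subjects, k>=2) matrix")
    if groups is None:
        groups = np.zeros(data.shape[0])
    scores = data @ _orthonormal_contrasts(data.shape[1]).T
    w, p, _eps = _sphericity_from_scores(scores, np.asarray(groups))
    return w, p


def gg_epsilon(data: np.ndarray, groups: Optional[np.ndarray] = None) -> float:
    """Greenhouse-Geisser epsilon for an (n_subjects, k) within-level matrix."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an (n_subjects, k>=2) matrix")
    if groups is None:
        groups = np.zeros(data.shape[0])
    scores = data @ _orthonormal_contrasts(data.shape[1]).T
    _w, _p, eps = _sphericity_from_scores(scores, np.asarray(groups))
    return eps


# ---------------------------------------------------------------------------
# mixed ANOVA on a long table
# ---------------------------------------------------------------------------

def _table_to_array(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    between: str,
    subject: str,
):
    """Validate completeness/balance and pivot to the (g, n, a, b) array."""
    required = {dv, between, subject, *within}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    if table[dv].isna().any():
        bad = table.loc[table[dv].isna(), subject].iloc[0]
        raise ValueError(
            f"missing {dv!r} value for participant {bad!r}; drop incomplete "
            "participants before the ANOVA"
        )
    levels = [np.unique(table[w]) for w in within]
    cells = int(np.prod([len(l) for l in levels]))
    counts = table.groupby(subject, sort=True).size()
    bad = counts[counts != cells]
    if len(bad):
        raise ValueError(
            f"participant {bad.index[0]!r} has {bad.iloc[0]} rows, expected "
            f"{cells} (one per within-subject cell)"
        )
    dup = table.groupby([subject, *within], sort=True).size()
    if (dup != 1).any():
        key = dup[dup != 1].index[0]
        raise ValueError(f"duplicate or missing cell for {key!r}")
    grp_of = table.groupby(subject, sort=True)[between].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else None
    )
    if grp_of.isna().any():
        raise ValueError("a participant appears in more than one group")
    group_levels = np.unique(grp_of)
    sizes = grp_of.value_counts()
    if sizes.nunique() != 1:
        raise ValueError(
            f"unequal group sizes {dict(sizes)}; the balanced split-plot "
            "decomposition requires equal n per group"
        )
    n = int(sizes.iloc[0])
    g, a = len(group_levels), len(levels[0])
    b = len(levels[1]) if len(within) == 2 else 1
    idx = table.set_index([subject, *within])[dv]
    y = np.empty((g, n, a, b))
    subj_order: List[List[str]] = []
    for gi, glev in enumerate(group_levels):
        subjects = sorted(grp_of.index[grp_of == glev])
        subj_order.append(subjects)
        for si, s in enumerate(subjects):
            for ai, alev in enumerate(levels[0]):
                if b == 1:
                    y[gi, si, ai, 0] = idx.loc[(s, alev)]
                else:
                    for bi, blev in enumerate(levels[1]):
                        y[gi, si, ai, bi] = idx.loc[(s, alev, blev)]
    return y, group_levels, levels, subj_order


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: Sequence[str] = ("sf", "orientation"),
    between: str = "group",
    subject: str = "participant",
    gg_when: str = "mauchly",
) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA on a long-format balanced table.

    One between-subject factor and one or two within-subject factors.
    Every within effect carries its Greenhouse-Geisser epsilon, the
    GG-corrected p, and Mauchly's W/p for its own contrast set; the
    ``p_report`` column applies the GG correction only when Mauchly's
    test rejects sphericity at 0.05 (``gg_when="mauchly"``), always
    (``"always"``), or never (``"never"``).

    Returns one row per effect with the schema in ``ANOVA_COLUMNS``.
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name one or two factors")
    if gg_when not in ("mauchly", "always", "never"):
        raise ValueError("gg_when must be 'mauchly', 'always' or 'never'")
    y, group_levels, levels, _ = _table_to_array(table, dv, within, between, subject)
    g, n, a, b = y.shape
    terms = splitplot_anova_array(y)

    a_name = within[0]
    b_name = within[1] if len(within) == 2 else None
    label = {
        "G": between, "A": a_name, "GA": f"{between} × {a_name}",
        "B": b_name, "GB": f"{between} × {b_name}" if b_name else None,
        "AB": f"{a_name} × {b_name}" if b_name else None,
        "GAB": f"{between} × {a_name} × {b_name}" if b_name else None,
    }
    error_of = {
        "G": "S(G)", "A": "AS(G)", "GA": "AS(G)",
        "B": "BS(G)", "GB": "BS(G)", "AB": "ABS(G)", "GAB": "ABS(G)",
    }

    # Sphericity quantities per within contrast set, from subject scores.
    groups_vec = np.repeat(np.arange(g), n)
    flat = y.reshape(g * n, a, b)
    sphericity: Dict[str, Tuple[float, float, float]] = {}
    ca = _orthonormal_contrasts(a)
    scores_a = flat.mean(axis=2) @ ca.T
    sphericity["A"] = _sphericity_from_scores(scores_a, groups_vec)
    if b > 1:
        cb = _orthonormal_contrasts(b)
        scores_b = flat.mean(axis=1) @ cb.T
        sphericity["B"] = _sphericity_from_scores(scores_b, groups_vec)
        cab = np.kron(ca, cb)
        scores_ab = flat.reshape(g * n, a * b) @ cab.T
        sphericity["AB"] = _sphericity_from_scores(scores_ab, groups_vec)
    within_effect_of = {"A": "A", "GA": "A", "B": "B", "GB": "B",
                        "AB": "AB", "GAB": "AB"}

    rows = []
    order = ["G", "A", "B", "GA", "GB", "AB", "GAB"]
    for key in order:
        if key not in terms:
            continue
        ss, df = terms[key]
        err_ss, err_df = terms[error_of[key]]
        ms = ss / df if df > 0 else math.nan
        ms_err = err_ss / err_df if err_df > 0 else math.nan
        if ms_err and ms_err > 0 and not math.isnan(ms_err):
            f_val = ms / ms_err
            p = float(_sps.f.sf(f_val, df, err_df))
        else:
            f_val, p = math.nan, math.nan
        eta = ss / (ss + err_ss) if (ss + err_ss) > 0 else 0.0
        w_val = p_w = eps = gg_p = math.nan
        p_report = p
        if key in within_effect_of:
            w_val, p_w, eps = sphericity[within_effect_of[key]]
            if not math.isnan(f_val):
                gg_p = float(_sps.f.sf(f_val, df * eps, err_df * eps))
            if gg_when == "always" or (
                gg_when == "mauchly"
                and not math.isnan(p_w) and p_w < 0.05
            ):
                p_report = gg_p
        rows.append({
            "effect": label[key], "SS": ss, "df": df, "MS": ms,
            "F": f_val, "p": p, "gg_epsilon": eps, "gg_p": gg_p,
            "eta2p": eta, "mauchly_W": w_val, "mauchly_p": p_w,
            "error_SS": err_ss, "error_df": err_df, "p_report": p_report,
        })
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------

def holm(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, returned in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted_sorted = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(adjusted_sorted), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * len(p), 1.0)


# ---------------------------------------------------------------------------
# simple main effects
# ---------------------------------------------------------------------------

def _oneway_rm(y: np.ndarray):
    """One-way repeated-measures F for an (n, k) matrix, own error term."""
    n, k = y.shape
    m = y.mean()
    col = y.mean(axis=0)
    row = y.mean(axis=1)
    ss_f = n * ((col - m) ** 2).sum()
    ss_s = k * ((row - m) ** 2).sum()
    ss_t = ((y - m) ** 2).sum()
    ss_e = max(ss_t - ss_f - ss_s, 0.0)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_e = ss_e / df2 if df2 > 0 else math.nan
    if ms_e and ms_e > 0 and not math.isnan(ms_e):
        f_val = (ss_f / df1) / ms_e
        p = float(_sps.f.sf(f_val, df1, df2))
    elif ss_f == 0:
        f_val, p = 0.0, 1.0
    else:
        f_val, p = math.nan, math.nan
    eta = ss_f / (ss_f + ss_e) if (ss_f + ss_e) > 0 else 0.0
    return f_val, df1, df2, p, eta


def _oneway_between(values: List[np.ndarray]):
    """One-way between-subjects F across the per-level value vectors."""
    k = len(values)
    ns = [len(v) for v in values]
    allv = np.concatenate(values)
    m = allv.mean()
    ss_f = sum(n * (v.mean() - m) ** 2 for n, v in zip(ns, values))
    ss_e = sum(((v - v.mean()) ** 2).sum() for v in values)
    df1, df2 = k - 1, len(allv) - k
    ms_e = ss_e / df2 if df2 > 0 else math.nan
    if ms_e and ms_e > 0 and not math.isnan(ms_e):
        f_val = (ss_f / df1) / ms_e
        p = float(_sps.f.sf(f_val, df1, df2))
    elif ss_f == 0:
        f_val, p = 0.0, 1.0
    else:
        f_val, p = math.nan, math.nan
    eta = ss_f / (ss_f + ss_e) if (ss_f + ss_e) > 0 else 0.0
    return f_val, df1, df2, p, eta


def simple_main_effects(
    table: pd.DataFrame,
    stratify_by: Sequence[str],
    test_factor: str,
    dv: str = "value",
    subject: str = "participant",
    adjust: str = "holm",
) -> pd.DataFrame:
    """Effect of ``test_factor`` inside each stratum, own error term per stratum.

    If ``test_factor`` varies within subjects the stratum test is a
    one-way repeated-measures F; if subjects are nested in its levels it
    is a one-way between-subjects F.  Raw p-values over the family of
    strata are adjusted by Holm (default) or plain Bonferroni.
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise ValueError("adjust must be 'holm', 'bonferroni' or 'none'")
    stratify_by = list(stratify_by)
    rows = []
    for key, sub in table.groupby(stratify_by, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        sub = sub.dropna(subset=[dv])
        if sub.empty:
            warnings.warn(f"empty stratum {key!r}; skipped", stacklevel=2)
            continue
        per_subj = sub.groupby(subject)[test_factor].nunique()
        repeated = per_subj.max() > 1
        if repeated:
            wide = sub.pivot_table(
                index=subject, columns=test_factor, values=dv, aggfunc="first"
            ).dropna()
            f_val, df1, df2, p, eta = _oneway_rm(wide.to_numpy())
            n_used = len(wide)
        else:
            groups = [
                grp[dv].to_numpy() for _, grp in sub.groupby(test_factor, sort=True)
            ]
            f_val, df1, df2, p, eta = _oneway_between(groups)
            n_used = sum(len(v) for v in groups)
        rows.append(dict(zip(stratify_by, key), F=f_val, df1=df1, df2=df2,
                         p=p, eta2p=eta, n=n_used))
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if adjust == "none":
        out["p_adjusted"] = out["p"]
    else:
        fn = holm if adjust == "holm" else bonferroni
        out["p_adjusted"] = fn(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test; identical vectors give t = 0, p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with >= 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return TestResult(0.0, len(d) - 1, 1.0, "paired t")
        return TestResult(math.nan, len(d) - 1, math.nan, "paired t")
    t, p = _sps.ttest_rel(x, y)
    return TestResult(float(t), len(d) - 1, float(p), "paired t")


def unpaired_t(x, y, equal_var: bool = True) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, len(x) + len(y) - 2, 1.0, "unpaired t")
        return TestResult(math.nan, len(x) + len(y) - 2, math.nan, "unpaired t")
    res = _sps.ttest_ind(x, y, equal_var=equal_var)
    df = len(x) + len(y) - 2 if equal_var else float(res.df)
    return TestResult(float(res.statistic), df, float(res.pvalue), "unpaired t")


def unpaired_t_from_stats(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> TestResult:
    """Unpaired t-test from summary moments (means, SDs, group sizes)."""
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    t, p = _sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df: float = n1 + n2 - 2
    else:
        v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
        df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    return TestResult(float(t), df, float(p), "unpaired t (summary)")


def pearson(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 pairs")
    if x.std() == 0 or y.std() == 0:
        return TestResult(math.nan, len(x) - 2, math.nan, "pearson")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = _sps.pearsonr(x, y)
    return TestResult(float(r), len(x) - 2, float(p), "pearson")
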