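"""The statistical battery for the study design.

Paired t for the MEP pre/post comparison; Wilcoxon signed-rank (exact by full
sign-pattern enumeration for n <= 12, continuity-corrected normal
approximation otherwise) for baseline small-vs-large contrasts; a 2 (TMS
condition: real, sham) x 2 (time: pre, post) fully within-subject ANOVA for
each kinematic measure; and a normality-gated Pearson/Spearman correlation
between excitability change and coordination change.

With two-level factors sphericity holds trivially (epsilon = 1); the report
notes this instead of running a vacuous Mauchly test.  Alpha is 0.05
two-sided throughout, with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MissingCellError, ParameterError


@dataclass
class StatReport:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_direction: int  # sign of the effect (mean difference / correlation)
    n: int
    notes: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value must lie in [0, 1], got {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "effect_direction": self.effect_direction,
            "n": self.n,
            "notes": self.notes,
        }
        d.update(self.extra)
        return d


# --------------------------------------------------------------------------
# paired t
# --------------------------------------------------------------------------

def paired_t(pre: np.ndarray, post: np.ndarray) -> StatReport:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ParameterError("paired samples must be matched 1-d arrays of equal length")
    n = pre.shape[0]
    if n < 2:
        raise ParameterError("paired t-test needs at least 2 pairs")
    d = pre - post
    if np.std(d, ddof=1) == 0.0:
        raise ParameterError("differences have zero variance; t is undefined")
    t, p = sps.ttest_rel(pre, post)
    return StatReport(
        test_name="paired_t",
        statistic=float(t),
        df=float(n - 1),
        p_value=float(p),
        effect_direction=int(np.sign(d.mean())),
        n=n,
    )


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all 2^m sign assignments.

    The null distribution of W+ is symmetric about m(m+1)/4 even with
    midranks, so the two-sided p is the mass at or beyond the observed tails.
    """
    m = ranks.shape[0]
    patterns = np.arange(2**m, dtype=np.uint32)
    signs = (patterns[:, None] >> np.arange(m)) & 1  # (2^m, m) in {0, 1}
    w_all = signs @ ranks
    total = ranks.sum()
    w_minus = total - w_plus
    lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
    p = (np.sum(w_all <= lo + 1e-9) + np.sum(w_all >= hi - 1e-9)) / 2.0**m
    return float(min(1.0, p))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray, exact_max_n: int = 12) -> StatReport:
    """Wilcoxon signed-rank test on matched pairs.

    Zero differences are discarded.  For n <= ``exact_max_n`` the two-sided p
    comes from full enumeration of sign patterns (handles midranks exactly);
    the continuity-corrected, tie-corrected z approximation is always reported
    as the statistic, matching z-style reporting conventions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("matched samples must be 1-d arrays of equal length")
    d = x - y
    d = d[d != 0.0]
    m = d.shape[0]
    if m == 0:
        raise ParameterError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if sigma2 <= 0:
        raise ParameterError("degenerate rank variance (all differences tied)")
    correction = 0.5 * np.sign(w_plus - mu)
    z = (w_plus - mu - correction) / np.sqrt(sigma2)
    if m <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact enumeration"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal approximation (continuity corrected)"
    return StatReport(
        test_name="wilcoxon_signed_rank",
        statistic=float(z),
        df=float(m - 1),
        p_value=p,
        effect_direction=int(np.sign(np.median(d))) if np.median(d) != 0 else 0,
        n=m,
        notes=method,
        extra={"w_plus": w_plus},
    )


# --------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA
# --------------------------------------------------------------------------

def _f_report(name, ss_effect, ss_error, df1, df2, direction, n, notes=""):
    ms_error = ss_error / df2
    if ms_error <= 1e-300:
        if ss_effect <= 1e-300:
            f, p = 0.0, 1.0
        else:
            f, p = float("inf"), 0.0
    else:
        f = (ss_effect / df1) / ms_error
        p = float(sps.f.sf(f, df1, df2))
    return StatReport(
        test_name=name,
        statistic=float(f),
        df=(float(df1), float(df2)),
        p_value=p,
        effect_direction=direction,
        n=n,
        notes=notes,
    )


def rm_anova_2x2(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    factor_a: str = "condition",
    factor_b: str = "time",
) -> dict[str, StatReport]:
    """Classical fully within-subject 2x2 ANOVA on a long-format table.

    Expects one value per subject x factor cell (trials already averaged).
    Returns reports for both main effects and the interaction, each tested
    against its own subject-by-factor error term with df (1, n - 1).
    Missing or duplicated cells raise with an explicit listing.
    """
    for col in (dv, subject, factor_a, factor_b):
        if col not in table.columns:
            raise ParameterError(f"column '{col}' missing from the input table")
    piv = table.pivot_table(
        index=subject, columns=[factor_a, factor_b], values=dv, aggfunc="count"
    )
    counts = piv.reindex(columns=pd.MultiIndex.from_product(
        [sorted(table[factor_a].unique()), sorted(table[factor_b].unique())]
    ))
    bad = []
    for subj in counts.index:
        for col in counts.columns:
            c = counts.loc[subj, col]
            if pd.isna(c) or c != 1:
                bad.append(f"{subj}/{col[0]}/{col[1]} (count={0 if pd.isna(c) else int(c)})")
    if bad:
        raise MissingCellError(
            "design must have exactly one value per subject x cell; offending cells: "
            + ", ".join(bad)
        )
    a_levels = sorted(table[factor_a].unique())
    b_levels = sorted(table[factor_b].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ParameterError("both factors must have exactly 2 levels")
    values = table.pivot_table(index=subject, columns=[factor_a, factor_b], values=dv)
    subjects = values.index
    n = len(subjects)
    if n < 2:
        raise ParameterError("need at least 2 subjects")
    y = np.empty((n, 2, 2))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            y[:, i, j] = values[(a, b)].to_numpy()

    g = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_a = 2 * n * np.sum((m_a - g) ** 2)
    ss_b = 2 * n * np.sum((m_b - g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_as = 2 * np.sum((m_as - m_s[:, None] - m_a[None, :] + g) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_s[:, None] - m_b[None, :] + g) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - g
    )
    ss_abs = np.sum(resid**2)

    df_err = n - 1
    note = "2-level within factors: sphericity holds trivially (epsilon = 1)"
    inter_dir = int(np.sign((m_ab[1, 1] - m_ab[1, 0]) - (m_ab[0, 1] - m_ab[0, 0])))
    reports = {
        factor_a: _f_report(
            f"rm_anova:{factor_a}", ss_a, ss_as, 1, df_err,
            int(np.sign(m_a[1] - m_a[0])), n, note,
        ),
        factor_b: _f_report(
            f"rm_anova:{factor_b}", ss_b, ss_bs, 1, df_err,
            int(np.sign(m_b[1] - m_b[0])), n, note,
        ),
        "interaction": _f_report(
            f"rm_anova:{factor_a}x{factor_b}", ss_ab, ss_abs, 1, df_err,
            inter_dir, n, note,
        ),
    }
    return reports


# --------------------------------------------------------------------------
# exploratory correlation
# --------------------------------------------------------------------------

def excitability_behavior_correlation(delta_mep: np.ndarray, delta_z_r: np.ndarray) -> StatReport:
    """Correlation of excitability change with coordination change.

    Shapiro-Wilk normality checks on both variables (alpha 0.05) select
    Pearson (both normal) or Spearman (otherwise).
    """
    dx = np.asarray(delta_mep, dtype=float)
    dy = np.asarray(delta_z_r, dtype=float)
    if dx.shape != dy.shape or dx.ndim != 1:
        raise ParameterError("inputs must be matched 1-d arrays")
    n = dx.shape[0]
    if n < 4:
        raise ParameterError("need at least 4 paired observations")
    if np.ptp(dx) == 0.0 or np.ptp(dy) == 0.0:
        raise ParameterError("constant input; correlation undefined")
    normal = sps.shapiro(dx).pvalue > 0.05 and sps.shapiro(dy).pvalue > 0.05
    if normal:
        r, p = sps.pearsonr(dx, dy)
        method = "pearson"
    else:
        r, p = sps.spearmanr(dx, dy)
        method = "spearman"
    return StatReport(
        test_name=f"correlation:{method}",
        statistic=float(r),
        df=float(n - 2),
        p_value=float(p),
        effect_direction=int(np.sign(r)),
        n=n,
        notes=f"{method} selected by Shapiro-Wilk normality gate at alpha=0.05",
    )
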