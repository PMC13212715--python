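"""Repeated-measures statistics: rmcorr, within-subject ANOVA with
sphericity handling, Holm-Sidak step-down comparisons, and paired-design
power.

The repeated-measures correlation is the common within-subject linear
association estimated by ANCOVA with subject as a categorical factor and
a common slope; its error degrees of freedom are
``N_observations - n_subjects - 1``.

"Mixed-effects" repeated-measures analyses are implemented as
complete-case within-subject ANOVA: subjects with missing cells are
dropped per analysis with a logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "RmCorrResult",
    "RmAnovaResult",
    "PairwiseComparison",
    "PowerResult",
    "rmcorr",
    "rm_anova",
    "holm_sidak",
    "pairwise_comparisons",
    "paired_power",
    "min_sample_size",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# repeated-measures correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmCorrResult:
    r_rm: float
    df: int
    p: float
    ci95: tuple[float, float]
    slope: float
    n_subjects: int
    n_observations: int
    ci_method: str = "fisher-z, se=1/sqrt(df-1)"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_rm <= 1.0:
            raise ValueError("r_rm outside [-1, 1]")
        if self.df != self.n_observations - self.n_subjects - 1:
            raise ValueError("df must equal N_observations - n_subjects - 1")


def rmcorr(data: pd.DataFrame, x: str, y: str, subject: str) -> RmCorrResult:
    """Repeated-measures correlation via subject-factor ANCOVA.

    r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_error)) where SS_x is
    the sum of squares removed from the subject-only model by adding the
    common slope; p comes from F(1, df) with df = N - n_subjects - 1;
    the CI uses a Fisher z transform with SE = 1/sqrt(df - 1).
    """
    df_ = data[[subject, x, y]].dropna()
    if not np.all(np.isfinite(df_[[x, y]].to_numpy(dtype=float))):
        raise ValueError("x and y must be finite")
    counts = df_.groupby(subject).size()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"subjects with < 2 observations: {sorted(map(str, thin.index))}"
        )
    if len(counts) < 2:
        raise ValueError("rmcorr needs >= 2 subjects")

    subjects = df_[subject].to_numpy()
    xs = df_[x].to_numpy(dtype=float)
    ys = df_[y].to_numpy(dtype=float)
    n_obs = xs.size
    n_sub = len(counts)

    # Within-subject centering is equivalent to projecting out the
    # subject dummies for both the reduced and full models.
    xw = xs - pd.Series(xs).groupby(subjects).transform("mean").to_numpy()
    yw = ys - pd.Series(ys).groupby(subjects).transform("mean").to_numpy()
    sxx = float(xw @ xw)
    if sxx <= 0:
        raise ValueError("x has no within-subject variance")
    slope = float(xw @ yw) / sxx
    ss_effect = slope * slope * sxx
    resid = yw - slope * xw
    ss_error = float(resid @ resid)

    dof = n_obs - n_sub - 1
    if dof < 1:
        raise ValueError("not enough observations: df < 1")
    total = ss_effect + ss_error
    r = 0.0 if total == 0 else np.sign(slope) * np.sqrt(ss_effect / total)
    r = float(np.clip(r, -1.0, 1.0))
    if ss_error == 0:
        p = 0.0
    else:
        f_stat = ss_effect / (ss_error / dof)
        p = float(sst.f.sf(f_stat, 1, dof))
    if dof > 1 and abs(r) < 1:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(dof - 1)
        zc = sst.norm.ppf(0.975)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    else:
        lo, hi = r, r
    return RmCorrResult(
        r_rm=r,
        df=dof,
        p=p,
        ci95=(float(lo), float(hi)),
        slope=slope,
        n_subjects=n_sub,
        n_observations=n_obs,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmAnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon_gg: float
    mauchly_p: float
    p: float
    p_uncorrected: float
    corrected: bool
    ss_effect: float
    ss_error: float
    n_subjects: int


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (Helmert basis, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _mauchly_gg(transformed: np.ndarray) -> tuple[float, float]:
    """Mauchly's p and Greenhouse-Geisser epsilon from contrast scores.

    ``transformed``: n_subjects x d matrix of contrast scores for one
    effect. d == 1 (two levels) is trivially spherical.
    """
    n, d = transformed.shape
    if d < 2:
        return 1.0, 1.0
    s = np.cov(transformed, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    tr = float(eig.sum())
    if tr <= 0:
        return 1.0, 1.0
    eps = tr * tr / (d * float((eig * eig).sum()))
    eps = float(min(max(eps, 1.0 / d), 1.0))
    f_err = n - 1
    if f_err <= d or np.any(eig <= 1e-12 * tr):
        # covariance singular at this sample size; test unavailable
        return float("nan"), eps
    w = float(np.prod(eig) / (tr / d) ** d)
    w = min(max(w, 1e-300), 1.0)
    # Box's chi-square approximation with the second-order term
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * f_err)
    chi2 = -f_err * f * np.log(w)
    df_chi = d * (d + 1) / 2.0 - 1.0
    k = d + 1
    w2 = (
        (d + 2.0) * (d - 1.0) * (d - 2.0)
        * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
        / (288.0 * (f_err * d * f) ** 2)
    )
    p1 = sst.chi2.sf(chi2, df_chi)
    p2 = sst.chi2.sf(chi2, df_chi + 4)
    p = float(p1 + w2 * (p2 - p1))
    return p, eps


def _complete_case(data: pd.DataFrame, dv: str, within: list[str], subject: str) -> pd.DataFrame:
    df_ = data[[subject, dv, *within]].dropna()
    # average duplicated cells
    df_ = df_.groupby([subject, *within], as_index=False, observed=True)[dv].mean()
    levels = [sorted(df_[w].unique()) for w in within]
    n_cells = int(np.prod([len(lv) for lv in levels]))
    counts = df_.groupby(subject, observed=True).size()
    complete = counts[counts == n_cells].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.warning(
            "rm_anova: dropping %d subject(s) with incomplete cells: %s",
            len(dropped), dropped,
        )
    out = df_[df_[subject].isin(complete)]
    if out[subject].nunique() < 3:
        raise ValueError("rm_anova needs >= 3 subjects after complete-case filtering")
    return out


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str,
    alpha: float = DEFAULT_ALPHA,
) -> list[RmAnovaResult]:
    """One- or two-way within-subject ANOVA with Mauchly/Greenhouse-Geisser.

    Returns one :class:`RmAnovaResult` per main effect (plus the
    interaction for two factors). The Greenhouse-Geisser correction is
    applied to an effect's degrees of freedom when Mauchly's test on
    that effect's contrast covariance rejects at ``alpha``.
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    df_ = _complete_case(data, dv, within, subject)
    levels = [sorted(df_[w].unique()) for w in within]
    if any(len(lv) < 2 for lv in levels):
        raise ValueError("every factor needs >= 2 levels")
    subjects = sorted(df_[subject].unique())
    n = len(subjects)

    if len(within) == 1:
        wide = df_.pivot(index=subject, columns=within[0], values=dv).loc[subjects, levels[0]]
        y = wide.to_numpy(dtype=float)  # n x a
        return [_within_effect(within[0], y[:, :, None], axis_levels=(y.shape[1], 1), alpha=alpha)]

    a, b = len(levels[0]), len(levels[1])
    cube = np.empty((n, a, b))
    piv = df_.set_index([subject, *within])[dv]
    for i, s in enumerate(subjects):
        for j, la in enumerate(levels[0]):
            for k, lb in enumerate(levels[1]):
                cube[i, j, k] = piv.loc[(s, la, lb)]
    results = [
        _within_effect(within[0], cube, axis_levels=(a, b), alpha=alpha),
        _within_effect(within[1], np.transpose(cube, (0, 2, 1)), axis_levels=(b, a), alpha=alpha),
        _interaction_effect(f"{within[0]}*{within[1]}", cube, alpha=alpha),
    ]
    return results


def _effect_result(
    name: str,
    ss_eff: float,
    ss_err: float,
    df_num: float,
    df_den: float,
    scores: np.ndarray,
    n: int,
    alpha: float,
) -> RmAnovaResult:
    ms_eff = ss_eff / df_num
    ms_err = ss_err / df_den if df_den > 0 else np.nan
    f_stat = float(ms_eff / ms_err) if ms_err > 0 else 0.0
    mauchly_p, eps = _mauchly_gg(scores)
    p_unc = float(sst.f.sf(f_stat, df_num, df_den)) if f_stat > 0 else 1.0
    corrected = bool(np.isfinite(mauchly_p) and mauchly_p < alpha)
    if corrected:
        p = float(sst.f.sf(f_stat, eps * df_num, eps * df_den)) if f_stat > 0 else 1.0
        out_num, out_den = eps * df_num, eps * df_den
    else:
        p, out_num, out_den = p_unc, float(df_num), float(df_den)
    return RmAnovaResult(
        effect=name,
        F=f_stat,
        df_num=out_num,
        df_den=out_den,
        epsilon_gg=eps,
        mauchly_p=mauchly_p,
        p=p,
        p_uncorrected=p_unc,
        corrected=corrected,
        ss_effect=float(ss_eff),
        ss_error=float(ss_err),
        n_subjects=n,
    )


def _within_effect(name: str, cube: np.ndarray, axis_levels, alpha: float) -> RmAnovaResult:
    """Main effect of the factor on axis 1 of ``cube`` (n x a x b)."""
    n, a, b = cube.shape
    grand = cube.mean()
    m_a = cube.mean(axis=(0, 2))
    m_s = cube.mean(axis=(1, 2))
    m_sa = cube.mean(axis=2)
    ss_a = n * b * float(((m_a - grand) ** 2).sum())
    ss_sa = b * float(((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    df_num = a - 1
    df_den = (n - 1) * (a - 1)
    scores = m_sa @ _orthonormal_contrasts(a).T  # n x (a-1)
    return _effect_result(name, ss_a, ss_sa, df_num, df_den, scores, n, alpha)


def _interaction_effect(name: str, cube: np.ndarray, alpha: float) -> RmAnovaResult:
    n, a, b = cube.shape
    grand = cube.mean()
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)
    resid_ab = m_ab - m_a[:, None] - m_b[None, :] + grand
    ss_ab = n * float((resid_ab ** 2).sum())
    # subject x A x B residual
    m_s = cube.mean(axis=(1, 2))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    resid = (
        cube
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = float((resid ** 2).sum())
    df_num = (a - 1) * (b - 1)
    df_den = (n - 1) * (a - 1) * (b - 1)
    c_ab = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
    scores = cube.reshape(n, a * b) @ c_ab.T
    return _effect_result(name, ss_ab, ss_sab, df_num, df_den, scores, n, alpha)


# ---------------------------------------------------------------------------
# Holm-Sidak
# ---------------------------------------------------------------------------

def holm_sidak(p_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down adjustment.

    Sorted ascending, adjusted p_(i) = 1 - (1 - p_(i))^(m - i + 1)
    (1-based rank i), then made monotone non-decreasing. Returns
    ``(adjusted, significant_at_05)`` in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty_like(adj_sorted)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < DEFAULT_ALPHA


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: object
    level_b: object
    mean_diff: float
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool
    variance: str  # pooled | individual


def pairwise_comparisons(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    pooled: Optional[bool] = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[PairwiseComparison]:
    """All pairwise condition comparisons with Holm-Sidak adjustment.

    ``pooled=None`` decides from Mauchly's test on the within-factor
    (pooled error variance when sphericity holds, per-pair paired-t
    variances otherwise), mirroring the post-hoc policy of the analysis.
    """
    df_ = _complete_case(data, dv, [within], subject)
    levels = sorted(df_[within].unique())
    subjects = sorted(df_[subject].unique())
    wide = df_.pivot(index=subject, columns=within, values=dv).loc[subjects, levels]
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    if pooled is None:
        scores = (y - y.mean(axis=1, keepdims=True)) @ _orthonormal_contrasts(k).T
        mauchly_p, _ = _mauchly_gg(scores)
        pooled = not (np.isfinite(mauchly_p) and mauchly_p < alpha)
    res = rm_anova(df_, dv=dv, within=[within], subject=subject, alpha=alpha)[0]
    ms_err = res.ss_error / ((n - 1) * (k - 1))
    rows = []
    for i, j in combinations(range(k), 2):
        diff = y[:, i] - y[:, j]
        md = float(diff.mean())
        if pooled:
            se = np.sqrt(2.0 * ms_err / n)
            dof = (n - 1) * (k - 1)
        else:
            se = diff.std(ddof=1) / np.sqrt(n)
            dof = n - 1
        t_stat = md / se if se > 0 else 0.0
        p_raw = float(2.0 * sst.t.sf(abs(t_stat), dof)) if se > 0 else 1.0
        rows.append((levels[i], levels[j], md, t_stat, dof, p_raw))
    adjusted, _sig = holm_sidak([r[5] for r in rows])
    return [
        PairwiseComparison(
            level_a=a_, level_b=b_, mean_diff=md, t=t_, df=dof, p_raw=p_raw,
            p_adjusted=float(p_adj), significant=bool(p_adj < alpha),
            variance="pooled" if pooled else "individual",
        )
        for (a_, b_, md, t_, dof, p_raw), p_adj in zip(rows, adjusted)
    ]


# ---------------------------------------------------------------------------
# paired-design power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    dz: float
    alpha: float
    n: int
    power: float


def paired_power(dz: float, n: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Power of a two-tailed paired t test via the noncentral t
    distribution with ncp = dz * sqrt(n), df = n - 1."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    if dz < 0:
        raise ValueError("dz must be >= 0")
    df_ = n - 1
    ncp = dz * np.sqrt(n)
    t_crit = sst.t.ppf(1.0 - alpha / 2.0, df_)
    return float(sst.nct.sf(t_crit, df_, ncp) + sst.nct.cdf(-t_crit, df_, ncp))


def min_sample_size(
    dz: float, power_target: float, alpha: float = DEFAULT_ALPHA, n_max: int = 10_000
) -> int:
    """Smallest n with ``paired_power(dz, n, alpha) >= power_target``."""
    if not (0 < power_target < 1):
        raise ValueError("power_target must lie in (0, 1)")
    if dz <= 0:
        raise ValueError("power target unreachable for dz <= 0")
    for n in range(2, n_max + 1):
        if paired_power(dz, n, alpha) >= power_target:
            return n
    raise ValueError(f"power target {power_target} not reached by n = {n_max}")
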