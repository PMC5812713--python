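"""Statistical layer: within-subject ANOVA, Friedman test, permutation
correlations, correlation power analysis, and median splits.

Conventions follow the analysis style of small within-subject vision
studies: subjects are a random effect, each within-subject effect is
tested against its own subject-by-effect interaction, correlation
significance is confirmed by shuffling one variable across subjects
(10,000 permutations, p = proportion of |r_perm| strictly greater than
|r_obs|), and the minimum correlation detectable at 80% power follows
the Fisher z approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["AnovaResult", "rm_anova", "rm_anova_linear_trend",
           "friedman_test", "permutation_correlation", "min_detectable_r",
           "median_split", "anova_or_friedman", "listwise_complete"]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float


def listwise_complete(table: pd.DataFrame, subject: str, cells: list[str],
                      dv: str) -> pd.DataFrame:
    """Drop subjects with any missing cell (logged), for a crossed design."""
    wide = table.pivot_table(index=subject, columns=cells, values=dv,
                             aggfunc="mean")
    bad = wide.index[wide.isna().any(axis=1)]
    if len(bad):
        logger.info("excluding %d subject(s) with incomplete cells: %s",
                    len(bad), list(bad))
    keep = table[~table[subject].isin(bad)]
    return keep


def _cell_means(table: pd.DataFrame, subject: str, factors: list[str],
                dv: str) -> pd.DataFrame:
    """Collapse replicates to one value per subject x cell."""
    return (table.groupby([subject] + factors, as_index=False)[dv].mean())


def _f_ratio(ss_eff: float, df_eff: int, ss_err: float, df_err: int,
             name: str) -> AnovaResult:
    if ss_err <= 1e-300 * max(1.0, ss_eff):
        # degenerate error term: define F = 0 when the effect is also null
        F = 0.0 if ss_eff <= 1e-300 else float("inf")
    else:
        F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
    return AnovaResult(effect=name, F=float(F), df1=df_eff, df2=df_err, p=p)


def rm_anova(table: pd.DataFrame, dv: str, within, subject: str = "subject"
             ) -> list[AnovaResult]:
    """Repeated-measures ANOVA with one or two within-subject factors.

    Standard within-subject sums-of-squares decomposition on subject x
    cell means; each effect is tested against its interaction with
    subjects.  Requires a complete crossed design (use
    ``listwise_complete`` first).  A constant dv yields F = 0.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within factors")
    data = _cell_means(table, subject, within, dv)
    subjects = data[subject].unique()
    levels = [np.sort(data[f].unique()) for f in within]
    n = len(subjects)
    if n < 2 or any(len(lv) < 2 for lv in levels):
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    shape = (n,) + tuple(len(lv) for lv in levels)
    # strict crossing check + cube construction
    cube = np.full(shape, np.nan)
    sidx = {s: i for i, s in enumerate(subjects)}
    lidx = [{v: i for i, v in enumerate(lv)} for lv in levels]
    for _, row in data.iterrows():
        pos = (sidx[row[subject]],) + tuple(lidx[k][row[f]]
                                            for k, f in enumerate(within))
        cube[pos] = row[dv]
    if np.isnan(cube).any():
        raise ValueError("design is not fully crossed after averaging; "
                         "apply listwise exclusion first")

    gm = cube.mean()
    results: list[AnovaResult] = []
    if len(within) == 1:
        k = shape[1]
        m_j = cube.mean(axis=0)
        m_i = cube.mean(axis=1)
        ss_a = n * np.sum((m_j - gm) ** 2)
        ss_s = k * np.sum((m_i - gm) ** 2)
        ss_tot = np.sum((cube - gm) ** 2)
        ss_err = ss_tot - ss_a - ss_s
        results.append(_f_ratio(ss_a, k - 1, ss_err, (n - 1) * (k - 1), within[0]))
    else:
        a, b = shape[1], shape[2]
        m_s = cube.mean(axis=(1, 2))            # subject means
        m_a = cube.mean(axis=(0, 2))            # factor-A level means
        m_b = cube.mean(axis=(0, 1))
        m_ab = cube.mean(axis=0)                # (a, b)
        m_sa = cube.mean(axis=2)                # (n, a)
        m_sb = cube.mean(axis=1)                # (n, b)
        ss_a = n * b * np.sum((m_a - gm) ** 2)
        ss_b = n * a * np.sum((m_b - gm) ** 2)
        ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
        ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
        ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
        ss_tot = np.sum((cube - gm) ** 2)
        ss_s = a * b * np.sum((m_s - gm) ** 2)
        ss_sab = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_sa - ss_sb
        results.append(_f_ratio(ss_a, a - 1, ss_sa, (n - 1) * (a - 1), within[0]))
        results.append(_f_ratio(ss_b, b - 1, ss_sb, (n - 1) * (b - 1), within[1]))
        results.append(_f_ratio(ss_ab, (a - 1) * (b - 1), ss_sab,
                                (n - 1) * (a - 1) * (b - 1),
                                f"{within[0]}*{within[1]}"))
    return results


def rm_anova_linear_trend(table: pd.DataFrame, dv: str, factor: str,
                          subject: str = "subject") -> AnovaResult:
    """Linear-trend F treating the factor as a continuous predictor.

    Applies centered linear contrast weights (the factor's numeric
    values) to each subject's cell means and tests the contrast scores
    against zero; F = t^2 with df (1, n-1).  For a 2-level factor this
    is the squared paired t test.
    """
    data = _cell_means(table, subject, [factor], dv)
    levels = np.sort(data[factor].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 levels")
    w = levels.astype(float) - levels.mean()
    wide = data.pivot(index=subject, columns=factor, values=dv)[levels]
    if wide.isna().any().any():
        raise ValueError("incomplete design")
    scores = wide.to_numpy() @ w
    n = scores.size
    if n < 2:
        raise ValueError("need >= 2 subjects")
    se = scores.std(ddof=1) / np.sqrt(n)
    if se == 0:
        return AnovaResult(effect=f"{factor} (linear)", F=0.0, df1=1,
                           df2=n - 1, p=1.0)
    t = scores.mean() / se
    return AnovaResult(effect=f"{factor} (linear)", F=float(t ** 2), df1=1,
                       df2=n - 1, p=float(sps.f.sf(t ** 2, 1, n - 1)))


def friedman_test(table: pd.DataFrame, dv: str, factor: str,
                  subject: str = "subject") -> tuple[float, float]:
    """Friedman rank test across the factor's levels (mid-rank ties)."""
    data = _cell_means(table, subject, [factor], dv)
    wide = data.pivot(index=subject, columns=factor, values=dv)
    if wide.isna().any().any():
        raise ValueError("incomplete design")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    cols = [wide[c].to_numpy() for c in wide.columns]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*cols)
    return float(stat), float(p)


def permutation_correlation(x, y, n_iter: int = 10000,
                            seed: int | np.random.Generator | None = None,
                            plus_one: bool = False) -> tuple[float, float]:
    """Pearson r with permutation significance.

    ``y`` is shuffled across subjects ``n_iter`` times; p is the
    proportion of permuted correlations whose absolute value strictly
    exceeds |r_obs|.  Set ``plus_one`` for the conventional
    (b+1)/(m+1) estimator instead of the strict proportion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xc = (x - x.mean()) / (x.std() * np.sqrt(x.size))
    # permuted correlations in one vectorized pass
    perm_idx = np.argsort(rng.random((n_iter, x.size)), axis=1)
    yp = y[perm_idx]
    ypc = (yp - yp.mean(axis=1, keepdims=True)) / (yp.std(axis=1, keepdims=True)
                                                   * np.sqrt(x.size))
    r_perm = ypc @ xc
    exceed = int(np.sum(np.abs(r_perm) > abs(r_obs)))
    p = (exceed + 1) / (n_iter + 1) if plus_one else exceed / n_iter
    return r_obs, float(p)


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest population correlation detectable at the given power.

    Fisher z approximation for a two-tailed test of r = 0:
    r = tanh((z_{1-alpha/2} + z_power) / sqrt(n - 3)).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    return float(np.tanh((z_a + z_b) / np.sqrt(n - 3)))


def median_split(values) -> np.ndarray:
    """Labels 0 (below-median half) / 1 (above-median half).

    An even n splits exactly n/2 and n/2.  Ties at the median are
    resolved by stable rank order (input order) with a logged note.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    order = np.argsort(v, kind="stable")
    labels = np.zeros(v.size, dtype=int)
    half = v.size // 2
    labels[order[half:]] = 1
    lower_max = v[order[half - 1]]
    upper_min = v[order[half]]
    if lower_max == upper_min:
        logger.info("median tie at %.6g resolved by stable rank order", lower_max)
    return labels


def anova_or_friedman(table: pd.DataFrame, dv: str, factor: str,
                      subject: str = "subject",
                      normality_alpha: float = 0.05) -> dict:
    """Report the more conservative of RM-ANOVA and Friedman p-values.

    Shapiro-Wilk screens each cell for normality; both tests are
    computed regardless and the larger p (with its statistic) is
    reported, so a normality violation can never inflate significance.
    """
    res_a = rm_anova(table, dv, factor, subject)[0]
    chi2, p_f = friedman_test(table, dv, factor, subject)
    cells = _cell_means(table, subject, [factor], dv)
    normal = True
    for _, grp in cells.groupby(factor):
        vals = grp[dv].to_numpy()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            if sps.shapiro(vals).pvalue < normality_alpha:
                normal = False
    if res_a.p >= p_f:
        chosen = {"test": "rm_anova", "stat": res_a.F, "p": res_a.p,
                  "df": (res_a.df1, res_a.df2)}
    else:
        chosen = {"test": "friedman", "stat": chi2, "p": p_f, "df": None}
    chosen.update(normality_ok=normal, anova=res_a, friedman=(chi2, p_f))
    return chosen
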