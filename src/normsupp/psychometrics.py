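"""Weibull psychometric fitting, duration thresholds, and size indices.

Accuracy in the 2AFC motion-direction task is modelled as a Weibull
function of stimulus duration x (ms):

    P(correct | x) = guess + (1 - guess - lapse) * (1 - exp(-(x/alpha)^beta))

with the guess rate fixed at 0.5 and the lapse rate at 0.04.  The
duration threshold is defined at 80% correct and obtained in closed
form from the fitted (alpha, beta).  The effect of stimulus size is
quantified by the size index

    SI = log10(threshold at smaller size) - log10(threshold at larger size)

negative SI = suppression (larger stimuli need more time), positive =
summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "GUESS", "LAPSE",
    "PsychometricFit", "SizeIndex",
    "weibull_p_correct", "threshold_at_p", "alpha_for_threshold",
    "fit_weibull_mle", "size_index", "geometric_mean_threshold",
    "drug_effect", "fit_trials_table", "size_index_table",
]

GUESS = 0.5
LAPSE = 0.04
THRESHOLD_P = 0.8
EXCLUSION_BOUNDS_MS = (0.0, 500.0)

# fixed multi-start grid for the MLE (log-spaced), for determinism
_ALPHA_STARTS = np.geomspace(5.0, 400.0, 5)
_BETA_STARTS = np.geomspace(0.5, 8.0, 5)


@dataclass(frozen=True)
class PsychometricFit:
    alpha: float
    beta: float
    threshold80: float
    loglik: float
    guess: float = GUESS
    lapse: float = LAPSE
    excluded: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class SizeIndex:
    value: float
    pair: tuple | None = None
    contrast: float | None = None

    def __float__(self) -> float:
        return self.value


def weibull_p_correct(duration, alpha, beta, guess: float = GUESS,
                      lapse: float = LAPSE):
    """Probability correct at the given duration(s), ms."""
    duration = np.asarray(duration, dtype=float)
    if np.any(duration < 0):
        raise ValueError("duration must be >= 0")
    if np.any(np.asarray(alpha) <= 0) or np.any(np.asarray(beta) <= 0):
        raise ValueError("alpha and beta must be > 0")
    p = guess + (1.0 - guess - lapse) * (1.0 - np.exp(-(duration / alpha) ** beta))
    return p if p.ndim else float(p)


def threshold_at_p(alpha: float, beta: float, p: float = THRESHOLD_P,
                   guess: float = GUESS, lapse: float = LAPSE) -> float:
    """Duration at which the Weibull reaches accuracy ``p`` (closed form)."""
    frac = (p - guess) / (1.0 - guess - lapse)
    if not 0.0 < frac < 1.0:
        raise ValueError(f"target accuracy {p} outside the attainable range")
    with np.errstate(over="ignore"):
        return alpha * (-np.log(1.0 - frac)) ** (1.0 / beta)


def alpha_for_threshold(threshold: float, beta: float, p: float = THRESHOLD_P,
                        guess: float = GUESS, lapse: float = LAPSE) -> float:
    """Weibull scale such that accuracy ``p`` is reached at ``threshold`` ms."""
    frac = (p - guess) / (1.0 - guess - lapse)
    return threshold / (-np.log(1.0 - frac)) ** (1.0 / beta)


def _neg_loglik(logab: np.ndarray, durations: np.ndarray,
                correct: np.ndarray, guess: float, lapse: float) -> float:
    with np.errstate(over="ignore"):
        alpha, beta = np.exp(logab)
        z = np.exp(np.clip(beta * (np.log(durations) - np.log(alpha)),
                           -745.0, 709.0))
    p = guess + (1.0 - guess - lapse) * (1.0 - np.exp(-z))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(correct, np.log(p), np.log1p(-p))))


def fit_weibull_mle(durations, correct, guess: float = GUESS,
                    lapse: float = LAPSE) -> PsychometricFit:
    """Maximum-likelihood Weibull fit with fixed guess and lapse.

    Deterministic multi-start Nelder-Mead on (log alpha, log beta) over
    a fixed 5x5 start grid.  All-correct or all-incorrect data cannot
    constrain the threshold: the fit is flagged degenerate, the
    threshold pinned to the corresponding domain boundary, and the
    estimate excluded.  Fits with threshold outside (0, 500] ms are
    excluded, mirroring the analysis exclusion rule.
    """
    durations = np.asarray(durations, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if durations.shape != correct.shape or durations.ndim != 1:
        raise ValueError("durations and correct must be equal-length 1-D")
    if durations.size < 2:
        raise ValueError("need at least 2 trials")

    if correct.all() or (~correct).all():
        boundary = 0.0 if correct.all() else float("inf")
        return PsychometricFit(alpha=np.nan, beta=np.nan, threshold80=boundary,
                               loglik=np.nan, guess=guess, lapse=lapse,
                               excluded=True, degenerate=True)

    # score the fixed 5x5 start grid, then polish the 3 best starts
    starts = [np.log([a0, b0]) for a0 in _ALPHA_STARTS for b0 in _BETA_STARTS]
    scores = [_neg_loglik(s, durations, correct, guess, lapse) for s in starts]
    best = None
    for k in np.argsort(scores, kind="stable")[:3]:
        res = minimize(_neg_loglik, x0=starts[k],
                       args=(durations, correct, guess, lapse),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    alpha, beta = np.exp(best.x)
    thr = threshold_at_p(alpha, beta, guess=guess, lapse=lapse)
    lo, hi = EXCLUSION_BOUNDS_MS
    excluded = not (lo <= thr <= hi)
    return PsychometricFit(alpha=float(alpha), beta=float(beta),
                           threshold80=float(thr), loglik=-float(best.fun),
                           guess=guess, lapse=lapse, excluded=excluded)


def size_index(threshold_smaller: float, threshold_larger: float,
               pair: tuple | None = None,
               contrast: float | None = None) -> SizeIndex:
    """SI = log10(smaller-size threshold) - log10(larger-size threshold)."""
    for name, t in (("threshold_smaller", threshold_smaller),
                    ("threshold_larger", threshold_larger)):
        if not np.isfinite(t) or t <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {t}")
    value = float(np.log10(threshold_smaller) - np.log10(threshold_larger))
    return SizeIndex(value=value, pair=pair, contrast=contrast)


def geometric_mean_threshold(thresholds) -> float:
    """exp(mean(log x)); used when averaging across heterogeneous conditions."""
    t = np.asarray(list(thresholds), dtype=float)
    if t.size == 0:
        raise ValueError("no thresholds to average")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("thresholds must be finite and > 0")
    return float(np.exp(np.mean(np.log(t))))


def drug_effect(drug_thresholds: pd.DataFrame,
                placebo_thresholds: pd.DataFrame,
                on=("subject", "contrast", "diameter_deg"),
                value: str = "threshold_ms") -> pd.DataFrame:
    """Within-subject drug-minus-placebo threshold differences.

    Both inputs need the key columns in ``on`` plus the ``value``
    column; the condition sets must match exactly per subject.
    Returns one row per key with column ``effect_ms`` plus a per-
    condition mean +/- sem aggregate accessible via groupby.
    """
    on = list(on)
    d = drug_thresholds.set_index(on)[value]
    p = placebo_thresholds.set_index(on)[value]
    missing = d.index.symmetric_difference(p.index)
    if len(missing):
        raise ValueError(
            f"unmatched drug/placebo conditions: {sorted(map(tuple, missing))}")
    out = (d - p).rename("effect_ms").reset_index()
    return out


def drug_effect_summary(effects: pd.DataFrame,
                        by=("contrast", "diameter_deg")) -> pd.DataFrame:
    """Across-subject mean +/- sem of within-subject drug effects."""
    g = effects.groupby(list(by))["effect_ms"]
    summary = g.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                    n="count")
    return summary.reset_index()


def fit_trials_table(trials: pd.DataFrame,
                     by=("subject", "session", "run", "contrast",
                         "diameter_deg")) -> pd.DataFrame:
    """Per-run Weibull fits of a trial log (catch trials excluded).

    Expects columns duration_ms, correct, is_catch plus the grouping
    keys; returns one row per group with alpha, beta, threshold80_ms,
    excluded.
    """
    by = [c for c in by if c in trials.columns]
    rows = []
    data = trials[~trials.get("is_catch", False)] if "is_catch" in trials else trials
    for keys, grp in data.groupby(by):
        fit = fit_weibull_mle(grp["duration_ms"].to_numpy(),
                              grp["correct"].to_numpy(dtype=bool))
        row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        row.update(alpha=fit.alpha, beta=fit.beta,
                   threshold80_ms=fit.threshold80, excluded=fit.excluded)
        rows.append(row)
    return pd.DataFrame(rows)


def size_index_table(thresholds: pd.DataFrame,
                     by=("subject",), contrast_col: str = "contrast",
                     size_col: str = "diameter_deg",
                     value: str = "threshold_ms") -> pd.DataFrame:
    """SIs pairing the smallest size with each larger one, per contrast.

    Excluded thresholds (column ``excluded`` if present) are dropped,
    never imputed; pairs lacking a member are omitted.
    """
    df = thresholds
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    rows = []
    for keys, grp in df.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for contrast, sub in grp.groupby(contrast_col):
            t = sub.groupby(size_col)[value].mean()
            sizes = sorted(t.index)
            if len(sizes) < 2:
                continue
            smallest = sizes[0]
            for larger in sizes[1:]:
                si = size_index(t[smallest], t[larger])
                row = dict(zip(by, keys))
                row.update({contrast_col: contrast,
                            "smaller_deg": smallest, "larger_deg": larger,
                            "si": si.value})
                rows.append(row)
    return pd.DataFrame(rows)
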