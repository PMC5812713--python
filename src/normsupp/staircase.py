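"""Psi adaptive staircase for duration-threshold estimation.

The Psi method maintains a Bayesian posterior over the Weibull
threshold (alpha) and slope (beta) of the observer's psychometric
function and, on every trial, presents the stimulus duration that
minimizes the expected entropy of the joint posterior after the
response.  Guess and lapse rates are fixed (0.5 / 0.04), matching the
analysis convention, and candidate durations span the presentable
range 6.7-333 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .psychometrics import GUESS, LAPSE, weibull_p_correct

__all__ = ["PsiConfig", "PsiState", "TrialRecord", "init_psi",
           "select_stimulus", "update_posterior", "run_staircase"]

STIMULUS_RANGE_MS = (6.7, 333.0)


@dataclass(frozen=True)
class PsiConfig:
    """Grid layout of the Psi posterior; all log-spaced."""

    alpha_range: tuple[float, float] = (3.0, 500.0)
    n_alpha: int = 40
    beta_range: tuple[float, float] = (0.5, 16.0)
    n_beta: int = 25
    stimulus_range: tuple[float, float] = STIMULUS_RANGE_MS
    n_stimulus: int = 60
    guess: float = GUESS
    lapse: float = LAPSE


@dataclass(frozen=True)
class TrialRecord:
    duration: float           # ms
    condition: tuple | str | None
    response_correct: bool
    is_catch: bool = False


@dataclass
class PsiState:
    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    posterior: np.ndarray          # shape (n_alpha, n_beta), sums to 1
    stimulus_domain: np.ndarray    # ms, ascending
    guess: float = GUESS
    lapse: float = LAPSE
    trial_count: int = 0
    # P(correct | duration d, alpha a, beta b): shape (n_d, n_alpha, n_beta)
    _likelihood: np.ndarray = field(default=None, repr=False)

    def posterior_mean_alpha(self) -> float:
        marginal = self.posterior.sum(axis=1)
        return float(np.exp(marginal @ np.log(self.alpha_grid)))


def init_psi(config: PsiConfig | None = None) -> PsiState:
    """Uniform prior over the (alpha, beta) grid."""
    cfg = config or PsiConfig()
    for name, (lo, hi), n in (("alpha", cfg.alpha_range, cfg.n_alpha),
                              ("beta", cfg.beta_range, cfg.n_beta),
                              ("stimulus", cfg.stimulus_range, cfg.n_stimulus)):
        if n < 1 or lo <= 0 or hi <= lo:
            raise ValueError(f"invalid {name} grid: range ({lo}, {hi}), n={n}")
    alpha = np.geomspace(*cfg.alpha_range, cfg.n_alpha)
    beta = np.geomspace(*cfg.beta_range, cfg.n_beta)
    domain = np.geomspace(*cfg.stimulus_range, cfg.n_stimulus)
    posterior = np.full((cfg.n_alpha, cfg.n_beta), 1.0 / (cfg.n_alpha * cfg.n_beta))
    lik = weibull_p_correct(domain[:, None, None], alpha[None, :, None],
                            beta[None, None, :], guess=cfg.guess, lapse=cfg.lapse)
    return PsiState(alpha_grid=alpha, beta_grid=beta, posterior=posterior,
                    stimulus_domain=domain, guess=cfg.guess, lapse=cfg.lapse,
                    _likelihood=lik)


def _entropy(p: np.ndarray, axis=None) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=axis)


def select_stimulus(state: PsiState) -> float:
    """Duration minimizing expected posterior entropy over (alpha, beta).

    For each candidate duration the posterior is updated under both
    possible responses; the expected entropy weights the two updated
    posteriors by the predicted probability of each response.  Ties
    break toward the shorter duration (the domain is ascending and
    argmin returns the first minimum).
    """
    post = state.posterior.ravel()
    if post.max() > 1.0 - 1e-12:
        warnings.warn("posterior is degenerate (all mass on one cell); "
                      "returning the duration nearest its alpha", stacklevel=2)
        ia, _ = np.unravel_index(int(state.posterior.argmax()),
                                 state.posterior.shape)
        alpha = state.alpha_grid[ia]
        return float(state.stimulus_domain[np.abs(state.stimulus_domain - alpha).argmin()])

    lik = state._likelihood.reshape(state.stimulus_domain.size, -1)  # (n_d, n_cells)
    joint_c = lik * post[None, :]
    p_correct = joint_c.sum(axis=1)
    joint_i = (1.0 - lik) * post[None, :]
    p_incorrect = 1.0 - p_correct
    with np.errstate(invalid="ignore"):
        h_c = _entropy(joint_c / p_correct[:, None], axis=1)
        h_i = _entropy(joint_i / p_incorrect[:, None], axis=1)
    expected_h = p_correct * h_c + p_incorrect * h_i
    return float(state.stimulus_domain[int(np.argmin(expected_h))])


def update_posterior(state: PsiState, duration: float, correct: bool) -> PsiState:
    """Bayes update of the posterior after one trial (log-space)."""
    domain = state.stimulus_domain
    idx = int(np.abs(domain - duration).argmin())
    if abs(domain[idx] - duration) > 1e-6 * max(1.0, duration):
        raise ValueError(f"duration {duration} ms not in the stimulus domain")
    lik = state._likelihood[idx] if correct else 1.0 - state._likelihood[idx]
    with np.errstate(divide="ignore"):
        log_post = np.log(state.posterior) + np.log(lik)
    m = log_post.max()
    if not np.isfinite(m):
        raise FloatingPointError("likelihood is zero over the entire grid")
    post = np.exp(log_post - m)
    post /= post.sum()
    return PsiState(alpha_grid=state.alpha_grid, beta_grid=state.beta_grid,
                    posterior=post, stimulus_domain=domain,
                    guess=state.guess, lapse=state.lapse,
                    trial_count=state.trial_count + 1,
                    _likelihood=state._likelihood)


def run_staircase(observer, condition, n_trials: int = 30,
                  seed: int | np.random.Generator | None = None,
                  config: PsiConfig | None = None
                  ) -> tuple[list[TrialRecord], PsiState]:
    """Run one adaptive staircase against an observer.

    ``observer`` is either a callable ``observer(duration, condition,
    rng) -> bool`` or an object with a ``respond`` method of that
    signature.  Returns the trial records and the final posterior
    state; bit-reproducible for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    respond = observer.respond if hasattr(observer, "respond") else observer
    state = init_psi(config)
    records: list[TrialRecord] = []
    for _ in range(n_trials):
        duration = select_stimulus(state)
        correct = bool(respond(duration, condition, rng))
        state = update_posterior(state, duration, correct)
        records.append(TrialRecord(duration=duration, condition=condition,
                                   response_correct=correct))
    return records, state
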