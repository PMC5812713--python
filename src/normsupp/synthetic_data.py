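"""Synthetic-data generators for every stage of the pipeline.

Simulated 2AFC observers respond by a Weibull psychometric function
whose 80%-correct durations come from the normalization model; blocked
BOLD runs follow the alternating small/large 10 s design (25 blocks,
125 samples at TR = 2 s) with a double-gamma hemodynamic response and
white noise; edited spectra carry a Gaussian GABA+ peak at 3 ppm and a
pseudo-Voigt water reference at 4.7 ppm with noise scaled for the
number of averages; and whole-population experiments draw subject
ability jointly with a GABA+ value at a target correlation.  Every
generator returns its ground truth next to the data so downstream
stages have recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from . import normalization_model as nm
from . import psychometrics as psy
from .fmri_roi import RoiTimecourse
from .mrs_quant import EditedSpectrum, reject_artifacts
from .staircase import PsiConfig, run_staircase

__all__ = ["ObserverSpec", "Observer", "PopulationSpec", "ExperimentDesign",
           "SimulatedExperiment", "gen_observer", "gen_experiment",
           "gen_bold_run", "gen_spectrum", "double_gamma_hrf",
           "DEFAULT_CRITERIA", "DEFAULT_DRUG_PROFILE"]

from .config import DEFAULT_CRITERIA

# lorazepam-arm additive log10-threshold shifts, largest for small stimuli
DEFAULT_DRUG_PROFILE = {1.0: 0.25, 2.0: 0.15, 12.0: 0.08}

CATCH_DURATION_MS = 333.0


@dataclass(frozen=True)
class ObserverSpec:
    """A simulated 2AFC observer.

    ``condition_thresholds`` maps (contrast, diameter) to the true
    80%-correct duration (ms); the Weibull scale for each condition is
    recovered in closed form so that P(correct | threshold) = 0.8.
    """

    condition_thresholds: dict
    slope_beta: float = 3.0
    guess: float = psy.GUESS
    lapse: float = psy.LAPSE

    def __post_init__(self) -> None:
        if self.slope_beta <= 0:
            raise ValueError("slope_beta must be > 0")
        for cond, t in self.condition_thresholds.items():
            if t <= 0:
                raise ValueError(f"threshold for {cond} must be > 0")


class Observer:
    """P(correct | duration, condition) with Bernoulli responses."""

    def __init__(self, spec: ObserverSpec):
        self.spec = spec
        self._alpha = {
            cond: psy.alpha_for_threshold(t, spec.slope_beta,
                                          guess=spec.guess, lapse=spec.lapse)
            for cond, t in spec.condition_thresholds.items()}

    def p_correct(self, duration: float, condition) -> float:
        if condition not in self._alpha:
            raise KeyError(f"unknown condition {condition!r}")
        return float(psy.weibull_p_correct(duration, self._alpha[condition],
                                           self.spec.slope_beta,
                                           guess=self.spec.guess,
                                           lapse=self.spec.lapse))

    def respond(self, duration: float, condition,
                rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(duration, condition))


def gen_observer(spec: ObserverSpec) -> Observer:
    return Observer(spec)


@dataclass(frozen=True)
class ExperimentDesign:
    """Session layout: runs of six interleaved staircases plus catch trials."""

    n_runs: int = 4
    n_trials_per_staircase: int = 30
    n_catch: int = 10
    catch_rate: float = 0.99
    sizes: tuple[float, ...] = (1.0, 2.0, 12.0)
    contrasts: tuple[float, ...] = (0.03, 0.98)
    slope_beta: float = 3.0
    psi_config: PsiConfig = field(default_factory=PsiConfig)

    @property
    def conditions(self) -> list[tuple[float, float]]:
        return [(c, s) for c in self.contrasts for s in self.sizes]


@dataclass(frozen=True)
class PopulationSpec:
    """Subject population with a target GABA-performance correlation.

    ``rho_gaba_performance`` is the population correlation between the
    GABA+ value and the subject's log10 geometric-mean threshold
    (negative: more GABA+, better performance).  Ability enters as a
    multiplicative threshold scaling (additive in log10), so size
    indices are untouched by construction.
    """

    n_subjects: int = 22
    between_subject_sd: float = 0.15     # log10-threshold spread
    gaba_mean: float = 1.0               # institutional units
    gaba_sd: float = 0.15
    rho_gaba_performance: float = -0.46
    drug_effect_profile: dict | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.rho_gaba_performance) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.n_subjects < 2:
            raise ValueError("need >= 2 subjects")


@dataclass
class SimulatedExperiment:
    trials: pd.DataFrame
    subjects: pd.DataFrame
    ground_truth: dict


def _model_condition_thresholds(params: nm.ModelParams | None,
                                design: ExperimentDesign,
                                criteria: dict | None) -> dict:
    params = params or nm.ModelParams()
    table = nm.predict_condition_table(params, sizes=design.sizes,
                                       contrasts=design.contrasts,
                                       criteria=criteria or DEFAULT_CRITERIA)
    return {(row.contrast, row.diameter_deg): row.predicted_threshold_ms
            for row in table.thresholds.itertuples()}


def _draw_population(pop: PopulationSpec, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(log10-threshold offsets, GABA values), bivariate normal at rho."""
    rho = pop.rho_gaba_performance
    cov = [[pop.between_subject_sd ** 2,
            rho * pop.between_subject_sd * pop.gaba_sd],
           [rho * pop.between_subject_sd * pop.gaba_sd, pop.gaba_sd ** 2]]
    draws = rng.multivariate_normal([0.0, pop.gaba_mean], cov,
                                    size=pop.n_subjects)
    return draws[:, 0], draws[:, 1]


def gen_experiment(population: PopulationSpec,
                   design: ExperimentDesign | None = None,
                   params: nm.ModelParams | None = None,
                   criteria: dict | None = None) -> SimulatedExperiment:
    """Simulate a full psychophysical experiment for a population.

    Per subject (and per session when a drug profile is set): each run
    holds one 30-trial Psi staircase per condition, interleaved in
    randomized condition order, plus 10 catch trials (big high-contrast,
    333 ms) answered correctly at ``catch_rate``.  Subject thresholds
    are the model-predicted condition thresholds scaled by the
    subject's ability factor; the lorazepam arm adds per-condition
    log10 shifts on top.
    """
    design = design or ExperimentDesign()
    base = _model_condition_thresholds(params, design, criteria)
    root = np.random.SeedSequence(population.seed)
    ss_pop, ss_trials = root.spawn(2)
    rng_pop = np.random.default_rng(ss_pop)
    offsets, gaba = _draw_population(population, rng_pop)

    sessions = ["placebo", "drug"] if population.drug_effect_profile else ["single"]
    catch_condition = (max(design.contrasts), max(design.sizes))
    rows, subj_rows, truth_thresholds = [], [], {}
    trial_streams = ss_trials.spawn(population.n_subjects)
    for i in range(population.n_subjects):
        subject = f"S{i + 1:02d}"
        per_session = {}
        for session in sessions:
            thresholds = {cond: t * 10.0 ** offsets[i]
                          for cond, t in base.items()}
            if session == "drug":
                prof = population.drug_effect_profile
                thresholds = {
                    (c, s): t * 10.0 ** prof.get(s, 0.0)
                    for (c, s), t in thresholds.items()}
            per_session[session] = thresholds
            observer = gen_observer(ObserverSpec(
                condition_thresholds=thresholds,
                slope_beta=design.slope_beta))
            n_streams = design.n_runs * (len(design.conditions) + 2)
            streams = iter(trial_streams[i].spawn(len(sessions) * n_streams))
            if session == "drug":           # keep placebo streams distinct
                for _ in range(n_streams):
                    next(streams)
            for run in range(1, design.n_runs + 1):
                run_records = []
                for cond in design.conditions:
                    rng = np.random.default_rng(next(streams))
                    records, _ = run_staircase(
                        observer, cond,
                        n_trials=design.n_trials_per_staircase,
                        seed=rng, config=design.psi_config)
                    run_records.extend(records)
                rng_catch = np.random.default_rng(next(streams))
                for _ in range(design.n_catch):
                    run_records.append(type(run_records[0])(
                        duration=CATCH_DURATION_MS, condition=catch_condition,
                        response_correct=bool(rng_catch.random() < design.catch_rate),
                        is_catch=True))
                rng_order = np.random.default_rng(next(streams))
                order = rng_order.permutation(len(run_records))
                for trial_index, j in enumerate(order, start=1):
                    rec = run_records[j]
                    contrast, diameter = rec.condition
                    rows.append({
                        "subject": subject, "session": session, "run": run,
                        "condition_contrast_pct": contrast * 100.0,
                        "condition_diameter_deg": diameter,
                        "contrast": contrast, "diameter_deg": diameter,
                        "trial_index": trial_index,
                        "duration_ms": rec.duration,
                        "correct": rec.response_correct,
                        "is_catch": rec.is_catch,
                    })
        truth_thresholds[subject] = per_session
        log_gmean = float(np.log10(psy.geometric_mean_threshold(
            list(per_session[sessions[0]].values()))))
        subj_rows.append({"subject": subject, "gaba": gaba[i],
                          "ability_log10_offset": offsets[i],
                          "true_log10_gmean_threshold_ms": log_gmean})

    subjects = pd.DataFrame(subj_rows)
    truth = {"condition_thresholds_ms": truth_thresholds,
             "base_model_thresholds_ms": {str(k): v for k, v in base.items()},
             "rho_gaba_performance": population.rho_gaba_performance,
             "seed": population.seed}
    return SimulatedExperiment(trials=pd.DataFrame(rows), subjects=subjects,
                               ground_truth=truth)


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    h = (gamma_dist.pdf(t, peak_s)
         - undershoot_ratio * gamma_dist.pdf(t, undershoot_s))
    return h / h.max()


def gen_bold_run(amplitudes: dict | tuple = (1.0, 0.8),
                 noise_sd: float = 0.25, tr_s: float = 2.0,
                 n_blocks: int = 25, block_duration_s: float = 10.0,
                 baseline: float = 100.0,
                 seed: int | np.random.Generator | None = None
                 ) -> tuple[RoiTimecourse, dict]:
    """One blocked alternating-size run with HRF convolution and noise.

    ``amplitudes`` gives the neural response (percent signal units) of
    the small- and big-stimulus blocks, as a (small, big) tuple or a
    {"small": ..., "big": ...} mapping.  Blocks alternate starting with
    small (13 small / 12 big at the default 25); ``noise_sd`` is white
    noise per TR sample, percent signal units.  Returns the time course
    (big-block onsets annotated) plus ground truth.
    """
    if isinstance(amplitudes, dict):
        a_small, a_big = float(amplitudes["small"]), float(amplitudes["big"])
    else:
        a_small, a_big = map(float, amplitudes)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    samples_per_block = int(round(block_duration_s / tr_s))
    n_samples = n_blocks * samples_per_block
    dt = 0.1
    t_hi = np.arange(0.0, n_samples * tr_s, dt)
    neural = np.where((t_hi // block_duration_s).astype(int) % 2 == 0,
                      a_small, a_big)
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt))
    hrf = hrf / hrf.sum()        # unit gain: a sustained block reaches its amplitude
    bold = np.convolve(neural, hrf)[: t_hi.size]
    sample_idx = (np.arange(n_samples) * tr_s / dt).astype(int)
    psc = bold[sample_idx] + rng.normal(0.0, noise_sd, n_samples)
    signal = baseline * (1.0 + psc / 100.0)

    big_onsets = tuple(b * samples_per_block for b in range(1, n_blocks, 2))
    ts = RoiTimecourse(samples=signal, tr_s=tr_s, block_onsets=big_onsets,
                       block_duration_s=block_duration_s)
    truth = {"amplitude_small_pct": a_small, "amplitude_big_pct": a_big,
             "effect_pct": a_big - a_small, "noise_sd_pct": noise_sd,
             "n_samples": n_samples}
    return ts, truth


def gen_spectrum(gaba_area: float = 3.0, water_area: float = 1000.0,
                 gaba_sd_ppm: float = 0.045, water_fwhm_ppm: float = 0.04,
                 water_eta: float = 0.3, noise_sd: float = 25.0,
                 n_averages: int = 320, n_points: int = 2048,
                 spectral_width_hz: float = 2000.0, field_mhz: float = 127.7,
                 n_outliers: int = 0, outlier_magnitude: float = 8.0,
                 seed: int | np.random.Generator | None = None
                 ) -> tuple[EditedSpectrum, dict]:
    """One edited difference spectrum plus water reference.

    The GABA+ peak is a Gaussian of known area at 3.0 ppm; water is a
    pseudo-Voigt of known area at 4.7 ppm.  ``noise_sd`` is the
    single-average noise SD; the averaged spectrum carries noise_sd /
    sqrt(n kept averages), where kept excludes averages flagged by the
    > 3 SD rule on the simulated per-average frequency-correction
    magnitudes (outliers injected on request).
    """
    if gaba_area <= 0 or water_area <= 0:
        raise ValueError("areas must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hz_per_point = spectral_width_hz / n_points
    ppm = 4.7 + (np.arange(n_points) - n_points / 2) * hz_per_point / field_mhz

    corr = np.abs(rng.standard_normal(n_averages))
    if n_outliers:
        out_idx = rng.choice(n_averages, size=n_outliers, replace=False)
        corr[out_idx] += outlier_magnitude
    n_rejected = int(reject_artifacts(corr).sum())
    n_kept = max(n_averages - n_rejected, 1)
    eff_noise = noise_sd / np.sqrt(n_kept)

    gaba_clean = gaba_area * np.exp(-0.5 * ((ppm - 3.0) / gaba_sd_ppm) ** 2) \
        / (gaba_sd_ppm * np.sqrt(2.0 * np.pi))
    amplitude = gaba_clean + rng.normal(0.0, eff_noise, n_points)

    hwhm = water_fwhm_ppm / 2.0
    lor = (hwhm / np.pi) / ((ppm - 4.7) ** 2 + hwhm ** 2)
    w_sd = water_fwhm_ppm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gau = np.exp(-0.5 * ((ppm - 4.7) / w_sd) ** 2) / (w_sd * np.sqrt(2.0 * np.pi))
    water_clean = water_area * (water_eta * lor + (1.0 - water_eta) * gau)
    water = water_clean + rng.normal(0.0, eff_noise, n_points)

    spectrum = EditedSpectrum(ppm=ppm, amplitude=amplitude,
                              water_amplitude=water, correction_params=corr)
    truth = {"gaba_area": gaba_area, "water_area": water_area,
             "ratio": gaba_area / water_area, "gaba_sd_ppm": gaba_sd_ppm,
             "water_fwhm_ppm": water_fwhm_ppm, "water_eta": water_eta,
             "n_averages": n_averages, "n_rejected": n_rejected,
             "effective_noise_sd": eff_noise, "field_mhz": field_mhz}
    return spectrum, truth
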