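"""Block-design ROI time-course analysis for surround suppression.

Stimuli of two sizes alternate in 10 s blocks; the response of a
center-selective ROI to the larger stimulus is measured relative to the
tail of the preceding small-stimulus block.  Each block of interest is
epoched from 4 s before onset to 2 s after block end, converted to
percent signal change against a run-wide baseline (the mean over the
0-4 s pre-onset windows of all epochs), and summarized by the mean
signal in the 8-12 s post-onset peak window.  Negative peak responses
indicate suppression by the size increase; positive, summation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RoiTimecourse", "EpochResponse", "epoch", "percent_signal_change",
           "peak_response", "aggregate", "analyze_run", "read_run_tsv"]

PRE_ONSET_S = 4.0        # epoch starts 4 s before block onset (baseline window)
POST_BLOCK_S = 2.0       # epoch ends 2 s after block end
PEAK_WINDOW_S = (8.0, 12.0)   # half-open [8, 12) s after onset


@dataclass(frozen=True)
class RoiTimecourse:
    """ROI-mean BOLD samples at TR resolution with block annotations."""

    samples: np.ndarray
    tr_s: float = 2.0
    block_onsets: tuple[int, ...] = ()
    block_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "block_onsets",
                           tuple(int(o) for o in self.block_onsets))


@dataclass(frozen=True)
class EpochResponse:
    """Percent-signal-change trace of one epoch and its peak-window mean."""

    psc: np.ndarray
    peak: float
    onset: int


def _epoch_sample_counts(ts: RoiTimecourse) -> tuple[int, int]:
    pre = int(round(PRE_ONSET_S / ts.tr_s))
    total = int(round((PRE_ONSET_S + ts.block_duration_s + POST_BLOCK_S) / ts.tr_s))
    return pre, total


def epoch(ts: RoiTimecourse) -> list[np.ndarray]:
    """Raw epochs [-4 s, block end + 2 s) around each onset.

    Out-of-range epochs (e.g. an onset too close to the run start to
    have a baseline window) are dropped with a logged count.
    """
    pre, total = _epoch_sample_counts(ts)
    epochs, dropped = [], 0
    for onset in ts.block_onsets:
        lo, hi = onset - pre, onset - pre + total
        if lo < 0 or hi > ts.samples.size:
            dropped += 1
            continue
        epochs.append(ts.samples[lo:hi].copy())
    if dropped:
        logger.warning("dropped %d/%d epochs outside the run extent",
                       dropped, len(ts.block_onsets))
    return epochs


def percent_signal_change(epochs: list[np.ndarray], tr_s: float = 2.0,
                          block_duration_s: float = 10.0) -> list[EpochResponse]:
    """Convert raw epochs to percent signal change.

    One shared baseline per run: the mean of the [-4, 0) s pre-onset
    samples pooled over all epochs.  psc = 100 * (x - b) / b, which is
    invariant to rescaling the whole time course.
    """
    if not epochs:
        return []
    pre = int(round(PRE_ONSET_S / tr_s))
    baseline = float(np.mean([e[:pre] for e in epochs]))
    if baseline <= 0:
        raise ValueError(
            f"run baseline {baseline:.3g} <= 0; input looks unnormalized or corrupt")
    out = []
    for onset_i, e in enumerate(epochs):
        psc = 100.0 * (e - baseline) / baseline
        out.append(EpochResponse(psc=psc, peak=peak_response(psc, tr_s),
                                 onset=onset_i))
    return out


def peak_response(epoch_psc: np.ndarray, tr_s: float = 2.0) -> float:
    """Mean psc over onset-relative times t with 8 s <= t < 12 s."""
    epoch_psc = np.asarray(epoch_psc, dtype=float)
    pre = int(round(PRE_ONSET_S / tr_s))
    t = (np.arange(epoch_psc.size) - pre) * tr_s
    mask = (t >= PEAK_WINDOW_S[0]) & (t < PEAK_WINDOW_S[1])
    if not mask.any():
        raise ValueError("no samples fall in the 8-12 s peak window")
    return float(epoch_psc[mask].mean())


def aggregate(responses: pd.DataFrame,
              levels: tuple[str, ...] = ("epoch", "hemisphere", "run"),
              value: str = "response",
              keep: tuple[str, ...] = ("subject", "condition")) -> pd.DataFrame:
    """Nested means: across epochs, then hemispheres per run, then runs.

    ``responses`` is long-form with one row per epoch and columns for
    every level plus the grouping keys in ``keep``.  Averaging is
    strictly nested in the order given (mean of means, not a pooled
    mean), matching the convention of averaging epochs within a
    hemisphere-run, hemispheres within a run, then runs within a
    subject.  Missing hemispheres are averaged over what is present,
    with a logged note.
    """
    df = responses.copy()
    remaining = [lv for lv in levels if lv in df.columns]
    if "hemisphere" in remaining:
        n_hemi = df.groupby(list(keep))["hemisphere"].nunique()
        short = n_hemi[n_hemi < n_hemi.max()]
        if len(short):
            logger.info("averaging over a single hemisphere for %d group(s)",
                        len(short))
    for lv in remaining:
        group_cols = [c for c in list(keep) + list(remaining) if c != lv
                      and c in df.columns]
        df = df.groupby(group_cols, as_index=False)[value].mean()
        remaining = [x for x in remaining if x != lv]
    return df


def analyze_run(ts: RoiTimecourse) -> dict:
    """Epoch, convert and summarize one run; returns per-epoch peaks + mean."""
    eps = epoch(ts)
    responses = percent_signal_change(eps, ts.tr_s, ts.block_duration_s)
    peaks = np.array([r.peak for r in responses])
    return {"epoch_peaks": peaks,
            "mean_peak": float(peaks.mean()) if peaks.size else float("nan"),
            "n_epochs": len(responses)}


def read_run_tsv(path) -> RoiTimecourse:
    """Read a run TSV: `# key=value` header lines then a `signal` column.

    Recognized keys: tr_s, onsets (comma-separated sample indices),
    block_duration_s.  A sidecar JSON (same stem, .json) may supply the
    same keys instead.
    """
    path = Path(path)
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            else:
                rows.append(line)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if rows and rows[0].lower() == "signal":
        rows = rows[1:]
    samples = np.array([float(r) for r in rows])
    onsets = meta.get("onsets", "")
    if isinstance(onsets, str):
        onsets = [int(x) for x in onsets.split(",") if x.strip()]
    return RoiTimecourse(samples=samples,
                         tr_s=float(meta.get("tr_s", 2.0)),
                         block_onsets=tuple(onsets),
                         block_duration_s=float(meta.get("block_duration_s", 10.0)))
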