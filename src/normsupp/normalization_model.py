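"""Divisive-normalization model of spatial suppression and summation.

The model describes the steady-state response of a population of
motion-sensitive visual neurons to a drifting grating as

    R = E / (S + sigma)

where ``E`` is an excitatory drive pooled over a narrow spatial (and
feature) extent, ``S`` is a suppressive drive pooled over a broader
extent, and ``sigma`` is the semi-saturation constant that controls
sensitivity at low input strength.  Both drives derive from the same
effective-contrast field (contrast raised to an expansive response
exponent), so suppression versus summation falls out of the relative
magnitude of ``S`` and ``sigma`` at a given contrast rather than from
separate mechanisms.

A winner-take-all readout takes the peak of the population response
(the response to the stimulus center), and the predicted duration
threshold for motion discrimination is inversely related to it:

    threshold = criterion / peak_response

Space is two-dimensional with circular symmetry: fields are stored as
their radial section through the stimulus center (a symmetric 1-D
profile), and spatial pooling is a genuine 2-D Gaussian convolution of
the circularly symmetric field, evaluated on that central line.  The
2-D geometry matters quantitatively - pooled drives grow with stimulus
area, not diameter, which sets the size of the predicted suppression
and summation effects.  The feature axis is motion direction on
[0, 360) with wrapped (circular) pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

__all__ = [
    "StimulusSpec",
    "ModelParams",
    "SpatialGrid",
    "PopulationResponse",
    "build_stimulus_drive",
    "radial_embed",
    "pooled_drive",
    "normalized_response",
    "readout_peak",
    "predict_threshold",
    "predict_condition_table",
    "ConditionTable",
]

KERNEL_TRUNCATION_SD = 5.0  # pooling kernels cut at +/- 5 SD, then renormalized


@dataclass(frozen=True)
class StimulusSpec:
    """A drifting grating in a blurred circular aperture.

    contrast: Michelson contrast as a fraction in [0, 1].
    diameter: aperture diameter, degrees of visual angle.
    edge_sd: SD of the Gaussian blur of the aperture edge, degrees.
    spatial_frequency: cycles/degree (metadata; the 1-D spatial model
        does not use it).
    """

    contrast: float
    diameter: float
    edge_sd: float = 0.25
    spatial_frequency: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.edge_sd < 0:
            raise ValueError(f"edge_sd must be >= 0, got {self.edge_sd}")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one instantiation of the normalization model.

    Pooling widths are Gaussian SDs.  The suppressive pool must be
    spatially broader than the excitatory pool; the feature pool at
    least as broad.  ``contrast_gain_exponent`` is the expansive
    contrast-response exponent (an energy-type nonlinearity; default
    2); together with ``contrast_gain`` and ``response_gain`` it also
    hosts the input-gain and output-gain variants used to model
    GABAergic (lorazepam) effects, which scale the gain and raise the
    exponent.  ``criterion`` is the accumulated-response level required
    for a perceptual decision.
    """

    sigma: float = 0.01
    exc_space_width: float = 0.4
    sup_space_width: float = 1.0
    exc_feature_width: float = 30.0
    sup_feature_width: float = 90.0
    contrast_gain: float = 1.0
    contrast_gain_exponent: float = 2.0
    response_gain: float = 1.0
    criterion: float = 105.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.sup_space_width <= self.exc_space_width:
            raise ValueError(
                "suppressive spatial pooling must be broader than excitatory "
                f"(sup={self.sup_space_width}, exc={self.exc_space_width})"
            )
        if self.sup_feature_width < self.exc_feature_width:
            raise ValueError("sup_feature_width must be >= exc_feature_width")
        for name in ("contrast_gain", "response_gain", "criterion",
                     "contrast_gain_exponent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SpatialGrid:
    """Discretization of the model: positions (deg) x directions (deg).

    Positions are uniformly spaced and symmetric about 0; features
    cover [0, 360) uniformly.
    """

    positions: np.ndarray
    features: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 360.0, 15.0))

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or pos.size < 3:
            raise ValueError("positions must be a 1-D array of >= 3 points")
        d = np.diff(pos)
        if not np.allclose(d, d[0]):
            raise ValueError("positions must be uniformly spaced")
        if abs(pos[0] + pos[-1]) > 1e-9 * max(1.0, abs(pos[-1])):
            raise ValueError("positions must be symmetric about 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "features",
                           np.asarray(self.features, dtype=float))

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def half_extent(self) -> float:
        return float(self.positions[-1])

    @property
    def center_index(self) -> int:
        return int(np.argmin(np.abs(self.positions)))

    @classmethod
    def for_stimuli(cls, max_diameter: float, params: ModelParams,
                    spacing: float = 0.05, n_features: int = 24,
                    margin_sd: float = 3.0) -> "SpatialGrid":
        """Grid wide enough that pooling kernels are not truncated.

        Half-extent is radius + ``margin_sd`` suppressive SDs (total
        extent >= diameter + 2*margin_sd*sup_space_width).
        """
        half = max_diameter / 2.0 + margin_sd * params.sup_space_width
        n = int(np.ceil(half / spacing))
        positions = np.arange(-n, n + 1) * spacing
        features = np.arange(0.0, 360.0, 360.0 / n_features)
        return cls(positions=positions, features=features)


@dataclass(frozen=True)
class PopulationResponse:
    """Non-negative response field over (position, feature)."""

    values: np.ndarray  # shape (n_positions, n_features)
    grid: SpatialGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.positions.size, self.grid.features.size):
            raise ValueError(
                f"values shape {v.shape} does not match grid "
                f"({self.grid.positions.size}, {self.grid.features.size})")
        if not np.all(np.isfinite(v)):
            raise ValueError("response field contains non-finite values")
        if np.any(v < 0):
            raise ValueError("response field contains negative values")
        object.__setattr__(self, "values", v)


def _aperture_profile(x: np.ndarray, radius: float, edge_sd: float) -> np.ndarray:
    """Circular aperture along a line through center, Gaussian-blurred edge.

    Closed form for a boxcar of half-width ``radius`` convolved with a
    Gaussian of SD ``edge_sd``; a hard edge when edge_sd == 0.
    """
    if edge_sd == 0:
        return (np.abs(x) <= radius).astype(float)
    s = edge_sd * np.sqrt(2.0)
    return 0.5 * (erf((radius - x) / s) + erf((radius + x) / s))


def build_stimulus_drive(stim: StimulusSpec, grid: SpatialGrid,
                         params: ModelParams) -> PopulationResponse:
    """Effective-contrast field of a grating in a blurred aperture.

    Effective contrast is ``(contrast * contrast_gain) **
    contrast_gain_exponent`` inside the aperture, falling to 0 across
    the blurred edge; uniform over the direction axis (a single
    drifting grating carries one direction, and direction pooling of a
    uniform field is the identity).
    """
    radius = stim.diameter / 2.0
    required_half = radius + 3.0 * params.sup_space_width
    if grid.half_extent < required_half - 1e-9:
        raise ValueError(
            f"grid half-extent {grid.half_extent:.2f} deg too small for a "
            f"{stim.diameter} deg stimulus; need >= {required_half:.2f} deg "
            f"(radius + 3 suppressive pooling SDs)")
    c_eff = (stim.contrast * params.contrast_gain) ** params.contrast_gain_exponent
    profile = c_eff * _aperture_profile(grid.positions, radius, stim.edge_sd)
    values = np.repeat(profile[:, None], grid.features.size, axis=1)
    return PopulationResponse(values=np.clip(values, 0.0, None), grid=grid)


def _space_kernel(space_width: float, spacing: float, n_positions: int) -> np.ndarray:
    half_n = int(np.ceil(KERNEL_TRUNCATION_SD * space_width / spacing))
    if 2 * half_n + 1 > 2 * n_positions - 1:
        raise ValueError(
            f"spatial pooling kernel ({2 * half_n + 1} taps at SD "
            f"{space_width} deg) exceeds the grid; enlarge the grid extent")
    offsets = np.arange(-half_n, half_n + 1) * spacing
    k = np.exp(-0.5 * (offsets / space_width) ** 2)
    return k / k.sum()


def _wrapped_feature_kernel(feature_width: float, features: np.ndarray) -> np.ndarray:
    """Unit-sum wrapped-Gaussian kernel over the circular direction axis."""
    n = features.size
    step = 360.0 / n
    offsets = np.arange(n) * step
    k = np.zeros(n)
    for wrap in range(-3, 4):
        k += np.exp(-0.5 * ((offsets + 360.0 * wrap) / feature_width) ** 2)
    return k / k.sum()


def radial_embed(profile: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Embed a symmetric radial section into its 2-D circular field.

    ``profile`` holds f(|x|) on the symmetric position grid; the result
    is F[i, j] = f(sqrt(x_i^2 + x_j^2)) by linear interpolation in
    radius (zero beyond the grid extent).  Asymmetric inputs are
    symmetrized by averaging the two half-profiles.
    """
    half = 0.5 * (profile + profile[::-1])
    center = int(np.argmin(np.abs(positions)))
    radii = positions[center:]
    values = half[center:]
    rr = np.hypot(positions[:, None], positions[None, :])
    return np.interp(rr, radii, values, right=0.0)


def _radial_pool(profile: np.ndarray, positions: np.ndarray,
                 space_width: float, kernel: np.ndarray) -> np.ndarray:
    """2-D Gaussian pooling of a circular field, on the central row.

    Separable convolution of the embedded field; only rows within the
    kernel support of the central row are convolved along x before the
    final cross-row combination at y = 0.
    """
    field = radial_embed(profile, positions)
    center = int(np.argmin(np.abs(positions)))
    half_n = (kernel.size - 1) // 2
    rows = np.arange(max(center - half_n, 0),
                     min(center + half_n + 1, positions.size))
    sub = ndimage.convolve1d(field[rows], kernel, axis=1, mode="constant",
                             cval=0.0)
    weights = kernel[(rows - center) + half_n]
    return weights @ sub


def pooled_drive(drive: PopulationResponse, space_width: float,
                 feature_width: float) -> PopulationResponse:
    """Pooling: 2-D Gaussian over space, wrapped Gaussian over direction.

    Each feature column is read as the radial section of a circularly
    symmetric 2-D field, convolved with a unit-volume 2-D Gaussian
    (separable, truncated at 5 SD), and returned as the pooled central
    row.  Direction pooling is a circular convolution with a unit-sum
    wrapped Gaussian.  A uniform field is unchanged, and the volume of
    the embedded 2-D field is conserved (up to boundary leakage for
    fields extending near the grid edge).
    """
    if space_width <= 0 or feature_width <= 0:
        raise ValueError("pooling widths must be > 0")
    grid = drive.grid
    sk = _space_kernel(space_width, grid.spacing, grid.positions.size)
    cols = drive.values
    if np.all(cols == cols[:, :1]):
        # identical feature columns (a single grating): pool once
        row = _radial_pool(cols[:, 0], grid.positions, space_width, sk)
        pooled = np.repeat(row[:, None], grid.features.size, axis=1)
    else:
        pooled = np.column_stack([
            _radial_pool(cols[:, f], grid.positions, space_width, sk)
            for f in range(grid.features.size)])
    fk = _wrapped_feature_kernel(feature_width, grid.features)
    # circular convolution along the feature axis via a circulant product
    n = fk.size
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    circulant = fk[idx]
    pooled = pooled @ circulant
    return PopulationResponse(values=np.clip(pooled, 0.0, None), grid=grid)


def normalized_response(stim: StimulusSpec, grid: SpatialGrid,
                        params: ModelParams) -> PopulationResponse:
    """R = response_gain * E / (S + sigma) over the population."""
    drive = build_stimulus_drive(stim, grid, params)
    exc = pooled_drive(drive, params.exc_space_width, params.exc_feature_width)
    sup = pooled_drive(drive, params.sup_space_width, params.sup_feature_width)
    resp = params.response_gain * exc.values / (sup.values + params.sigma)
    return PopulationResponse(values=resp, grid=grid)


def readout_peak(resp: PopulationResponse) -> float:
    """Winner-take-all readout: the maximum of the population response.

    For a centered stimulus the response field is symmetric about
    position 0; an asymmetric field (peak without a mirror twin)
    indicates an asymmetric grid and triggers a warning.  Note the
    maximum need not sit exactly at the center: with a flat-top
    aperture, large stimuli develop a symmetric response maximum just
    inside the aperture edge, where the broad suppressive pool is
    truncated sooner than the narrow excitatory pool.
    """
    if resp.values.size == 0:
        raise ValueError("empty response field")
    if not np.allclose(resp.values, resp.values[::-1], atol=1e-9):
        warnings.warn("response field is not symmetric about the center; "
                      "grid may be asymmetric", stacklevel=2)
    return float(resp.values.max())


def predict_threshold(peak_response: float, criterion: float) -> float:
    """Predicted duration threshold (ms): criterion / peak response."""
    if peak_response <= 0:
        raise ValueError(
            "peak response must be > 0 (unresponsive model configuration)")
    if criterion <= 0:
        raise ValueError("criterion must be > 0")
    return criterion / peak_response


@dataclass(frozen=True)
class ConditionTable:
    """Model predictions over a size x contrast design."""

    thresholds: pd.DataFrame   # contrast, diameter_deg, peak_response, predicted_threshold_ms
    size_indices: pd.DataFrame  # contrast, pair, si


def predict_condition_table(params: ModelParams,
                            sizes: list[float] | tuple[float, ...] = (1.0, 2.0, 12.0),
                            contrasts: list[float] | tuple[float, ...] = (0.03, 0.98),
                            criteria: dict[float, float] | None = None,
                            edge_sd: float = 0.25,
                            grid: SpatialGrid | None = None) -> ConditionTable:
    """Predicted thresholds and size indices for each (size, contrast).

    ``criteria`` maps contrast -> criterion (a lower criterion is
    typically used for low-contrast stimuli); conditions without an
    entry use ``params.criterion``.  Size indices pair the smallest
    size with each larger one, per contrast.
    """
    from .psychometrics import size_index

    sizes = sorted(float(s) for s in sizes)
    contrasts = [float(c) for c in contrasts]
    criteria = dict(criteria or {})
    if grid is None:
        grid = SpatialGrid.for_stimuli(max(sizes), params)

    # Peaks are computed with response_gain stripped and the gain
    # reapplied to the scalar peak (exact: rounding is monotone, so the
    # field max commutes with positive scaling).  Size indices are then
    # taken from the gain-free peaks: SI = log10(t_s) - log10(t_l) =
    # log10(peak_l) - log10(peak_s), so criterion and response gain
    # cancel analytically and the invariance holds to the bit.
    bare = params.with_(response_gain=1.0)
    rows, raw_peaks = [], {}
    for contrast in contrasts:
        criterion = criteria.get(contrast, params.criterion)
        for diameter in sizes:
            stim = StimulusSpec(contrast=contrast, diameter=diameter,
                                edge_sd=edge_sd)
            peak0 = readout_peak(normalized_response(stim, grid, bare))
            raw_peaks[(contrast, diameter)] = peak0
            peak = params.response_gain * peak0
            rows.append({
                "contrast": contrast,
                "diameter_deg": diameter,
                "peak_response": peak,
                "predicted_threshold_ms": predict_threshold(peak, criterion),
            })
    thresholds = pd.DataFrame(rows)

    si_rows = []
    labels = _size_labels(sizes)
    smallest = sizes[0]
    for contrast in contrasts:
        for larger in sizes[1:]:
            # threshold is inversely proportional to the peak, so the
            # larger size's peak plays the "smaller threshold" role
            si = size_index(raw_peaks[(contrast, larger)],
                            raw_peaks[(contrast, smallest)])
            si_rows.append({
                "contrast": contrast,
                "pair": f"{labels[smallest]}-{labels[larger]}",
                "smaller_deg": smallest,
                "larger_deg": larger,
                "si": si.value,
            })
    return ConditionTable(thresholds=thresholds,
                          size_indices=pd.DataFrame(si_rows))


def _size_labels(sizes: list[float]) -> dict[float, str]:
    names = ["s", "m", "b"]
    if len(sizes) <= 3:
        return {s: names[i] for i, s in enumerate(sorted(sizes))}
    return {s: f"d{s:g}" for s in sizes}
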