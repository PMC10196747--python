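"""Single-vessel velocimetry from cardiac-gated phase-contrast MRI.

Converts a paired magnitude/phase image series (rows x cols x cardiac
phases) into one velocity waveform and its pulsatility measures:

* phase -> velocity scaling by the velocity-encoding limit (VENC),
* noise-floor masking against a static-tissue region,
* magnitude-based vessel segmentation (connected components),
* temporal aliasing (phase-wrap) correction,
* peak-voxel selection by highest time-averaged velocity,
* Gosling's pulsatility index PI = (v_max - v_min) / v_mean and the
  large-to-small-artery damping factor DF = PI_MCA / PI_LSA.

Phase convention: radians in (-pi, pi], velocity = venc * phase / pi,
positive for through-plane flow toward the reader.  Coordinates are
0-based (row, col); ties break on the smallest row-major linear index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import ndimage

__all__ = [
    "VelocitySeries",
    "VesselMask",
    "WaveformMeasures",
    "DampingResult",
    "phase_to_velocity",
    "estimate_noise_floor",
    "apply_noise_mask",
    "segment_vessel",
    "correct_aliasing",
    "select_peak_voxel",
    "waveform_measures",
    "damping_factor",
    "extract_waveform",
    "load_series",
]

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class VelocitySeries:
    """Cardiac-gated magnitude/phase stacks with acquisition metadata.

    magnitude : (rows, cols, phases) non-negative intensities
    phase     : (rows, cols, phases) radians in (-pi, pi]
    venc      : velocity-encoding limit in cm/s
    temporal_resolution : ms per cardiac phase
    vessel_seed : optional (row, col) hint for segmentation
    excluded  : boolean (rows, cols) map of voxels below the noise floor
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc: float
    temporal_resolution: float = 0.0
    vessel_seed: tuple[int, int] | None = None
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if self.magnitude.ndim != 3 or self.magnitude.shape[2] < 2:
            raise ValueError("series must be rows x cols x phases with >= 2 phases")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if np.any(self.phase > np.pi) or np.any(self.phase <= -np.pi):
            raise ValueError("phase values must lie in (-pi, pi]")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[2]

    def mean_magnitude(self) -> np.ndarray:
        """Time-averaged magnitude image."""
        return self.magnitude.mean(axis=2)

    def velocity(self) -> np.ndarray:
        """Per-voxel velocity stack (cm/s), no aliasing correction."""
        return phase_to_velocity(self.phase, self.venc)


@dataclass
class VesselMask:
    """Single 4-connected component of supra-threshold voxels."""

    mask: np.ndarray
    seed: tuple[int, int]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("vessel mask is empty")
        n_comp = ndimage.label(self.mask, structure=_FOUR_CONNECTED)[1]
        if n_comp != 1:
            raise ValueError("vessel mask must be one 4-connected component")

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class WaveformMeasures:
    """Velocity extrema, mean, and Gosling PI for one vessel."""

    v_min: float
    v_max: float
    v_mean: float
    pi: float
    peak_voxel: tuple[int, int] | None
    waveform: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class DampingResult:
    """Pulse damping between a feeding and a perforating artery."""

    pi_mca: float
    pi_lsa: float
    df: float


def phase_to_velocity(phase_value, venc: float):
    """Map phase (radians) to velocity (cm/s): v = venc * phase / pi.

    Linear and odd in phase; full scale (phase = pi) maps to +venc.
    """
    if venc <= 0:
        raise ValueError("venc must be positive")
    return venc * np.asarray(phase_value, dtype=float) / np.pi


def estimate_noise_floor(
    magnitude: np.ndarray, static_roi: np.ndarray, k: float = 0.0
) -> float:
    """Noise threshold from a static-tissue region.

    Returns mean time-averaged magnitude over the ROI plus ``k`` standard
    deviations (default k=0: the plain mean noise level).

    Parameters
    ----------
    magnitude : (rows, cols, phases) stack or (rows, cols) time average.
    static_roi : boolean map or sequence of (row, col) voxels, disjoint
        from the vessel.
    """
    mag = np.asarray(magnitude, dtype=float)
    if mag.ndim == 3:
        mag = mag.mean(axis=2)
    roi = _as_roi_mask(static_roi, mag.shape)
    vals = mag[roi]
    if vals.size == 0:
        raise ValueError("static ROI is empty")
    return float(vals.mean() + k * vals.std(ddof=0))


def _as_roi_mask(roi, shape) -> np.ndarray:
    roi = np.asarray(roi)
    if roi.dtype == bool and roi.shape == tuple(shape):
        return roi
    roi = np.atleast_2d(roi)
    if roi.shape[1] != 2:
        raise ValueError("ROI must be a boolean map or (n, 2) voxel list")
    mask = np.zeros(shape, dtype=bool)
    mask[roi[:, 0].astype(int), roi[:, 1].astype(int)] = True
    return mask


def apply_noise_mask(series: VelocitySeries, threshold: float) -> VelocitySeries:
    """Flag voxels whose time-averaged magnitude is <= threshold as excluded.

    Excluded voxels keep their data (geometry unchanged) but their phase is
    no longer interpreted as velocity downstream.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    excluded = series.mean_magnitude() <= threshold
    return VelocitySeries(
        magnitude=series.magnitude,
        phase=series.phase,
        venc=series.venc,
        temporal_resolution=series.temporal_resolution,
        vessel_seed=series.vessel_seed,
        excluded=excluded,
    )


def segment_vessel(
    series: VelocitySeries,
    threshold: float,
    seed_hint: tuple[int, int] | None = None,
) -> VesselMask:
    """Segment the vessel on the time-averaged magnitude image.

    Binarizes at the noise threshold, labels 4-connected components, and
    returns the component containing ``seed_hint``; absent a hint, the
    component with the highest mean time-averaged magnitude.
    """
    mean_mag = series.mean_magnitude()
    supra = mean_mag > threshold
    if series.excluded is not None:
        supra &= ~series.excluded
    if not supra.any():
        raise ValueError("no voxels survive the noise threshold")
    labels, n_comp = ndimage.label(supra, structure=_FOUR_CONNECTED)
    if seed_hint is None and series.vessel_seed is not None:
        seed_hint = series.vessel_seed
    if seed_hint is not None:
        r, c = int(seed_hint[0]), int(seed_hint[1])
        lab = labels[r, c]
        if lab == 0:
            raise ValueError("seed hint lies in an excluded voxel")
    else:
        comp_means = ndimage.mean(mean_mag, labels, index=np.arange(1, n_comp + 1))
        lab = int(np.argmax(comp_means)) + 1
        rr, cc = np.nonzero(labels == lab)
        r, c = int(rr[0]), int(cc[0])
    return VesselMask(mask=labels == lab, seed=(r, c))


def correct_aliasing(waveform: np.ndarray, venc: float) -> np.ndarray:
    """Temporal unwrapping of a velocity waveform around the VENC limit.

    Anchors at the cardiac phase whose value is nearest the waveform median
    and walks outward in both directions; whenever a step between
    consecutive phases exceeds ``venc`` in magnitude, the later sample is
    shifted by the multiple of 2*venc that minimizes the step.  Identity on
    already-unwrapped input; output differs from input only by per-sample
    multiples of 2*venc.  Assumes at most a single wrap.
    """
    v = np.asarray(waveform, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("waveform must be 1-D with length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("waveform must be finite")
    if venc <= 0:
        raise ValueError("venc must be positive")
    out = v.copy()
    anchor = int(np.argmin(np.abs(v - np.median(v))))
    span = 2.0 * venc
    for idx in range(anchor + 1, v.size):
        step = out[idx] - out[idx - 1]
        if abs(step) > venc:
            out[idx] -= span * np.round(step / span)
    for idx in range(anchor - 1, -1, -1):
        step = out[idx] - out[idx + 1]
        if abs(step) > venc:
            out[idx] -= span * np.round(step / span)
    return out


def select_peak_voxel(
    velocity: np.ndarray, mask: np.ndarray, venc: float | None = None
) -> tuple[int, int]:
    """In-mask voxel with the highest time-averaged (signed) velocity.

    ``velocity`` is a (rows, cols, phases) stack; each in-mask voxel's
    waveform is aliasing-corrected (when ``venc`` is given) before time
    averaging.  Ties break on the smallest row-major linear index.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(mask)
    best, best_mean = None, -np.inf
    for r, c in zip(rows, cols):  # nonzero already yields row-major order
        wf = velocity[r, c, :]
        if venc is not None:
            wf = correct_aliasing(wf, venc)
        m = wf.mean()
        if m > best_mean:
            best, best_mean = (int(r), int(c)), m
    return best


def waveform_measures(
    waveform: np.ndarray, peak_voxel: tuple[int, int] | None = None
) -> WaveformMeasures:
    """Gosling pulsatility measures of one velocity waveform.

    v_max/v_min/v_mean are the max, min, and unweighted arithmetic mean
    over acquired cardiac phases; PI = (v_max - v_min) / v_mean.

    Raises
    ------
    ValueError
        If v_mean <= 0, which signals a non-physiological or mis-segmented
        waveform for which the PI is undefined.
    """
    wf = np.asarray(waveform, dtype=float)
    if wf.ndim != 1 or wf.size < 2:
        raise ValueError("waveform must be 1-D with length >= 2")
    v_min, v_max, v_mean = float(wf.min()), float(wf.max()), float(wf.mean())
    if v_mean <= 0:
        raise ValueError("non-positive mean velocity: waveform is not interpretable")
    return WaveformMeasures(
        v_min=v_min,
        v_max=v_max,
        v_mean=v_mean,
        pi=(v_max - v_min) / v_mean,
        peak_voxel=peak_voxel,
        waveform=wf,
    )


def damping_factor(pi_mca: float, pi_lsa: float) -> DampingResult:
    """DF = PI_MCA / PI_LSA; lower values mean less damping of the pulse
    between the feeding and the perforating artery (stiffer trajectory)."""
    if pi_mca <= 0 or pi_lsa <= 0:
        raise ValueError("pulsatility indices must be positive")
    return DampingResult(pi_mca=pi_mca, pi_lsa=pi_lsa, df=pi_mca / pi_lsa)


def extract_waveform(
    series: VelocitySeries,
    static_roi: np.ndarray,
    seed_hint: tuple[int, int] | None = None,
    k: float = 0.0,
    subtract_background_phase: bool = False,
) -> WaveformMeasures:
    """Full single-vessel pipeline: noise floor -> mask -> segment ->
    aliasing-correct -> peak voxel -> pulsatility measures.

    ``subtract_background_phase`` optionally removes the mean static-ROI
    phase per cardiac phase (residual eddy-current offset) before decoding;
    off by default.
    """
    threshold = estimate_noise_floor(series.magnitude, static_roi, k=k)
    phase = series.phase
    if subtract_background_phase:
        roi = _as_roi_mask(static_roi, series.magnitude.shape[:2])
        offset = series.phase[roi, :].mean(axis=0)
        phase = np.angle(np.exp(1j * (series.phase - offset[None, None, :])))
        phase = np.where(phase == -np.pi, np.pi, phase)
        series = VelocitySeries(
            magnitude=series.magnitude,
            phase=phase,
            venc=series.venc,
            temporal_resolution=series.temporal_resolution,
            vessel_seed=series.vessel_seed,
        )
    masked = apply_noise_mask(series, threshold)
    vessel = segment_vessel(masked, threshold, seed_hint=seed_hint)
    velocity = masked.velocity()
    peak = select_peak_voxel(velocity, vessel.mask, venc=series.venc)
    wf = correct_aliasing(velocity[peak[0], peak[1], :], series.venc)
    return waveform_measures(wf, peak_voxel=peak)


def load_series(
    mag_path: str | Path, phase_path: str | Path, sidecar_path: str | Path | None = None
) -> VelocitySeries:
    """Read paired NIfTI magnitude/phase stacks plus an optional JSON
    sidecar carrying ``venc_cm_s`` and ``temporal_resolution_ms``."""
    mag = np.asanyarray(nib.load(str(mag_path)).dataobj, dtype=float)
    pha = np.asanyarray(nib.load(str(phase_path)).dataobj, dtype=float)
    venc, tres, seed = 0.0, 0.0, None
    if sidecar_path is not None:
        meta = json.loads(Path(sidecar_path).read_text())
        venc = float(meta["venc_cm_s"])
        tres = float(meta.get("temporal_resolution_ms", 0.0))
        if "vessel_seed" in meta:
            seed = tuple(int(x) for x in meta["vessel_seed"])
    return VelocitySeries(
        magnitude=mag, phase=pha, venc=venc, temporal_resolution=tres, vessel_seed=seed
    )
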