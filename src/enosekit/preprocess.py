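"""Raw resistance series -> normalized M x N response matrix.

The chain is: Savitzky-Golay smoothing of each sensor's time series, then the
fractional resistance change dR/R = (R - R0)/R0 between the clean-air
baseline and the steady state under analyte exposure, then per-sensor
autoscaling (z-scoring) across measurements.  dR/R suppresses multiplicative
drift; autoscaling equalizes sensor weights so a few high-amplitude sensors
do not dominate the subsequent variance decomposition.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .containers import PreprocessingError, ResponseMatrix, SensorArrayRecording

__all__ = [
    "savitzky_golay_smooth",
    "smooth_recording",
    "percent_resistance",
    "fractional_response",
    "autoscale",
    "build_response_matrix",
]

#: Smoothing defaults: local quadratic fit over a 101-sample window,
#: i.e. ~100 s of context at the device's 1 Hz acquisition rate.
DEFAULT_SG_ORDER = 2
DEFAULT_SG_FRAME = 101


def savitzky_golay_smooth(
    signal: np.ndarray,
    poly_order: int = DEFAULT_SG_ORDER,
    frame_size: int = DEFAULT_SG_FRAME,
) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing along the time axis.

    Each interior sample is replaced by the centre value of a degree-
    ``poly_order`` polynomial fitted by least squares to the surrounding
    ``frame_size`` samples; polynomials up to that degree pass through
    unchanged, so peak height and shape are preserved (unlike a moving
    average).  Edges are filled by evaluating a polynomial fitted to the
    terminal window, so output length equals input length.

    ``signal`` may be 1-D (one sensor) or 2-D ``(T, N)`` (smoothed
    column-wise).
    """
    signal = np.asarray(signal, dtype=float)
    if frame_size % 2 == 0:
        raise PreprocessingError(f"frame_size must be odd, got {frame_size}")
    if poly_order >= frame_size:
        raise PreprocessingError(
            f"poly_order ({poly_order}) must be < frame_size ({frame_size})"
        )
    if signal.shape[0] < frame_size:
        raise PreprocessingError(
            f"signal length {signal.shape[0]} shorter than frame_size {frame_size}"
        )
    return savgol_filter(signal, frame_size, poly_order, axis=0, mode="interp")


def smooth_recording(
    recording: SensorArrayRecording,
    poly_order: int = DEFAULT_SG_ORDER,
    frame_size: int = DEFAULT_SG_FRAME,
) -> SensorArrayRecording:
    """Return a copy of ``recording`` with every sensor trace smoothed."""
    smoothed = savitzky_golay_smooth(recording.resistance, poly_order, frame_size)
    # SG fits can marginally undershoot near sharp transients; resistances
    # must stay positive for the ratio formulas downstream.
    smoothed = np.maximum(smoothed, np.finfo(float).tiny)
    return SensorArrayRecording(
        resistance=smoothed,
        sample_interval=recording.sample_interval,
        stimulus_onset=recording.stimulus_onset,
        stimulus_end=recording.stimulus_end,
        label=recording.label,
        material_map=recording.material_map,
    )


def _window_slice(window: tuple[int, int] | None, default: tuple[int, int], T: int,
                  name: str) -> slice:
    lo, hi = window if window is not None else default
    if not (0 <= lo < hi <= T):
        raise PreprocessingError(
            f"{name} window [{lo}, {hi}) invalid for {T} samples"
        )
    return slice(lo, hi)


def percent_resistance(
    recording: SensorArrayRecording,
    baseline_window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Percentage resistance trace 100 * (Rs - R0) / Rs for every sensor.

    ``R0`` is the per-sensor mean over the pre-stimulus (clean air) window;
    ``Rs`` is the instantaneous reading.  This is the live display quantity
    of the acquisition software; note the denominator is the current reading,
    not the baseline.
    """
    T = recording.n_samples
    sl = _window_slice(baseline_window, (0, recording.stimulus_onset), T, "baseline")
    if sl.stop - sl.start < 1:
        raise PreprocessingError("baseline window is empty")
    R = recording.resistance
    if np.any(R == 0):
        idx = int(np.argwhere(R == 0)[0, 1])
        raise PreprocessingError(f"zero resistance reading at sensor {idx}")
    R0 = R[sl].mean(axis=0)
    return 100.0 * (R - R0[None, :]) / R


def fractional_response(
    recording: SensorArrayRecording,
    baseline_window: tuple[int, int] | None = None,
    steady_window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-sensor fractional response dR/R = (R - R0) / R0.

    ``R0`` is the mean resistance over the baseline window (default: the full
    pre-stimulus interval) and ``R`` the mean over the steady-state window
    (default: the last 100 samples of the stimulus phase, where first-order
    sensor kinetics have plateaued).  Window means rather than single samples
    are used for noise robustness; pass length-1 windows for single-sample
    semantics.  Returns a length-N vector.
    """
    T = recording.n_samples
    b = _window_slice(baseline_window, (0, recording.stimulus_onset), T, "baseline")
    default_steady = (max(recording.stimulus_end - 100, recording.stimulus_onset),
                      recording.stimulus_end)
    s = _window_slice(steady_window, default_steady, T, "steady")
    if not (b.stop <= s.start or s.stop <= b.start):
        raise PreprocessingError(
            f"baseline [{b.start},{b.stop}) and steady [{s.start},{s.stop}) overlap"
        )
    R0 = recording.resistance[b].mean(axis=0)
    R = recording.resistance[s].mean(axis=0)
    if np.any(R0 == 0):
        idx = int(np.argwhere(R0 == 0)[0])
        raise PreprocessingError(f"zero baseline resistance at sensor {idx}")
    return (R - R0) / R0


def autoscale(matrix: np.ndarray, labels: list[str] | None = None) -> ResponseMatrix:
    """Column-wise z-score an ``M x N`` response matrix.

    Uses the population convention (divide by M) so every non-degenerate
    column has mean 0 and variance exactly 1.  Zero-variance columns (sensors
    that responded identically in every measurement, typically dead ones) are
    set to 0 and flagged rather than dropped.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise PreprocessingError(
            f"autoscaling needs an M x N matrix with M >= 2, got shape {matrix.shape}"
        )
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0)  # population (ddof=0)
    dead = std == 0.0
    safe = np.where(dead, 1.0, std)
    values = (matrix - mean) / safe
    values[:, dead] = 0.0
    return ResponseMatrix(
        values=values,
        labels=list(labels) if labels is not None else [],
        mean=mean,
        std=std,
        dead_mask=dead,
    )


def build_response_matrix(
    recordings: list[SensorArrayRecording],
    sg_order: int = DEFAULT_SG_ORDER,
    sg_frame: int = DEFAULT_SG_FRAME,
    baseline_window: tuple[int, int] | None = None,
    steady_window: tuple[int, int] | None = None,
    scale: bool = True,
) -> ResponseMatrix | np.ndarray:
    """Smooth + dR/R every recording and stack into an M x N matrix.

    With ``scale=True`` (default) the stacked matrix is autoscaled and a
    :class:`ResponseMatrix` returned; with ``scale=False`` the raw stacked
    responses come back as a plain array (useful when scaling statistics must
    be fitted on a training subset only, as in cross-validation).
    """
    if not recordings:
        raise PreprocessingError("no recordings supplied")
    n_sensors = {r.n_sensors for r in recordings}
    if len(n_sensors) != 1:
        raise PreprocessingError(f"inconsistent sensor counts: {sorted(n_sensors)}")
    rows = []
    for rec in recordings:
        sm = smooth_recording(rec, sg_order, sg_frame)
        rows.append(fractional_response(sm, baseline_window, steady_window))
    raw = np.vstack(rows)
    if not scale:
        return raw
    return autoscale(raw, labels=[r.label for r in recordings])
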