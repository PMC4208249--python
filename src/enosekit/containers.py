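"""Core in-memory containers for sensor-array data.

A measurement with a large conducting-polymer chemiresistor array produces a
``T x N`` grid of resistance readings (T time samples at a fixed interval,
N sensors).  A dataset is a stack of M such measurements, each tagged with an
odour-composition label.  After preprocessing, the dataset collapses to an
``M x N`` matrix of fractional responses — the object every downstream stage
(PCA, LDA, SVM) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PreprocessingError(ValueError):
    """Invalid parameters or degenerate data in the preprocessing stage."""


@dataclass
class SensorArrayRecording:
    """One measurement: resistance time series for every sensor in the array.

    Parameters
    ----------
    resistance
        ``(T, N)`` array of resistance readings in ohms; strictly positive.
    sample_interval
        Sampling interval in seconds (the reference device reads the whole
        array at 1 s intervals).
    stimulus_onset, stimulus_end
        Sample indices bounding the analyte-delivery phase.  Before
        ``stimulus_onset`` the sensors see clean air (baseline); after
        ``stimulus_end`` clean air is restored and the sensors recover.
    label
        Odour-composition tag, e.g. ``"B75E25"`` for a 75% butanone / 25%
        ethanol binary mixture.
    material_map
        ``(N,)`` integer array mapping each sensor to its polymer class.
    """

    resistance: np.ndarray
    sample_interval: float = 1.0
    stimulus_onset: int = 100
    stimulus_end: int = 650
    label: str = ""
    material_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.resistance.ndim != 2:
            raise PreprocessingError(
                f"resistance must be a T x N grid, got shape {self.resistance.shape}"
            )
        if not np.all(self.resistance > 0):
            bad = np.argwhere(self.resistance <= 0)[0]
            raise PreprocessingError(
                f"resistance must be strictly positive; first violation at "
                f"sample {bad[0]}, sensor {bad[1]}"
            )
        T = self.resistance.shape[0]
        if not (0 <= self.stimulus_onset < self.stimulus_end <= T):
            raise PreprocessingError(
                f"need 0 <= stimulus_onset < stimulus_end <= T, got "
                f"onset={self.stimulus_onset}, end={self.stimulus_end}, T={T}"
            )
        if self.material_map is not None:
            self.material_map = np.asarray(self.material_map)
            if self.material_map.shape != (self.n_sensors,):
                raise PreprocessingError(
                    f"material_map must cover all {self.n_sensors} sensors, "
                    f"got shape {self.material_map.shape}"
                )

    @property
    def n_samples(self) -> int:
        return self.resistance.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.resistance.shape[1]


@dataclass
class ResponseMatrix:
    """``M x N`` matrix of smoothed, baseline-normalized, autoscaled responses.

    ``values`` holds per-sensor z-scores across the M measurements so each
    sensor is equally weighted regardless of its raw sensitivity.  Sensors
    whose response never varies across measurements carry no information and
    cannot be z-scored; their columns are zeroed and flagged in ``dead_mask``,
    preserving the N-dimensional layout (and hence the sensor-to-material
    mapping) instead of dropping columns.

    ``mean`` and ``std`` are the autoscaling statistics, retained so the same
    affine map can be applied to held-out measurements (e.g. test folds during
    cross-validation).
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    dead_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessingError(
                f"values must be M x N, got shape {self.values.shape}"
            )
        if self.labels and len(self.labels) != self.values.shape[0]:
            raise PreprocessingError(
                f"{len(self.labels)} labels for {self.values.shape[0]} rows"
            )

    @property
    def n_measurements(self) -> int:
        return self.values.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]

    def apply(self, raw: np.ndarray) -> np.ndarray:
        """Autoscale new raw response rows with the stored statistics.

        Masked (zero-variance) sensors map to 0, mirroring the training
        matrix.  ``raw`` may be a single length-N vector or a ``(m, N)``
        block.
        """
        if self.mean is None or self.std is None or self.dead_mask is None:
            raise PreprocessingError("no autoscaling statistics stored")
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if raw.shape[1] != self.n_sensors:
            raise PreprocessingError(
                f"expected {self.n_sensors} sensors, got {raw.shape[1]}"
            )
        safe_std = np.where(self.dead_mask, 1.0, self.std)
        out = (raw - self.mean) / safe_std
        out[:, self.dead_mask] = 0.0
        return out
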