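"""Synthetic conducting-polymer sensor-array simulator.

Stands in for the physical large-scale chemiresistor array so the whole
pipeline can be exercised at desk scale.  The model is deliberately
structural rather than chemical: what matters downstream is that the data
share the real device's shape and pathologies — M measurements far fewer
than N sensors, material-dependent and analyte-dependent sensitivities,
first-order response kinetics, a sizeable fraction of non-responding
("dead") sensors, multiplicative read noise, and measurement-to-measurement
concentration variability.

Per sensor n of material m exposed to a mixture, the target fractional
amplitude is a_n = sum_analytes s(m, analyte) * concentration_ppm; the
resistance trace is

    R_n(t) = R0_n * (1 + a_n * g(t)) * (1 + noise)

with g(t) = 0 before stimulus onset, 1 - exp(-(t - t_on)/tau_rise) during
exposure, and exponential recovery with tau_rec after the clean-air purge
starts.  Sensitivities s are drawn log-uniformly once per configuration and
are a declared modelling assumption, not an estimate of any real polymer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .containers import SensorArrayRecording

__all__ = [
    "Mixture",
    "SimulationConfig",
    "simulate_recording",
    "simulate_dataset",
    "dataset1_config",
    "dataset2_config",
    "DATASET1_DESIGN",
    "DATASET2_DESIGN",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Mixture:
    """A delivered odour: per-analyte proportions and ppm concentrations."""

    label: str
    proportions: dict
    concentrations_ppm: dict

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"mixture {self.label!r}: proportions sum to {total}, not 1"
            )


#: Binary butanone/ethanol mixture series: both analytes' concentrations
#: vary with the mixing ratio (8/8/9/8/8 measurements per composition).
DATASET1_MIXTURES = (
    Mixture("B100", {"butanone": 1.0}, {"butanone": 19520.0}),
    Mixture("B75E25", {"butanone": 0.75, "ethanol": 0.25},
            {"butanone": 14656.0, "ethanol": 3433.0}),
    Mixture("B50E50", {"butanone": 0.50, "ethanol": 0.50},
            {"butanone": 9760.0, "ethanol": 6867.0}),
    Mixture("B25E75", {"butanone": 0.25, "ethanol": 0.75},
            {"butanone": 4880.0, "ethanol": 10300.0}),
    Mixture("E100", {"ethanol": 1.0}, {"ethanol": 13734.0}),
)
DATASET1_DESIGN = ((0, 8), (1, 8), (2, 9), (3, 8), (4, 8))

#: Butanone steps against a constant ethanol background — the harder task,
#: since only one analyte's concentration carries class information.
DATASET2_MIXTURES = (
    Mixture("E100", {"ethanol": 1.0}, {"ethanol": 13734.0}),
    Mixture("B20E80", {"butanone": 0.20, "ethanol": 0.80},
            {"butanone": 4880.0, "ethanol": 13734.0}),
    Mixture("B33E67", {"butanone": 0.33, "ethanol": 0.67},
            {"butanone": 9760.0, "ethanol": 13734.0}),
    Mixture("B43E57", {"butanone": 0.43, "ethanol": 0.57},
            {"butanone": 14656.0, "ethanol": 13734.0}),
    Mixture("B50E50", {"butanone": 0.50, "ethanol": 0.50},
            {"butanone": 19520.0, "ethanol": 13734.0}),
)
DATASET2_DESIGN = ((0, 8), (1, 3), (2, 3), (3, 3), (4, 3))


@dataclass
class SimulationConfig:
    """Array geometry, response model and noise levels for the simulator.

    Defaults are desk-scale: 1024 sensors over 24 responsive polymer
    classes (the full 16384-sensor geometry is supported, just slower).
    Sensitivities span 1e-6..3e-5 fractional dR/R per ppm, so at the
    ppm levels of the mixture tables plateau responses fall between about
    1% and 60% — the order of magnitude conducting polymers show for
    alcohols and ketones.  Timing mirrors the reference protocol: 1 Hz
    sampling, clean-air baseline up to t = 100 s, analyte until t = 650 s,
    recovery afterwards.
    """

    n_sensors: int = 1024
    n_materials: int = 24
    analytes: tuple = ("butanone", "ethanol")
    mixtures: tuple = DATASET1_MIXTURES
    sensitivity_range: tuple = (1e-6, 3e-5)
    tau_rise: float = 60.0
    tau_recovery: float = 120.0
    n_samples: int = 750
    stimulus_onset: int = 100
    stimulus_end: int = 650
    sample_interval: float = 1.0
    noise_sd: float = 0.002
    dead_fraction: float = 0.3
    baseline_range: tuple = (1e4, 1e6)
    concentration_jitter: float = 0.05
    seed: int = 0
    _sensitivities: np.ndarray = field(default=None, repr=False, compare=False)
    _material_map: np.ndarray = field(default=None, repr=False, compare=False)
    _dead: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dead_fraction < 1.0:
            raise SimulationError("dead_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.tau_rise <= 0 or self.tau_recovery <= 0:
            raise SimulationError("kinetic time constants must be > 0")
        # Material layout, sensitivities and the non-responding sensor set
        # are fixed once per configuration (deposition pattern, polymer
        # chemistry and deposition defects do not change between
        # measurements); all derive deterministically from `seed`.
        rng = np.random.default_rng([int(self.seed), 2**20])
        lo, hi = self.sensitivity_range
        self._sensitivities = np.exp(
            rng.uniform(np.log(lo), np.log(hi),
                        size=(self.n_materials, len(self.analytes)))
        )
        per = int(np.ceil(self.n_sensors / self.n_materials))
        self._material_map = np.repeat(
            np.arange(1, self.n_materials + 1), per
        )[: self.n_sensors]
        self._dead = rng.random(self.n_sensors) < self.dead_fraction

    @property
    def material_map(self) -> np.ndarray:
        return self._material_map

    def sensitivity(self, material: int, analyte: str) -> float:
        return float(
            self._sensitivities[material - 1, self.analytes.index(analyte)]
        )

    def to_json(self) -> dict:
        d = {
            k: v for k, v in self.__dict__.items() if not k.startswith("_")
        }
        d["mixtures"] = [
            {"label": m.label, "proportions": m.proportions,
             "concentrations_ppm": m.concentrations_ppm}
            for m in self.mixtures
        ]
        for key in ("analytes", "sensitivity_range", "baseline_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_json(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["mixtures"] = tuple(
            Mixture(m["label"], m["proportions"], m["concentrations_ppm"])
            for m in d["mixtures"]
        )
        for key in ("analytes", "sensitivity_range", "baseline_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(self.to_json(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _kinetic_profile(config: SimulationConfig) -> np.ndarray:
    t = np.arange(config.n_samples) * config.sample_interval
    t_on = config.stimulus_onset * config.sample_interval
    t_off = config.stimulus_end * config.sample_interval
    g = np.zeros(config.n_samples)
    rising = (t >= t_on) & (t < t_off)
    g[rising] = 1.0 - np.exp(-(t[rising] - t_on) / config.tau_rise)
    g_end = 1.0 - np.exp(-(t_off - t_on) / config.tau_rise)
    after = t >= t_off
    g[after] = g_end * np.exp(-(t[after] - t_off) / config.tau_recovery)
    return g


def simulate_recording(
    config: SimulationConfig, mixture_index: int, seed_offset: int = 0
) -> SensorArrayRecording:
    """Simulate one measurement of the given mixture.

    Reproducible: the random stream is a pure function of
    ``(config.seed, seed_offset)``.  Baselines, the dead-sensor draw, the
    concentration jitter and the read noise all come from that stream;
    material layout and sensitivities are fixed by the configuration.
    """
    if not 0 <= mixture_index < len(config.mixtures):
        raise SimulationError(
            f"mixture index {mixture_index} out of range "
            f"(have {len(config.mixtures)})"
        )
    mixture = config.mixtures[mixture_index]
    rng = np.random.default_rng([int(config.seed), int(seed_offset)])
    N = config.n_sensors

    lo, hi = config.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=N))
    dead = config._dead

    # Per-measurement delivery variability: each analyte's concentration
    # jitters around its nominal value.
    amplitudes = np.zeros(N)
    mat_idx = config.material_map - 1
    for analyte, ppm in mixture.concentrations_ppm.items():
        a_col = config.analytes.index(analyte)
        jitter = 1.0 + config.concentration_jitter * rng.standard_normal()
        ppm_actual = max(ppm * jitter, 0.0)
        amplitudes += config._sensitivities[mat_idx, a_col] * ppm_actual
    amplitudes[dead] = 0.0

    g = _kinetic_profile(config)
    resistance = baselines[None, :] * (1.0 + np.outer(g, amplitudes))
    if config.noise_sd > 0:
        noise = rng.standard_normal((config.n_samples, N))
        resistance = resistance * (1.0 + config.noise_sd * noise)
        resistance = np.maximum(resistance, 1e-12)

    return SensorArrayRecording(
        resistance=resistance,
        sample_interval=config.sample_interval,
        stimulus_onset=config.stimulus_onset,
        stimulus_end=config.stimulus_end,
        label=mixture.label,
        material_map=config.material_map,
    )


def simulate_dataset(
    config: SimulationConfig,
    design=DATASET1_DESIGN,
    seed: int | None = None,
) -> tuple[list[SensorArrayRecording], list[str]]:
    """Simulate a full measurement campaign in memory.

    ``design`` is a sequence of ``(mixture_index, n_measurements)`` pairs;
    measurement j of the campaign uses ``seed_offset = j``.  Returns the
    recordings and their labels.  (Use :func:`enosekit.io.write_dataset` to
    persist them as CSV files plus a manifest.)
    """
    if seed is not None and seed != config.seed:
        cfg_dict = config.to_json()
        cfg_dict["seed"] = int(seed)
        config = SimulationConfig.from_json(cfg_dict)
    recordings: list[SensorArrayRecording] = []
    labels: list[str] = []
    j = 0
    for mixture_index, n_meas in design:
        for _ in range(int(n_meas)):
            rec = simulate_recording(config, mixture_index, seed_offset=j)
            recordings.append(rec)
            labels.append(rec.label)
            j += 1
    return recordings, labels


def dataset1_config(**overrides) -> SimulationConfig:
    """Configuration for the varying-ratio binary-mixture campaign."""
    return SimulationConfig(mixtures=DATASET1_MIXTURES, **overrides)


def dataset2_config(**overrides) -> SimulationConfig:
    """Configuration for the constant-background butanone-step campaign."""
    return SimulationConfig(mixtures=DATASET2_MIXTURES, **overrides)
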