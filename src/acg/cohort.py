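"""Synthetic acoustocerebrography (ACG) cohorts.

Acoustocerebrography probes the brain with transcranial ultrasound at
several carrier frequencies simultaneously and records, per frequency, the
relative time of flight (TOF, microseconds) and the attenuation (ATT, dB)
of the transmitted component.  Because tissue is dispersive, the channels
of a healthy brain move almost in lockstep; pathology desynchronises them.

No clinical recordings are distributed with this package, so this module
simulates a two-arm ICU cohort (septic-shock group SG vs. postoperative
control group CG) in which a latent per-patient severity in [0, 1] drives

* the degree of frequency-channel desynchronisation: every channel is an
  affine image of one shared smooth latent series, plus an independent
  per-channel component whose amplitude grows with severity, and
* the clinical surface: SOFA, ICDSC, CAM-ICU and four laboratory values
  (lactate, procalcitonin, creatinine, bilirubin) are noisy monotone
  functions of the same severity.

SG patients carry sessions on days 1, 3, 7 and 14; CG patients on days 1
and 3; every session is partitioned into 10 single measurements, mirroring
the probe re-positioning protocol of the bedside device.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "FrequencyGrid",
    "MediumParams",
    "MeasurementSeries",
    "PatientRecord",
    "Cohort",
    "CohortConfig",
    "simulate_received_pulse",
    "generate_measurement",
    "generate_cohort",
]

SG = "SG"
CG = "CG"


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered ultrasound carrier frequencies in MHz (default 10 on [0.5, 2.5])."""

    frequencies: tuple[float, ...] = tuple(np.linspace(0.5, 2.5, 10).round(12))

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size < 2:
            raise ValueError("frequency grid needs at least 2 frequencies")
        if np.any(f <= 0) or not np.isfinite(f).all():
            raise ValueError("frequencies must be finite and positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", tuple(float(x) for x in f))

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


@dataclass(frozen=True)
class MediumParams:
    """Toy dispersive medium: linear speed dispersion, linear attenuation in f·d.

    Units: path_length mm, speed_base mm/µs, dispersion_slope (mm/µs)/MHz,
    attenuation_slope dB/(MHz·mm), noise SDs in µs and dB.
    """

    path_length: float = 150.0
    speed_base: float = 1.50
    dispersion_slope: float = 0.01
    attenuation_slope: float = 0.05
    noise_sd_tof: float = 0.01
    noise_sd_att: float = 0.1

    def __post_init__(self) -> None:
        if self.path_length <= 0 or self.speed_base <= 0:
            raise ValueError("path_length and speed_base must be positive")
        if self.noise_sd_tof < 0 or self.noise_sd_att < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_received_pulse(
    grid: FrequencyGrid, medium: MediumParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One transmitted multifrequency pulse: per-frequency (TOF µs, ATT dB).

    TOF_f = d / (c0 + c1·f) + N(0, σ_tof);  ATT_f = α·f·d + N(0, σ_att).
    The medium is rejected if the dispersion law yields a non-positive phase
    speed anywhere on the grid.
    """
    f = grid.array
    speed = medium.speed_base + medium.dispersion_slope * f
    if np.any(speed <= 0):
        raise ValueError("dispersion law gives non-positive speed on the grid")
    tof = medium.path_length / speed
    att = medium.attenuation_slope * f * medium.path_length
    if medium.noise_sd_tof > 0:
        tof = tof + rng.normal(0.0, medium.noise_sd_tof, size=f.size)
    if medium.noise_sd_att > 0:
        att = att + rng.normal(0.0, medium.noise_sd_att, size=f.size)
    return tof, att


@dataclass
class MeasurementSeries:
    """One single measurement: T×F TOF (µs) and T×F ATT (dB) series."""

    tof: np.ndarray
    att: np.ndarray
    signal_strength: float
    measurement_index: int

    def __post_init__(self) -> None:
        self.tof = np.asarray(self.tof, dtype=float)
        self.att = np.asarray(self.att, dtype=float)
        if self.tof.shape != self.att.shape:
            raise ValueError("tof and att shapes disagree")
        if self.tof.ndim != 2 or self.tof.shape[0] < 2:
            raise ValueError("need a T×F array with T >= 2")
        if not (np.isfinite(self.tof).all() and np.isfinite(self.att).all()):
            raise ValueError("measurement contains non-finite values")
        if not 0.0 <= self.signal_strength <= 100.0:
            raise ValueError("signal_strength must lie in [0, 100]")

    @property
    def t_samples(self) -> int:
        return self.tof.shape[0]

    @property
    def n_frequencies(self) -> int:
        return self.tof.shape[1]


@dataclass
class PatientRecord:
    """Clinical surface of one patient on one measured day, plus its session."""

    patient_id: str
    group: str
    day: int
    severity: float
    sofa: int
    icdsc: int
    cam_icu: bool
    lactate: float
    pct: float
    creatinine: float
    bilirubin: float
    sessions: list[MeasurementSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in (SG, CG):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == CG and (self.icdsc != 0 or self.cam_icu):
            raise ValueError("control records must have ICDSC 0 and CAM-ICU negative")


@dataclass
class Cohort:
    records: list[PatientRecord]
    frequency_grid: FrequencyGrid
    config_fingerprint: str

    def __iter__(self):
        return iter(self.records)

    def patient_days(self) -> list[tuple[str, int]]:
        return [(r.patient_id, r.day) for r in self.records]

    def subset(self, group: str | None = None, day: int | None = None) -> list[PatientRecord]:
        out = self.records
        if group is not None:
            out = [r for r in out if r.group == group]
        if day is not None:
            out = [r for r in out if r.day == day]
        return out


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings.  Defaults are the study conditions being emulated:

    10 septic + 10 control patients, SG sessions on days 1/3/7/14 and CG on
    days 1/3, 10 single measurements per session, 10 frequencies spanning
    0.5–2.5 MHz, recording quality centred at 80.9 % ± 14.6 %.
    """

    n_sg: int = 10
    n_cg: int = 10
    sg_days: tuple[int, ...] = (1, 3, 7, 14)
    cg_days: tuple[int, ...] = (1, 3)
    n_measurements: int = 10
    t_samples: int = 256
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    medium: MediumParams = field(default_factory=MediumParams)
    # channel-dynamics model
    tof_scale: float = 0.05     # µs fluctuation scale around the propagation baseline
    att_scale: float = 0.8      # dB fluctuation scale
    loading_spread: float = 0.25  # per-frequency spread of the shared-latent loadings
    noise_floor: float = 0.15   # per-channel independent amplitude at severity 0
    desync_gain: float = 1.0    # additional independent amplitude per unit severity
    smoothing: int = 16         # moving-average window making latent series smooth
    # severity and clinical-score links
    sg_severity_beta: tuple[float, float] = (5.0, 2.0)
    cg_severity_beta: tuple[float, float] = (1.2, 8.0)
    severity_day_sd: float = 0.05
    sofa_noise_sd: float = 1.0
    icdsc_noise_sd: float = 0.7
    signal_strength_mean: float = 80.9
    signal_strength_sd: float = 14.6
    min_signal_strength: float = 0.0  # quality filter, off by default
    cam_icu_cutoff: int = 4

    def __post_init__(self) -> None:
        if self.n_sg < 1 or self.n_cg < 1:
            raise ValueError("group sizes must be >= 1")
        if self.t_samples < 2:
            raise ValueError("need at least 2 time samples per measurement")
        if not set(self.sg_days) <= {1, 3, 7, 14} or not set(self.cg_days) <= {1, 3}:
            raise ValueError("measured days outside the study schedule")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid.frequencies)
        return json.dumps(d, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "CohortConfig":
        d = json.loads(text)
        d["grid"] = FrequencyGrid(tuple(d["grid"]))
        d["medium"] = MediumParams(**d["medium"])
        for k in ("sg_days", "cg_days", "sg_severity_beta", "cg_severity_beta"):
            d[k] = tuple(d[k])
        return CohortConfig(**d)


def _smooth_unit_series(t: int, window: int, rng: np.random.Generator,
                        k: int = 1) -> np.ndarray:
    """k independent smooth zero-mean unit-SD series, as a (t, k) array.

    Hann-window moving average of white noise, then standardised per column.
    """
    pad = max(window, 1)
    e = rng.standard_normal((t + 2 * pad, k))
    if window > 1:
        kernel = np.hanning(window + 2)[1:-1]
        kernel /= kernel.sum()
        e = convolve1d(e, kernel, axis=0, mode="constant")
    z = e[pad : pad + t]
    z = z - z.mean(axis=0)
    sd = z.std(axis=0)
    return z / np.where(sd > 0, sd, 1.0)


def _truncated_normal(mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_measurement(
    severity: float,
    grid: FrequencyGrid,
    config: CohortConfig,
    rng: np.random.Generator,
    measurement_index: int = 1,
) -> MeasurementSeries:
    """One single measurement at the given severity.

    Per modality, channel f follows  baseline(f) + scale·(l_f·z(t) + a·η_f(t))
    with z a shared smooth latent series, η_f independent smooth series and
    amplitude a = noise_floor + desync_gain·severity.  At severity 0 with the
    noise floor at 0 every channel is an affine image of z (rank one).
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    t, nf = config.t_samples, len(grid)
    if t < 2:
        raise ValueError("dimensionality is undefined on fewer than 2 samples")

    # the medium's pulse noise doubles as probe-placement jitter, so the
    # per-channel baselines differ between the session's single measurements
    base_tof, base_att = simulate_received_pulse(grid, config.medium, rng)
    loadings = 1.0 + config.loading_spread * np.linspace(-1.0, 1.0, nf)
    amp = config.noise_floor + config.desync_gain * severity

    def modality(baseline: np.ndarray, scale: float) -> np.ndarray:
        z = _smooth_unit_series(t, config.smoothing, rng)[:, 0]
        out = baseline[None, :] + scale * loadings[None, :] * z[:, None]
        if amp > 0:
            eta = _smooth_unit_series(t, config.smoothing, rng, k=nf)
            out = out + scale * amp * eta
        return out

    tof = modality(base_tof, config.tof_scale)
    att = modality(base_att, config.att_scale)
    strength = _truncated_normal(
        config.signal_strength_mean, config.signal_strength_sd, 0.0, 100.0, rng
    )
    return MeasurementSeries(tof=tof, att=att, signal_strength=strength,
                             measurement_index=measurement_index)


def _clinical_fields(group: str, day: int, severity: float, config: CohortConfig,
                     rng: np.random.Generator) -> dict:
    sofa = int(np.clip(round(2.0 + 12.0 * severity + rng.normal(0, config.sofa_noise_sd)), 0, 24))
    if group == CG:
        icdsc = 0
    else:
        icdsc = int(np.clip(round(1.0 + 5.0 * severity + rng.normal(0, config.icdsc_noise_sd)), 0, 8))
        if day == 1:
            # septic patients are delirium-screen positive at inclusion
            icdsc = max(icdsc, config.cam_icu_cutoff)
    cam_icu = group == SG and icdsc >= config.cam_icu_cutoff
    labs = {
        "lactate": float(np.exp(np.log(0.9) + 1.2 * severity + rng.normal(0, 0.25))),
        "pct": float(np.exp(np.log(0.5) + 3.5 * severity + rng.normal(0, 0.5))),
        "creatinine": float(np.exp(np.log(75.0) + 0.8 * severity + rng.normal(0, 0.15))),
        "bilirubin": float(np.exp(np.log(10.0) + 0.9 * severity + rng.normal(0, 0.3))),
    }
    return {"sofa": sofa, "icdsc": icdsc, "cam_icu": cam_icu, **labs}


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Simulate a full cohort; identical (config, seed) gives an identical cohort.

    Enrollment interleaves the two arms (P01 septic, P02 control, ...), so a
    first-half/second-half patient split is balanced by construction.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)

    order: list[tuple[str, str]] = []
    sg_left, cg_left, idx = config.n_sg, config.n_cg, 1
    while sg_left or cg_left:
        if sg_left:
            order.append((f"P{idx:02d}", SG)); idx += 1; sg_left -= 1
        if cg_left:
            order.append((f"P{idx:02d}", CG)); idx += 1; cg_left -= 1

    records: list[PatientRecord] = []
    for pid, group in order:
        a, b = config.sg_severity_beta if group == SG else config.cg_severity_beta
        base = float(rng.beta(a, b))
        days = config.sg_days if group == SG else config.cg_days
        for day in days:
            sev = float(np.clip(base + rng.normal(0, config.severity_day_sd), 0.0, 1.0))
            clin = _clinical_fields(group, day, sev, config, rng)
            sessions = [
                generate_measurement(sev, config.grid, config, rng, measurement_index=m + 1)
                for m in range(config.n_measurements)
            ]
            if config.min_signal_strength > 0:
                sessions = [s for s in sessions
                            if s.signal_strength >= config.min_signal_strength]
            records.append(PatientRecord(
                patient_id=pid, group=group, day=day, severity=sev,
                sessions=sessions, **clin,
            ))

    fingerprint = json.dumps({"seed": seed, "config": json.loads(config.to_json())},
                             sort_keys=True)
    return Cohort(records=records, frequency_grid=config.grid,
                  config_fingerprint=fingerprint)
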