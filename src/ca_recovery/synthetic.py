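"""Synthetic inputs for every stage of the recovery-analysis pipeline.

Generates, with controllable ground truth and full seed determinism:

* post-arrest ECoG as a two-state (burst/suppression) semi-Markov process
  whose suppression probability decays exponentially from a starting to a
  final fraction, with amplitude-separable burst and suppression waveforms;
* neurological-deficit-scale cohorts with a configurable group shift and a
  death schedule that removes sheets after death;
* survival records (deaths at configured times, survivors censored at the
  72 h horizon; a death exactly at the horizon is an event);
* clustered or Poisson 2-D fields of stained-cell coordinates, with
  optional rasterization to an image of disks;
* blood-analyte panels (glucose pre/post arrest, ketone, corticosterone,
  glucagon, insulin) around group x time means, truncated at zero.

The analyte and survival defaults mirror the published cohort: 14 animals
per group, control deaths at resuscitation (x2), 24 h and 48 h, none in
the calorically restricted (CR) group; control glucose rises after arrest
while CR glucose stays flat; CR ketones exceed control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .nds import NdsRubric, NdsScoreSheet, compose_subscores, default_rubric
from .qeeg import SignalRecording
from .stats import SurvivalDataset

__all__ = [
    "EcogSimConfig",
    "CohortSimConfig",
    "PointFieldSimConfig",
    "StateTrack",
    "EcogSimulation",
    "simulate_ecog",
    "simulate_nds_cohort",
    "simulate_survival",
    "simulate_point_field",
    "rasterize_points",
    "simulate_analytes",
    "DEFAULT_ANALYTE_MEANS",
]

HORIZON_H = 72.0
TIMEPOINTS_H = (4, 24, 48, 72)

# Group x analyte (mean, SD) defaults, in the units of the source assays:
# glucose mg/dL, ketone mmol/L, hormones pg/mL.
DEFAULT_ANALYTE_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "glucose_pre": {"control": (219.5, 16.4), "cr": (147.1, 15.7)},
    "glucose_post": {"control": (277.6, 30.6), "cr": (143.4, 42.4)},
    "ketone": {"control": (0.6, 0.2), "cr": (1.4, 0.5)},
    "corticosterone": {"control": (196040.0, 22092.0), "cr": (398542.0, 59024.0)},
    "glucagon": {"control": (19.6, 7.8), "cr": (8.4, 2.9)},
    "insulin": {"control": (2621.0, 965.4), "cr": (393.4, 265.9)},
}

# Control-group mean NDS totals per timepoint; the 72 h value is a
# plausible continuation (the source switches to medians there).
_NDS_CONTROL_MEANS = {4: 15.4, 24: 48.5, 48: 52.0, 72: 55.0}


@dataclass(frozen=True)
class EcogSimConfig:
    """Ground-truth parameters of the burst-suppression ECoG simulator.

    The instantaneous suppression probability decays from
    ``supp_frac_start`` to ``supp_frac_end`` with half-life
    ``recovery_halflife`` seconds.  State durations are exponential by
    default (gamma optional) with means scaled so the local stationary
    suppressed fraction equals the target probability:
    supp mean = (burst_dur_mean + supp_dur_mean) * p(t), burst mean the
    complement.  Burst waveform: 1-30 Hz band-limited Gaussian noise at
    ``burst_amp`` RMS; suppression: white Gaussian at ``supp_amp`` RMS.
    """

    duration: float
    sampling_rate: float = 1526.0
    n_channels: int = 4
    burst_amp: float = 100.0
    supp_amp: float = 5.0
    burst_dur_mean: float = 3.0
    supp_dur_mean: float = 6.0
    supp_frac_start: float = 0.9
    supp_frac_end: float = 0.2
    recovery_halflife: float = 1800.0
    duration_law: str = "exponential"
    gamma_shape: float = 2.0
    ekg_amp: float = 0.0
    ekg_rate: float = 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.duration > 0 and self.sampling_rate > 0):
            raise ValueError("duration and sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if not (self.burst_dur_mean > 0 and self.supp_dur_mean > 0):
            raise ValueError("state duration means must be positive")
        for f in (self.supp_frac_start, self.supp_frac_end):
            if not 0.0 <= f <= 1.0:
                raise ValueError("suppression fractions must lie in [0, 1]")
        if self.duration_law not in ("exponential", "gamma"):
            raise ValueError("duration_law must be 'exponential' or 'gamma'")
        if self.ekg_amp < 0 or self.ekg_rate < 0:
            raise ValueError("EKG artifact parameters must be non-negative")

    def is_separable(self, threshold: float = 25.0) -> bool:
        """Amplitudes straddle the suppression threshold."""
        return self.supp_amp < threshold < self.burst_amp


@dataclass
class StateTrack:
    """Ground-truth burst/suppression segments partitioning [0, duration]."""

    starts: np.ndarray
    ends: np.ndarray
    suppressed: np.ndarray  # bool per segment

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.suppressed = np.asarray(self.suppressed, dtype=bool)
        if self.starts.size:
            if not np.allclose(self.starts[1:], self.ends[:-1]):
                raise ValueError("state track must partition time (no gaps/overlaps)")
            if np.any(self.ends <= self.starts):
                raise ValueError("segments must have positive length")

    @property
    def duration(self) -> float:
        return float(self.ends[-1]) if self.ends.size else 0.0

    def suppressed_time(self, a: float, b: float) -> float:
        """Ground-truth suppressed time within [a, b]."""
        if not self.starts.size:
            return 0.0
        lo = np.maximum(self.starts, a)
        hi = np.minimum(self.ends, b)
        overlap = np.clip(hi - lo, 0.0, None)
        return float(overlap[self.suppressed].sum())

    def suppressed_fraction(self, a: float, b: float) -> float:
        return self.suppressed_time(a, b) / (b - a)


@dataclass
class EcogSimulation:
    recording: SignalRecording
    state_track: StateTrack
    config: EcogSimConfig


def _supp_prob(t: float, cfg: EcogSimConfig) -> float:
    if cfg.recovery_halflife <= 0:
        return cfg.supp_frac_end
    decay = 0.5 ** (t / cfg.recovery_halflife)
    return cfg.supp_frac_end + (cfg.supp_frac_start - cfg.supp_frac_end) * decay


def _draw_duration(mean: float, cfg: EcogSimConfig, rng: np.random.Generator) -> float:
    if mean <= 0:
        return 0.0
    if cfg.duration_law == "exponential":
        return float(rng.exponential(mean))
    return float(rng.gamma(cfg.gamma_shape, mean / cfg.gamma_shape))


def _simulate_track(cfg: EcogSimConfig, rng: np.random.Generator) -> StateTrack:
    base = cfg.burst_dur_mean + cfg.supp_dur_mean
    t = 0.0
    suppressed_now = bool(rng.random() < _supp_prob(0.0, cfg))
    starts, ends, states = [], [], []
    while t < cfg.duration:
        p = _supp_prob(t, cfg)
        mean = base * p if suppressed_now else base * (1.0 - p)
        dur = _draw_duration(mean, cfg, rng)
        if dur > 0.0:
            end = min(t + dur, cfg.duration)
            if states and states[-1] == suppressed_now:
                ends[-1] = end  # merge with previous same-state segment
            else:
                starts.append(t)
                ends.append(end)
                states.append(suppressed_now)
            t = end
        suppressed_now = not suppressed_now
    return StateTrack(np.array(starts), np.array(ends), np.array(states))


def simulate_ecog(config: EcogSimConfig) -> EcogSimulation:
    """Simulate a multichannel burst-suppression ECoG recording.

    Returns the recording together with the shared ground-truth state
    track (one track for all channels: burst suppression is a global
    brain state).  Identical configs (same seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    track = _simulate_track(config, rng)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))

    # per-sample suppression mask from the segment track
    mask = np.zeros(n, dtype=bool)
    for s, e, supp in zip(track.starts, track.ends, track.suppressed):
        if supp:
            i0 = int(np.ceil(s * fs - 1e-9))
            i1 = min(int(np.ceil(e * fs - 1e-9)), n)
            mask[i0:i1] = True

    sos = sps.butter(4, [1.0, min(30.0, fs / 2 * 0.9)], btype="bandpass", fs=fs, output="sos")
    samples = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        white = rng.standard_normal(n)
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        crms = carrier.std()
        if crms > 0:
            carrier = carrier / crms
        samples[ch] = np.where(
            mask, config.supp_amp * white, config.burst_amp * carrier
        )

    if config.ekg_amp > 0 and config.ekg_rate > 0:
        samples += _ekg_artifact(n, fs, config.ekg_amp, config.ekg_rate)

    rec = SignalRecording(
        samples=samples,
        sampling_rate=fs,
        channel_labels=tuple(f"ecog{i}" for i in range(config.n_channels)),
        t0_offset=0.0,
    )
    return EcogSimulation(recording=rec, state_track=track, config=config)


def _ekg_artifact(n: int, fs: float, amp: float, rate: float) -> np.ndarray:
    """Periodic sharp biphasic spikes (cardiac contamination), all channels."""
    x = np.zeros(n)
    half = max(1, int(round(0.01 * fs)))  # 10 ms per lobe
    period = int(round(fs / rate))
    for start in range(0, n, max(period, 2 * half)):
        x[start:start + half] += amp
        x[start + half:start + 2 * half] -= amp
    return x


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level ground truth: group sizes, deaths, NDS shift, analytes."""

    n_per_group: int = 14
    groups: tuple[str, str] = ("control", "cr")
    nds_group_shift: float = 7.0
    nds_noise_sd: float = 6.0
    control_death_times: tuple[float, ...] = (0.0, 0.0, 24.0, 48.0)
    cr_death_times: tuple[float, ...] = ()
    nds_baseline_means: Mapping[int, float] = field(
        default_factory=lambda: dict(_NDS_CONTROL_MEANS)
    )
    analyte_means: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_ANALYTE_MEANS
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        for t in self.control_death_times + self.cr_death_times:
            if not 0.0 <= t <= HORIZON_H:
                raise ValueError(f"death time {t} outside [0, {HORIZON_H}] h")
        if len(self.control_death_times) > self.n_per_group:
            raise ValueError("more control deaths than animals")
        if len(self.cr_death_times) > self.n_per_group:
            raise ValueError("more CR deaths than animals")

    def death_times(self, group: str) -> tuple[float, ...]:
        return self.control_death_times if group == self.groups[0] else self.cr_death_times


def _death_schedule(config: CohortSimConfig) -> dict[str, dict[str, float]]:
    """Per-group mapping animal id -> death time (inf for survivors)."""
    out: dict[str, dict[str, float]] = {}
    for g in config.groups:
        deaths = sorted(config.death_times(g))
        sched = {}
        for i in range(config.n_per_group):
            aid = f"{g}{i:02d}"
            sched[aid] = deaths[i] if i < len(deaths) else np.inf
        out[g] = sched
    return out


def simulate_nds_cohort(
    config: CohortSimConfig, rubric: NdsRubric | None = None
) -> list[NdsScoreSheet]:
    """Simulate NDS score sheets for a two-group cohort.

    Per surviving animal x timepoint, a target total is drawn around the
    group trajectory (control baseline + ``nds_group_shift`` for the
    restricted group) with ``nds_noise_sd`` Gaussian noise, clipped to
    [0, 70], then decomposed into an exact legal subscore assignment.
    Animals dead at or before a timepoint have no sheet for it.
    """
    rub = rubric or default_rubric()
    rng = np.random.default_rng(config.seed)
    schedule = _death_schedule(config)
    sheets: list[NdsScoreSheet] = []
    for gi, g in enumerate(config.groups):
        shift = 0.0 if gi == 0 else config.nds_group_shift
        for aid, death in schedule[g].items():
            for tp in TIMEPOINTS_H:
                if death <= tp:
                    continue
                target = config.nds_baseline_means[tp] + shift
                target += rng.normal(0.0, config.nds_noise_sd) if config.nds_noise_sd > 0 else 0.0
                target = float(np.clip(target, 0.0, 70.0))
                sheets.append(
                    NdsScoreSheet(
                        animal_id=aid,
                        group=g,
                        timepoint_h=tp,
                        subscores=compose_subscores(target, rub, rng=rng),
                    )
                )
    return sheets


def simulate_survival(config: CohortSimConfig) -> SurvivalDataset:
    """Survival records: configured deaths, survivors censored at 72 h."""
    times, events, groups = [], [], []
    schedule = _death_schedule(config)
    for g in config.groups:
        for aid, death in schedule[g].items():
            if np.isfinite(death):
                times.append(death)
                events.append(True)  # death at exactly 72 h is an event
            else:
                times.append(HORIZON_H)
                events.append(False)
            groups.append(g)
    return SurvivalDataset(
        time=np.array(times), event=np.array(events), group=np.array(groups, dtype=object)
    )


@dataclass(frozen=True)
class PointFieldSimConfig:
    """2-D field of stained-cell coordinates (micrometres).

    ``mode='poisson'`` scatters cells uniformly; ``mode='clustered'`` is a
    Neyman-Scott process: cells attach to uniformly placed parents with
    isotropic Gaussian dispersion ``dispersion_um`` and are clipped to the
    extent.
    """

    width_um: float = 1000.0
    height_um: float = 1000.0
    n_cells: int = 100
    mode: str = "poisson"
    cluster_size: int = 10
    dispersion_um: float = 20.0
    cell_radius_um: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValueError("field extent must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.mode not in ("poisson", "clustered"):
            raise ValueError("mode must be 'poisson' or 'clustered'")
        if self.mode == "clustered" and self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")


def simulate_point_field(config: PointFieldSimConfig) -> pd.DataFrame:
    """Simulate cell coordinates; columns x_um, y_um, radius_um."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    if n == 0:
        return pd.DataFrame(columns=["x_um", "y_um", "radius_um"])
    if config.mode == "poisson":
        x = rng.uniform(0.0, config.width_um, size=n)
        y = rng.uniform(0.0, config.height_um, size=n)
    else:
        n_parents = max(1, int(round(n / config.cluster_size)))
        px = rng.uniform(0.0, config.width_um, size=n_parents)
        py = rng.uniform(0.0, config.height_um, size=n_parents)
        which = rng.integers(0, n_parents, size=n)
        x = np.clip(px[which] + rng.normal(0, config.dispersion_um, n), 0, config.width_um)
        y = np.clip(py[which] + rng.normal(0, config.dispersion_um, n), 0, config.height_um)
    return pd.DataFrame(
        {"x_um": x, "y_um": y, "radius_um": np.full(n, config.cell_radius_um)}
    )


def rasterize_points(
    points: pd.DataFrame,
    width_um: float,
    height_um: float,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Render cells as filled disks into a uint8 image (row 0 = top)."""
    nx = int(np.ceil(width_um / pixel_size_um))
    ny = int(np.ceil(height_um / pixel_size_um))
    img = np.zeros((ny, nx), dtype=np.uint8)
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    xs = cols * pixel_size_um
    ys = (ny - 1 - rows) * pixel_size_um
    for p in points.itertuples():
        r = max(p.radius_um, pixel_size_um / 2)
        img[(xs - p.x_um) ** 2 + (ys - p.y_um) ** 2 <= r**2] = 255
    return img


def simulate_analytes(config: CohortSimConfig) -> pd.DataFrame:
    """Blood-analyte panels, one row per animal x variable (x timepoint).

    Values are Gaussian around the configured group (x time, for glucose)
    means and truncated at zero.  Columns: animal, group, variable,
    timepoint, value.  Glucose rows carry timepoint 'pre'/'post'; the
    other analytes a single 'pre' measurement.
    """
    rng = np.random.default_rng(
        config.seed if config.seed is None else config.seed + 1
    )
    rows = []
    for g in config.groups:
        for i in range(config.n_per_group):
            aid = f"{g}{i:02d}"
            for var, per_group in config.analyte_means.items():
                mean, sd = per_group[g]
                value = max(0.0, float(rng.normal(mean, sd)) if sd > 0 else mean)
                if var.startswith("glucose_"):
                    variable, timepoint = "glucose", var.split("_", 1)[1]
                else:
                    variable, timepoint = var, "pre"
                rows.append(
                    {
                        "animal": aid,
                        "group": g,
                        "variable": variable,
                        "timepoint": timepoint,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
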