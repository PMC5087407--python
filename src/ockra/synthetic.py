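"""Synthetic wearable-band sensor logs: normal daily behavior plus staged anomalies.

The real personal-risk data this emulates (week-long band logs from 23
subjects, available only on request) mixes tri-axial motion channels at 8 Hz,
heart rate and cumulative counters at 1 Hz, and slow skin-temperature / UV
channels, with battery-recharge gaps.  The generator reproduces that
*statistical structure*, not physiology: a hidden rest/walk/brisk Markov
chain modulates per-channel means and variances, heart rate follows a
resting level plus a circadian sinusoid, a state shift and Gaussian noise,
and cumulative counters integrate per-state rates.

The five staged anomaly scenarios (sprinting 100 m, stairs, boxing, falls,
breath-holding) are generated by the *same* process with a scenario overlay:
a heart-rate offset trajectory, variance multipliers on the motion channels,
step-rate multipliers, impact spikes for falls and a stillness factor.  With
all effect sizes scaled to zero the overlay vanishes and the anomaly log is
distributed exactly like normal behavior — giving a proper null for
calibration checks — while the default effect sizes produce anomalies that a
working detector should separate almost perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ockra.preprocess import (
    LABEL_ATYPICAL,
    LABEL_TYPICAL,
    LabeledDataset,
    build_feature_vectors,
    features_to_dataset,
)

SCENARIOS = ("rushing_100m", "stairs", "boxing", "falling", "breath_holding")

_STATES = ("rest", "walk", "brisk")
# per-state channel parameters: accel sd [g], gyro sd [deg/s], step rate
# [steps/s], heart-rate shift [bpm], speed [cm/s], calorie rate [kcal/s]
_STATE_PARAMS = {
    "rest": dict(accel_sd=0.02, gyro_sd=3.0, steps=0.0, hr=0.0, speed=0.0, kcal=0.02),
    "walk": dict(accel_sd=0.15, gyro_sd=30.0, steps=1.8, hr=12.0, speed=120.0, kcal=0.06),
    "brisk": dict(accel_sd=0.30, gyro_sd=60.0, steps=2.5, hr=25.0, speed=180.0, kcal=0.10),
}
_STAY_PROB = 0.98  # per-second probability of remaining in the current state


@dataclass
class SubjectProfile:
    """Per-subject physiology and activity parameters."""

    subject_id: str = "S1"
    resting_hr: float = 62.0  # bpm
    hr_circadian_amplitude: float = 6.0  # bpm
    baseline_skin_temp: float = 33.0  # Celsius
    stride_cm: float = 75.0
    activity_scale: float = 1.0  # scales motion variances
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40.0 <= self.resting_hr <= 120.0:
            raise ValueError("resting_hr must lie in [40, 120] bpm")
        if self.activity_scale < 0:
            raise ValueError("activity_scale must be non-negative")


@dataclass
class ScenarioSpec:
    """Effect sizes of one staged anomaly, applied on top of normal behavior."""

    scenario: str
    duration: float = 60.0  # seconds
    hr_shift: float = 0.0  # bpm added after a short ramp-in
    hr_dip: float = 0.0  # bpm subtracted during breath-holding
    accel_var_mult: float = 1.0
    gyro_var_mult: float = 1.0
    step_rate_mult: float = 1.0
    accel_sd_add: float = 0.0  # g, floor of vigorous-motion variability
    gyro_sd_add: float = 0.0  # deg/s
    step_rate_add: float = 0.0  # steps/s
    speed_add: float = 0.0  # cm/s
    spike_amplitude: float = 0.0  # g, fall-impact acceleration spikes
    spike_gyro_sd: float = 0.0  # deg/s, rotation burst during an impact second
    spike_interval: float = 5.0  # seconds between successive impacts
    stillness: float = 1.0  # multiplies motion sd (<1 = frozen)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.accel_var_mult, self.gyro_var_mult, self.step_rate_mult) < 0:
            raise ValueError("multipliers must be non-negative")

    def scaled(self, effect_scale: float) -> "ScenarioSpec":
        """Interpolate all effects between the null (0) and the spec (1)."""
        e = effect_scale
        return replace(
            self,
            hr_shift=self.hr_shift * e,
            hr_dip=self.hr_dip * e,
            accel_var_mult=1.0 + (self.accel_var_mult - 1.0) * e,
            gyro_var_mult=1.0 + (self.gyro_var_mult - 1.0) * e,
            step_rate_mult=1.0 + (self.step_rate_mult - 1.0) * e,
            accel_sd_add=self.accel_sd_add * e,
            gyro_sd_add=self.gyro_sd_add * e,
            step_rate_add=self.step_rate_add * e,
            speed_add=self.speed_add * e,
            spike_amplitude=self.spike_amplitude * e,
            spike_gyro_sd=self.spike_gyro_sd * e,
            stillness=1.0 + (self.stillness - 1.0) * e,
        )


def default_scenarios() -> dict[str, ScenarioSpec]:
    """Default effect sizes for the five staged anomaly scenarios.

    The multiplicative terms amplify whatever the hidden activity state is
    doing; the additive terms impose the absolute intensity of the staged
    activity (a sprint is vigorous no matter what preceded it), which is what
    makes the scenarios separable from every normal state rather than only
    from rest.
    """
    return {
        "rushing_100m": ScenarioSpec(
            "rushing_100m", duration=30, hr_shift=50, accel_var_mult=10,
            gyro_var_mult=5, step_rate_mult=3, accel_sd_add=0.6,
            gyro_sd_add=60.0, step_rate_add=2.0, speed_add=380.0,
        ),
        "stairs": ScenarioSpec(
            "stairs", duration=120, hr_shift=40, accel_var_mult=10,
            gyro_var_mult=5, step_rate_mult=3, accel_sd_add=0.4,
            gyro_sd_add=50.0, step_rate_add=1.5, speed_add=150.0,
        ),
        "boxing": ScenarioSpec(
            "boxing", duration=120, hr_shift=25, accel_var_mult=15,
            gyro_var_mult=15, accel_sd_add=0.8, gyro_sd_add=150.0,
        ),
        "falling": ScenarioSpec(
            "falling", duration=60, hr_shift=15, spike_amplitude=3.5,
            spike_gyro_sd=250.0, spike_interval=5.0, step_rate_mult=0.0,
            accel_sd_add=0.5, gyro_sd_add=100.0,
        ),
        # hold phase: frozen posture and bradycardia; struggle phase near the
        # breakpoint: involuntary movement bursts and post-release tachycardia
        "breath_holding": ScenarioSpec(
            "breath_holding", duration=45, hr_dip=25, hr_shift=35,
            step_rate_mult=0.0, stillness=0.15, accel_sd_add=0.5,
            gyro_sd_add=100.0,
        ),
    }


def _markov_states(n_seconds: int, rng: np.random.Generator) -> np.ndarray:
    states = np.empty(n_seconds, dtype=int)
    states[0] = rng.integers(0, len(_STATES))
    for t in range(1, n_seconds):
        if rng.random() < _STAY_PROB:
            states[t] = states[t - 1]
        else:
            others = [s for s in range(len(_STATES)) if s != states[t - 1]]
            states[t] = others[rng.integers(0, len(others))]
    return states


def _simulate(
    profile: SubjectProfile,
    n_seconds: int,
    rng: np.random.Generator,
    spec: ScenarioSpec | None = None,
    gap_schedule=None,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Shared generative core; ``spec`` overlays scenario effects if given."""
    n_seconds = int(n_seconds)
    states = _markov_states(n_seconds, rng)
    p = {key: np.array([_STATE_PARAMS[s][key] for s in _STATES]) for key in
         ("accel_sd", "gyro_sd", "steps", "hr", "speed", "kcal")}
    accel_sd = p["accel_sd"][states] * profile.activity_scale
    gyro_sd = p["gyro_sd"][states] * profile.activity_scale
    step_rate = p["steps"][states]
    hr_state = p["hr"][states]
    speed = p["speed"][states].astype(float)
    kcal_rate = p["kcal"][states]

    t = np.arange(n_seconds, dtype=float)
    hr_offset = np.zeros(n_seconds)
    spike_seconds: np.ndarray = np.empty(0, dtype=int)
    if spec is not None:
        ramp = np.minimum(1.0, (t + 1.0) / max(1.0, 0.1 * spec.duration))
        still = np.full(n_seconds, spec.stillness)
        add_on = np.ones(n_seconds)
        if spec.scenario == "breath_holding":
            # clean hold for the first 60%, struggle phase afterwards
            hold = t < 0.6 * n_seconds
            hr_offset = np.where(hold, -spec.hr_dip, spec.hr_shift) * ramp
            still = np.where(hold, spec.stillness, 1.0)
            add_on = (~hold).astype(float)
        else:
            hr_offset = spec.hr_shift * ramp
        accel_sd = accel_sd * np.sqrt(spec.accel_var_mult) * still + spec.accel_sd_add * add_on
        gyro_sd = gyro_sd * np.sqrt(spec.gyro_var_mult) * still + spec.gyro_sd_add * add_on
        step_rate = step_rate * spec.step_rate_mult + spec.step_rate_add
        speed = speed * spec.step_rate_mult + spec.speed_add
        if spec.spike_amplitude > 0:
            spike_seconds = np.arange(2, n_seconds, max(1, int(spec.spike_interval)))
            gyro_sd = np.asarray(gyro_sd, dtype=float).copy()
            gyro_sd[spike_seconds] += spec.spike_gyro_sd

    # --- 8 Hz motion channels --------------------------------------------
    hi_t = (t[:, None] + np.arange(8) / 8.0).ravel() + t0
    frames = []
    accel_means = {"accel_x": 0.0, "accel_y": 0.0, "accel_z": 1.0}  # gravity on z
    for ch, mu in accel_means.items():
        vals = (mu + rng.standard_normal((n_seconds, 8)) * accel_sd[:, None])
        if len(spike_seconds) and ch == "accel_z":
            vals[spike_seconds[:, None], :3] += spec.spike_amplitude
        frames.append(pd.DataFrame({"timestamp": hi_t, "channel": ch, "value": vals.ravel()}))
    for axis in "xyz":
        vals = rng.standard_normal((n_seconds, 8)) * gyro_sd[:, None]
        frames.append(pd.DataFrame({"timestamp": hi_t, "channel": f"gyro_{axis}", "value": vals.ravel()}))
        # the gyroscope event also reports acceleration, slightly noisier
        vals = (accel_means[f"accel_{axis}"]
                + rng.standard_normal((n_seconds, 8)) * accel_sd[:, None] * 1.2)
        frames.append(pd.DataFrame({"timestamp": hi_t, "channel": f"gyro_accel_{axis}", "value": vals.ravel()}))

    # --- 1 Hz channels -----------------------------------------------------
    hr = (profile.resting_hr
          + profile.hr_circadian_amplitude * np.sin(2 * np.pi * (t + t0) / 86400.0)
          + hr_state + hr_offset + rng.standard_normal(n_seconds) * 1.5)
    speed_obs = np.maximum(0.0, speed + rng.standard_normal(n_seconds) * 5.0 * (speed > 0))
    pace = np.where(speed_obs > 1.0, 1.0e5 / np.maximum(speed_obs, 1.0), 0.0)
    steps_inc = rng.poisson(np.maximum(step_rate, 0.0))
    steps_total = np.cumsum(steps_inc)
    distance_total = np.cumsum(steps_inc * profile.stride_cm)
    calories_total = np.cumsum(kcal_rate)
    for ch, vals in (
        ("heart_rate", hr), ("pace", pace), ("speed", speed_obs),
        ("steps_total", steps_total.astype(float)),
        ("distance_total", distance_total.astype(float)),
        ("calories_total", calories_total),
    ):
        frames.append(pd.DataFrame({"timestamp": t + t0, "channel": ch, "value": vals}))

    # --- slow channels -----------------------------------------------------
    st_t = np.arange(0, n_seconds, 30, dtype=float)
    skin = (profile.baseline_skin_temp + 0.3 * np.sin(2 * np.pi * (st_t + t0) / 3600.0)
            + rng.standard_normal(len(st_t)) * 0.05)
    frames.append(pd.DataFrame({"timestamp": st_t + t0, "channel": "skin_temp", "value": skin}))
    uv_t = np.arange(0, n_seconds, 60, dtype=float)
    uv = rng.choice([0.0, 1.0, 2.0], size=len(uv_t), p=[0.7, 0.2, 0.1])
    frames.append(pd.DataFrame({"timestamp": uv_t + t0, "channel": "uv", "value": uv}))

    log = pd.concat(frames, ignore_index=True)
    if gap_schedule:
        ts = log["timestamp"].to_numpy()
        keep = np.ones(len(log), dtype=bool)
        for start, end in gap_schedule:
            keep &= ~((ts >= start) & (ts < end))
        log = log[keep]
    return log.sort_values("timestamp", kind="stable", ignore_index=True)


def simulate_normal_log(
    profile: SubjectProfile,
    n_seconds: int,
    gap_schedule=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a normal daily-behavior log at the band's native rates.

    ``gap_schedule`` is a list of ``(start, end)`` second intervals whose
    readings are dropped entirely, emulating battery-recharge gaps.
    """
    if n_seconds < 60:
        raise ValueError("n_seconds must be at least 60")
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    return _simulate(profile, n_seconds, rng, gap_schedule=gap_schedule)


def simulate_anomaly_log(
    profile: SubjectProfile,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Simulate one staged anomaly scenario log of ``spec.duration`` seconds."""
    if rng is None:
        rng = np.random.default_rng(profile.seed + 1)
    return _simulate(profile, int(spec.duration), rng, spec=spec, t0=t0)


def generate_dataset(
    n_subjects: int = 2,
    seconds_per_subject: int = 3600,
    scenarios: dict[str, ScenarioSpec] | None = None,
    master_seed: int = 0,
    effect_scale: float = 1.0,
    gap_schedule=None,
) -> dict[str, tuple[LabeledDataset, LabeledDataset]]:
    """Per-subject (normal, anomalous) labeled feature tables.

    Both logs are pushed through the standard per-second feature extraction;
    normal rows are labeled ``typical`` and scenario rows ``atypical``.
    ``effect_scale`` interpolates every scenario effect between the null
    model (0, anomalies indistinguishable from normal) and the defaults (1).
    Fully deterministic under ``master_seed``.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    root = np.random.SeedSequence(master_seed)
    out: dict[str, tuple[LabeledDataset, LabeledDataset]] = {}
    for i, child in enumerate(root.spawn(n_subjects)):
        rngs = [np.random.default_rng(s) for s in child.spawn(2 + len(scenarios))]
        profile_rng = rngs[0]
        profile = SubjectProfile(
            subject_id=f"S{i + 1}",
            resting_hr=float(profile_rng.uniform(55, 75)),
            hr_circadian_amplitude=float(profile_rng.uniform(4, 8)),
            baseline_skin_temp=float(profile_rng.uniform(32, 34)),
            stride_cm=float(profile_rng.uniform(60, 90)),
            activity_scale=float(profile_rng.uniform(0.8, 1.2)),
        )
        normal_log = _simulate(profile, seconds_per_subject, rngs[1], gap_schedule=gap_schedule)
        normal = features_to_dataset(build_feature_vectors(normal_log), LABEL_TYPICAL)
        anomaly_parts = []
        t0 = 0.0
        for rng, spec in zip(rngs[2:], scenarios.values()):
            log = _simulate(profile, int(spec.duration), rng, spec=spec.scaled(effect_scale), t0=t0)
            anomaly_parts.append(build_feature_vectors(log))
            t0 += float(spec.duration) + 300.0  # scenarios well separated in time
        anomalous = features_to_dataset(
            pd.concat(anomaly_parts, ignore_index=True), LABEL_ATYPICAL
        )
        out[profile.subject_id] = (normal, anomalous)
    return out
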