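"""Synthetic accelerometer-walking study generator.

Emulates the structure of a two-visit, twenty-subject gait validation study:
self-paced walking tasks at three speeds, in-lab simulated-activity sessions
and a longer outside-lab session, recorded simultaneously by a chest and a
lumbar tri-axial accelerometer.  Walking kinematics follow the inverted
pendulum model used by the extraction pipeline, run in the forward
direction: given a true gait speed v and stride time T, the step length is
``sl = v*T/2`` and the vertical centre-of-mass excursion at a location with
pendulum length ``l`` is ``h = l - sqrt(l^2 - (sl/2)^2)``.  The vertical
displacement is a periodic arc at the step frequency whose minima are the
initial contacts; the sensor reads its second time-derivative plus gravity.

Every recording comes with complete ground truth (event times, bout
intervals, per-stride parameters) so downstream estimators can be validated
without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AccelRecording, GaitEvents, GroundTruth, GRAVITY_MPS2

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "simulate_walk_segment",
    "simulate_activity_session",
    "simulate_study",
    "simulate_endpoint_table",
    "simulate_fragmented_bout_stats",
]

#: fraction of the step period separating an initial contact from the
#: following (contralateral) final contact in the arc model
FC_PHASE = 0.75

WALK_TASKS = ("walk_slow", "walk_normal", "walk_fast")
ACTIVITY_TASKS = ("simulated_activities", "outside_activities")


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the generator.

    Speed and stride-time defaults describe healthy self-paced walking;
    the slow/fast multipliers scale the normal-pace speed.  ``chest_bias_mps``
    is an additive device effect on the amplitude-generating speed of the
    chest channel (0 = no device effect).  ``visit_retest_rho`` correlates a
    subject's walking parameters across the two visits.
    """

    n_subjects: int = 20
    n_visits: int = 2
    sampling_rate_hz: float = 128.0
    tasks: tuple[str, ...] = WALK_TASKS + ACTIVITY_TASKS
    speed_mean_mps: float = 1.25
    speed_sd_mps: float = 0.15
    speed_multipliers: tuple[float, float] = (0.75, 1.25)
    stride_time_mean_s: float = 1.05
    stride_time_sd_s: float = 0.08
    chest_bias_mps: float = 0.0
    noise_sd_g: dict = field(default_factory=lambda: {"chest": 0.02, "lumbar": 0.015})
    visit_retest_rho: float = 0.8
    height_fraction: dict = field(default_factory=lambda: {"chest": 0.72, "lumbar": 0.53})
    orientation_jitter_deg: float = 2.0
    walk_task_duration_s: float = 30.0
    inlab_activity_duration_s: float = 420.0
    outside_activity_duration_s: float = 1200.0
    inlab_walk_fraction: float = 0.4
    outside_walk_fraction: float = 0.5
    mean_bout_duration_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not (0 < self.visit_retest_rho <= 1):
            raise ValueError("visit_retest_rho must be in (0, 1]")
        lo, hi = self.speed_multipliers
        if not (lo < 1 < hi):
            raise ValueError("speed_multipliers must bracket 1")
        for sd in (self.speed_sd_mps, self.stride_time_sd_s):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if isinstance(self.noise_sd_g, (int, float)):
            self.noise_sd_g = {"chest": float(self.noise_sd_g),
                               "lumbar": float(self.noise_sd_g)}


@dataclass
class StudyBundle:
    """All recordings of a simulated study plus shared ground truth."""

    recordings: dict          # (subject, visit, task, location) -> AccelRecording
    truths: dict              # (subject, visit, task) -> GroundTruth
    metadata: pd.DataFrame    # subject, visit, task, location, age, height_m, ...
    config: SimulationConfig


def pendulum_excursion(step_length: float, l: float) -> float:
    """Vertical excursion h solving ``step_length = 2*sqrt(2*l*h - h^2)``."""
    if step_length >= 2 * l:
        raise ValueError(
            f"infeasible geometry: step length {step_length:.3f} m >= 2*l = {2 * l:.3f} m")
    return l - np.sqrt(l * l - (step_length / 2) ** 2)


def _random_rotation(rng: np.random.Generator, jitter_deg: float) -> np.ndarray:
    """Small proper rotation about a random axis."""
    if jitter_deg <= 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.normal(0.0, jitter_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def simulate_walk_segment(
    speed: float,
    stride_time: float,
    duration: float,
    sensor_height: float = 1.0,
    sampling_rate: float = 128.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[AccelRecording, GroundTruth]:
    """Simulate one continuous walking segment.

    ``speed = 0`` yields a still segment (vertical channel at 1 g, no events).
    Raises for an infeasible step length (>= 2 * sensor_height) or a duration
    shorter than one stride.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if stride_time <= 0:
        raise ValueError("stride_time must be positive")
    fs = float(sampling_rate)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    if speed == 0.0:
        accel = np.zeros((n, 3))
        accel[:, 2] = 1.0
        accel += rng.normal(0.0, noise_sd, accel.shape)
        rec = AccelRecording(time=t, accel=accel, fs=fs, sensor_height=sensor_height)
        truth = GroundTruth(events=GaitEvents(), bouts=[],
                            strides=pd.DataFrame(), step_count=0,
                            params={"speed_mps": 0.0})
        return rec, truth

    if duration < stride_time:
        raise ValueError("duration must cover at least one stride")
    step_length = speed * stride_time / 2.0
    h = pendulum_excursion(step_length, sensor_height)
    step_period = stride_time / 2.0
    f_step = 1.0 / step_period
    w = 2 * np.pi * f_step
    t0 = step_period / 2.0  # first initial contact, strictly inside the segment

    # vertical CoM arc: minima at initial contacts, peak-to-peak h
    dyn = (h / 2.0) * w * w * np.cos(w * (t - t0))  # m/s^2
    az = 1.0 + dyn / GRAVITY_MPS2
    # low-amplitude harmonics on the horizontal axes (AP at step frequency,
    # ML at stride frequency) so the signal is genuinely tri-axial
    amp = (h / 2.0) * w * w / GRAVITY_MPS2
    ax = 0.25 * amp * np.sin(w * (t - t0))
    ay = 0.15 * amp * np.sin(0.5 * w * (t - t0))
    accel = np.column_stack([ax, ay, az])
    accel += rng.normal(0.0, noise_sd, accel.shape)

    ics = t0 + np.arange(int(np.floor((duration - t0) / step_period)) + 1) * step_period
    ics = ics[ics < duration - 1e-9]
    fcs = ics[:-1] + FC_PHASE * step_period
    fcs = fcs[fcs < duration - 1e-9]
    events = GaitEvents(initial_contacts=ics, final_contacts=fcs)

    n_strides = max(0, ics.size - 2)
    strides = pd.DataFrame({
        "stride_time_s": np.full(n_strides, stride_time),
        "stride_length_m": np.full(n_strides, speed * stride_time),
        "gait_speed_mps": np.full(n_strides, speed),
        "cadence_spm": np.full(n_strides, 120.0 / stride_time),
    })
    truth = GroundTruth(
        events=events, bouts=[(0.0, duration)], strides=strides,
        step_count=int(ics.size),
        params={"speed_mps": speed, "stride_time_s": stride_time,
                "h_m": h, "l_m": sensor_height, "step_length_m": step_length})
    rec = AccelRecording(time=t, accel=accel, fs=fs, sensor_height=sensor_height)
    return rec, truth


def _nonwalk_segment(n: int, rng: np.random.Generator, active: bool) -> np.ndarray:
    """Non-gait accelerometry: quiet sitting or aperiodic activity noise."""
    sd = 0.05 if active else 0.004
    seg = rng.normal(0.0, sd, (n, 3))
    seg[:, 2] += 1.0
    return seg


def simulate_activity_session(
    duration_s: float,
    walk_fraction: float,
    speed: float,
    stride_time: float,
    sensor_height: float = 1.0,
    sampling_rate: float = 128.0,
    noise_sd: float = 0.0,
    mean_bout_s: float = 30.0,
    min_bout_s: float = 10.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[AccelRecording, GroundTruth]:
    """Simulate a free-living session: walking bouts interleaved with non-gait.

    ``walk_fraction`` is the expected proportion of session time spent
    walking; bout durations are gamma-distributed around ``mean_bout_s``.
    Non-gait segments alternate quiet sitting and aperiodic object-handling
    noise and contain no periodic locomotor component.
    """
    if not (0 <= walk_fraction <= 1):
        raise ValueError("walk_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = float(sampling_rate)
    n_total = int(round(duration_s * fs))

    if walk_fraction >= 0.999:
        rec, truth = simulate_walk_segment(
            speed, stride_time, duration_s, sensor_height, fs, noise_sd, rng)
        return rec, truth

    chunks: list[np.ndarray] = []
    bouts: list[tuple[float, float]] = []
    ic_all: list[np.ndarray] = []
    fc_all: list[np.ndarray] = []
    stride_tabs: list[pd.DataFrame] = []
    step_count = 0

    mean_gap = mean_bout_s * (1 - walk_fraction) / max(walk_fraction, 1e-9)
    pos = 0  # samples written
    walking = False
    active_toggle = True
    while pos < n_total:
        remaining = (n_total - pos) / fs
        if walking and walk_fraction > 0.001:
            dur = float(np.clip(rng.gamma(4.0, mean_bout_s / 4.0),
                                min_bout_s, 4 * mean_bout_s))
            dur = min(dur, remaining)
            if dur >= max(min_bout_s / 2, 2 * stride_time):
                n_seg = int(round(dur * fs))
                bout_speed = speed * float(np.clip(rng.normal(1.0, 0.05), 0.7, 1.3))
                seg_rec, seg_truth = simulate_walk_segment(
                    bout_speed, stride_time, n_seg / fs, sensor_height, fs,
                    noise_sd, rng)
                start = pos / fs
                chunks.append(seg_rec.accel)
                bouts.append((start, start + n_seg / fs))
                ic_all.append(seg_truth.events.initial_contacts + start)
                fc_all.append(seg_truth.events.final_contacts + start)
                stride_tabs.append(seg_truth.strides)
                step_count += seg_truth.step_count
                pos += n_seg
            else:
                n_seg = n_total - pos
                chunks.append(_nonwalk_segment(n_seg, rng, active_toggle))
                pos += n_seg
        else:
            dur = float(np.clip(rng.gamma(4.0, mean_gap / 4.0),
                                5.0, 6 * max(mean_gap, 5.0)))
            if walk_fraction <= 0.001:
                dur = remaining
            dur = min(dur, remaining)
            n_seg = max(1, int(round(dur * fs)))
            n_seg = min(n_seg, n_total - pos)
            chunks.append(_nonwalk_segment(n_seg, rng, active_toggle))
            active_toggle = not active_toggle
            pos += n_seg
        walking = not walking

    accel = np.vstack(chunks)[:n_total]
    t = np.arange(n_total) / fs
    events = GaitEvents(
        initial_contacts=np.concatenate(ic_all) if ic_all else np.empty(0),
        final_contacts=np.concatenate(fc_all) if fc_all else np.empty(0))
    strides = (pd.concat(stride_tabs, ignore_index=True)
               if stride_tabs else pd.DataFrame())
    truth = GroundTruth(events=events, bouts=bouts, strides=strides,
                        step_count=step_count,
                        params={"speed_mps": speed, "stride_time_s": stride_time,
                                "walk_fraction": walk_fraction})
    rec = AccelRecording(time=t, accel=accel, fs=fs, sensor_height=sensor_height)
    return rec, truth


def _subject_params(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Draw subject-level walking parameters, correlated across visits."""
    rho = cfg.visit_retest_rho
    z = rng.normal(size=(2, 2))  # rows: speed, stride_time; cols: latent draws
    mix = np.array([z[:, 0], rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]]).T
    speeds = cfg.speed_mean_mps + cfg.speed_sd_mps * mix[0]
    stride_times = cfg.stride_time_mean_s + cfg.stride_time_sd_s * mix[1]
    return {
        "speed_by_visit": np.clip(speeds, 0.5, 2.2),
        "stride_time_by_visit": np.clip(stride_times, 0.7, 1.6),
        "age": float(np.clip(rng.normal(33.9, 9.1), 20, 70)),
        "height_m": float(np.clip(rng.normal(1.70, 0.09), 1.50, 1.95)),
    }


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Simulate the full study: subjects x visits x tasks x {chest, lumbar}.

    Chest and lumbar channels share identical ground-truth kinematics per
    subject/visit/task; each location's signal amplitude is generated from
    its own pendulum length (so the extraction model inverts it exactly),
    and the channels differ further only by device noise, the configured
    chest amplitude bias, and an orientation jitter.  Fully reproducible
    from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    subj_seqs = root.spawn(config.n_subjects)
    recordings: dict = {}
    truths: dict = {}
    meta_rows: list[dict] = []
    lo_mult, hi_mult = config.speed_multipliers
    multipliers = {"walk_slow": lo_mult, "walk_normal": 1.0, "walk_fast": hi_mult}

    for si, sseq in enumerate(subj_seqs):
        subject = f"S{si + 1:03d}"
        streams = sseq.spawn(1 + config.n_visits)
        params = _subject_params(config, np.random.default_rng(streams[0]))
        for vi in range(config.n_visits):
            visit = vi + 1
            speed_v = float(params["speed_by_visit"][vi])
            stride_v = float(params["stride_time_by_visit"][vi])
            task_seqs = streams[1 + vi].spawn(len(config.tasks))
            for task, tseq in zip(config.tasks, task_seqs):
                mult = multipliers.get(task)
                if mult is not None:
                    speed_t = speed_v * mult
                    stride_t = stride_v / np.sqrt(mult)
                    duration = config.walk_task_duration_s
                    wf = None
                else:
                    speed_t = speed_v
                    stride_t = stride_v
                    if task == "outside_activities":
                        duration = config.outside_activity_duration_s
                        wf = config.outside_walk_fraction
                    else:
                        duration = config.inlab_activity_duration_s
                        wf = config.inlab_walk_fraction
                kin_seq, chest_seq, lumbar_seq = tseq.spawn(3)
                loc_seeds = {"chest": chest_seq, "lumbar": lumbar_seq}
                for location in ("lumbar", "chest"):
                    l_loc = config.height_fraction[location] * params["height_m"]
                    bias = config.chest_bias_mps if location == "chest" else 0.0
                    # shared kinematic stream so both locations walk identically
                    kin_rng = np.random.default_rng(kin_seq)
                    if wf is None:
                        rec, truth = simulate_walk_segment(
                            speed_t + bias, stride_t, duration, l_loc,
                            config.sampling_rate_hz, 0.0, kin_rng)
                    else:
                        rec, truth = simulate_activity_session(
                            duration, wf, speed_t + bias, stride_t, l_loc,
                            config.sampling_rate_hz, 0.0,
                            mean_bout_s=config.mean_bout_duration_s, seed=kin_rng)
                    noise_rng = np.random.default_rng(loc_seeds[location])
                    sd = config.noise_sd_g.get(location, 0.0)
                    accel = rec.accel + noise_rng.normal(0.0, sd, rec.accel.shape)
                    rot = _random_rotation(noise_rng, config.orientation_jitter_deg)
                    accel = accel @ rot.T
                    rec = AccelRecording(
                        time=rec.time, accel=accel, fs=rec.fs, location=location,
                        subject=subject, visit=visit, task=task,
                        sensor_height=l_loc)
                    recordings[(subject, visit, task, location)] = rec
                    if location == "lumbar":
                        # lumbar pass carries no amplitude bias: its truth is
                        # the shared, location-independent kinematics
                        truths[(subject, visit, task)] = truth
                    meta_rows.append({
                        "subject": subject, "visit": visit, "task": task,
                        "location": location, "age": params["age"],
                        "height_m": params["height_m"],
                        "sensor_height_m": l_loc,
                        "true_speed_mps": speed_t, "true_stride_time_s": stride_t,
                    })
    metadata = pd.DataFrame(meta_rows)
    return StudyBundle(recordings=recordings, truths=truths,
                       metadata=metadata, config=config)


def simulate_endpoint_table(
    n_subjects: int = 20,
    devices: tuple[str, ...] = ("chest", "lumbar"),
    tasks: tuple[str, ...] = ("walk_slow", "walk_normal", "walk_fast"),
    grand_mean: float = 1.25,
    device_effects: dict | None = None,
    task_effects: dict | None = None,
    subject_sd: float = 0.12,
    resid_sd: float = 0.05,
    age_beta: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Generate a long endpoint table from the mixed-model generative process.

    value = grand + subject intercept + device effect + task effect
            + age_beta * (age - 34) + residual.

    Used to validate the inferential layer (type-I error, contrast coverage)
    without running the full signal pipeline.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    device_effects = device_effects or {}
    task_effects = task_effects or {}
    rows = []
    for si in range(n_subjects):
        subj = f"S{si + 1:03d}"
        b = rng.normal(0.0, subject_sd)
        age = float(np.clip(rng.normal(33.9, 9.1), 20, 70))
        for dev in devices:
            for task in tasks:
                val = (grand_mean + b + device_effects.get(dev, 0.0)
                       + task_effects.get(task, 0.0) + age_beta * (age - 34.0)
                       + rng.normal(0.0, resid_sd))
                rows.append({"subject": subj, "age": age, "device": dev,
                             "task": task, "value": val})
    return pd.DataFrame(rows)


def simulate_fragmented_bout_stats(
    n_subjects: int = 20,
    split_prob: float = 0.3,
    mean_bouts: float = 20.0,
    mean_duration_s: float = 40.0,
    cadence_spm: float = 110.0,
    measurement_cv: float = 0.02,
    seed: int | np.random.Generator | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bout-level simulation of chest fragmentation of long walking bouts.

    Both devices observe the same true bouts; the chest device splits each
    bout into two with probability ``split_prob`` (preserving total time and
    steps), and both devices measure durations/steps with a small independent
    error.  Returns per-subject bout statistics for chest and lumbar.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chest_rows, lumbar_rows = [], []
    for si in range(n_subjects):
        subj = f"S{si + 1:03d}"
        n_b = rng.poisson(mean_bouts) + 3
        durs = rng.gamma(4.0, mean_duration_s / 4.0, n_b).clip(10.0, None)
        steps = durs * cadence_spm / 60.0

        def measure(d, s):
            d = d * (1 + rng.normal(0, measurement_cv, d.shape))
            s = s * (1 + rng.normal(0, measurement_cv, s.shape))
            return d, s

        ld, ls = measure(durs, steps)
        lumbar_rows.append({"subject": subj, "n_bouts": ld.size,
                            "mean_bout_duration_s": ld.mean(),
                            "total_walking_time_s": ld.sum(),
                            "total_steps": ls.sum()})
        cd, cs = [], []
        for d, s in zip(durs, steps):
            if rng.random() < split_prob:
                frac = rng.uniform(0.3, 0.7)
                cd += [d * frac, d * (1 - frac)]
                cs += [s * frac, s * (1 - frac)]
            else:
                cd.append(d)
                cs.append(s)
        cd, cs = measure(np.array(cd), np.array(cs))
        chest_rows.append({"subject": subj, "n_bouts": cd.size,
                           "mean_bout_duration_s": cd.mean(),
                           "total_walking_time_s": cd.sum(),
                           "total_steps": cs.sum()})
    return pd.DataFrame(chest_rows), pd.DataFrame(lumbar_rows)
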