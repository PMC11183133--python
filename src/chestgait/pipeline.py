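"""Single-sensor gait extraction from a trunk accelerometer.

Stages, run in order by :func:`extract_gait`:

1. vertical-axis estimation (gravity alignment);
2. gait-bout detection from per-3 s-window signal features combined by a
   transparent frozen logistic rule;
3. wavelet-based initial/final contact detection inside each bout
   (integrate the de-meaned vertical acceleration, smooth-differentiate it
   with a first-derivative-of-Gaussian CWT at a scale tied to the dominant
   step frequency; minima mark initial contacts);
4. inverted-pendulum spatial reconstruction: per-step vertical excursion h
   from double integration, step length ``2*sqrt(2*l*h - h^2)``;
5. per-stride parameters, bout filtering and endpoint aggregation.

The pipeline is a pure function of the recording and configuration: it
contains no random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, detrend, find_peaks, periodogram, sosfiltfilt, welch

from .types import (AccelRecording, GaitBout, GaitEvents, GRAVITY_MPS2,
                    STRIDE_COLUMNS, empty_stride_table)

__all__ = [
    "PipelineConfig",
    "estimate_vertical_axis",
    "window_features",
    "detect_gait_bouts",
    "detect_contact_events",
    "compute_vertical_excursion",
    "compute_stride_parameters",
    "filter_bouts",
    "aggregate_endpoints",
    "compute_bout_stats",
    "extract_gait",
]

#: anthropometric pendulum-length fraction of body height per wearing location
HEIGHT_FRACTION = {"chest": 0.72, "lumbar": 0.53}
DEFAULT_BODY_HEIGHT_M = 1.70


@dataclass
class PipelineConfig:
    """Tunable constants of the extraction pipeline."""

    window_s: float = 3.0
    step_band_hz: tuple[float, float] = (0.5, 3.0)
    wavelet: str = "gaus1"
    ic_scale_factor: float = 1.25
    min_band_fraction: float = 0.1       # below: no locomotor component
    highpass_cutoff_hz: float | None = None  # optional pre-filter per step
    stride_time_bounds_s: tuple[float, float] = (0.4, 2.25)
    stride_length_bounds_m: tuple[float, float] = (0.3, 3.0)
    bout_min_duration_s: float = 9.0
    bout_min_cycles: int = 4
    # frozen logistic bout-classifier coefficients:
    # intercept, log10(RMS), locomotor-band power fraction, autocorr peak
    classifier_coefs: tuple[float, float, float, float] = (-6.0, 0.5, 6.0, 6.0)
    classifier_threshold: float = 0.5
    apply_bout_filter_to_endpoints: bool = False


# ---------------------------------------------------------------------------
# orientation

def estimate_vertical_axis(recording: AccelRecording) -> tuple[AccelRecording, np.ndarray]:
    """Rotate the recording so the third channel is gravity-aligned.

    The gravity direction is estimated from the mean specific-force vector;
    a proper rotation (det = +1) mapping it onto +z is applied.  Gravity is
    retained in the rotated vertical channel (its mean stays near 1 g).
    Returns the rotated recording and the rotation matrix.
    """
    if recording.duration_s < 3.0:
        raise ValueError("recording too short for axis estimation (< 3 s)")
    g_vec = recording.accel.mean(axis=0)
    norm = np.linalg.norm(g_vec)
    if norm < 0.5:
        raise ValueError(
            "no stable gravity direction: mean acceleration magnitude "
            f"{norm:.3f} g < 0.5 g")
    u = g_vec / norm
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, ez)
    c = float(u @ ez)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + k + k @ k / (1.0 + c)
    return recording.replace(accel=recording.accel @ rot.T), rot


# ---------------------------------------------------------------------------
# bout detection

def window_features(vert_g: np.ndarray, fs: float,
                    band: tuple[float, float] = (0.5, 3.0)) -> np.ndarray:
    """Features of one window of vertical acceleration (g, gravity included).

    Returns [log10 RMS of dynamic accel, locomotor-band power fraction,
    autocorrelation peak in the step-period lag range].
    """
    x = vert_g - vert_g.mean()
    rms = float(np.sqrt(np.mean(x ** 2)))
    f, p = periodogram(x, fs=fs)
    total = p[1:].sum()
    in_band = (f >= band[0]) & (f <= band[1])
    band_frac = float(p[in_band].sum() / total) if total > 0 else 0.0
    # autocorrelation peak between 0.25 and 1.2 s lag
    n = x.size
    denom = float(x @ x)
    ac_peak = 0.0
    if denom > 0:
        lags = np.arange(int(0.25 * fs), min(int(1.2 * fs), n - 1))
        if lags.size:
            ac = np.array([x[:-k] @ x[k:] for k in lags]) / denom
            ac_peak = float(ac.max())
    return np.array([np.log10(rms + 1e-6), band_frac, ac_peak])


def _classify_windows(rec: AccelRecording, cfg: PipelineConfig) -> np.ndarray:
    nwin = int(rec.accel.shape[0] // (cfg.window_s * rec.fs))
    wlen = int(cfg.window_s * rec.fs)
    b0, b1, b2, b3 = cfg.classifier_coefs
    probs = np.empty(nwin)
    for i in range(nwin):
        feats = window_features(rec.vertical[i * wlen:(i + 1) * wlen], rec.fs,
                                cfg.step_band_hz)
        z = b0 + b1 * feats[0] + b2 * feats[1] + b3 * feats[2]
        probs[i] = 1.0 / (1.0 + np.exp(-z))
    return probs


def detect_gait_bouts(recording: AccelRecording,
                      config: PipelineConfig | None = None) -> list[GaitBout]:
    """Detect walking bouts from per-window gait probabilities.

    The recording is split into consecutive ``window_s`` windows; windows
    whose logistic gait probability exceeds the threshold are flagged and
    adjacent positive windows are merged into maximal bouts with boundaries
    on the window grid.
    """
    cfg = config or PipelineConfig()
    if recording.duration_s < cfg.window_s:
        raise ValueError("recording shorter than one classification window")
    probs = _classify_windows(recording, cfg)
    flags = probs >= cfg.classifier_threshold
    bouts: list[GaitBout] = []
    i = 0
    while i < flags.size:
        if flags[i]:
            j = i
            while j + 1 < flags.size and flags[j + 1]:
                j += 1
            bouts.append(GaitBout(start_s=i * cfg.window_s,
                                  end_s=(j + 1) * cfg.window_s,
                                  window_flags=flags[i:j + 1].copy()))
            i = j + 1
        else:
            i += 1
    return bouts


# ---------------------------------------------------------------------------
# contact events

def _dominant_step_frequency(a_dyn: np.ndarray, fs: float,
                             band: tuple[float, float]) -> tuple[float, float]:
    """Dominant frequency in the locomotor band and the band power fraction."""
    nper = min(a_dyn.size, 1024)
    f, p = welch(a_dyn, fs=fs, nperseg=nper)
    total = p[1:].sum()
    in_band = (f >= band[0]) & (f <= band[1])
    if total <= 0 or not np.any(in_band):
        return 0.0, 0.0
    f_step = float(f[in_band][np.argmax(p[in_band])])
    return f_step, float(p[in_band].sum() / total)


def detect_contact_events(vert_g: np.ndarray, fs: float,
                          config: PipelineConfig | None = None) -> GaitEvents:
    """Wavelet-based initial/final contact detection on a bout segment.

    The de-meaned vertical acceleration is integrated (trapezoid rule) and
    smooth-differentiated with a first-derivative-of-Gaussian CWT at a scale
    matched to 1.25x the dominant step frequency.  Minima of the transform
    mark initial contacts; the transform is differentiated and re-transformed,
    and its maxima mark final contacts.  If the segment has no dominant
    locomotor (0.5-3 Hz) component, empty events are returned with a warning.
    """
    cfg = config or PipelineConfig()
    x = np.asarray(vert_g, dtype=float)
    if x.size < int(fs):
        warnings.warn("segment too short for event detection")
        return GaitEvents()
    a = (x - x.mean()) * GRAVITY_MPS2
    if np.allclose(a, 0.0):
        warnings.warn("constant segment: no gait events")
        return GaitEvents()
    f_step, band_frac = _dominant_step_frequency(a, fs, cfg.step_band_hz)
    if f_step <= 0 or band_frac < cfg.min_band_fraction:
        warnings.warn("no dominant locomotor frequency in 0.5-3 Hz band")
        return GaitEvents()

    v = cumulative_trapezoid(a, dx=1.0 / fs, initial=0.0)
    v = v - v.mean()
    fc_wav = pywt.central_frequency(cfg.wavelet)
    scale = fc_wav * fs / (cfg.ic_scale_factor * f_step)
    coef, _ = pywt.cwt(v, [scale], cfg.wavelet, sampling_period=1.0 / fs)
    c1 = coef[0]  # ~ negative smoothed acceleration

    min_dist = max(1, int(0.5 * fs / f_step))
    prom = 0.3 * np.std(c1)
    ic_idx, _ = find_peaks(-c1, distance=min_dist, prominence=prom)

    dc1 = np.gradient(c1, 1.0 / fs)
    coef2, _ = pywt.cwt(dc1, [scale], cfg.wavelet, sampling_period=1.0 / fs)
    c2 = coef2[0]
    fc_idx, _ = find_peaks(c2, distance=min_dist, prominence=0.3 * np.std(c2))

    ics = ic_idx / fs
    # keep at most one final contact strictly inside each IC-to-IC interval
    fcs = []
    fc_times = fc_idx / fs
    for a_t, b_t in zip(ics[:-1], ics[1:]):
        inside = fc_times[(fc_times > a_t) & (fc_times < b_t)]
        if inside.size:
            fcs.append(float(inside[0]))
    return GaitEvents(initial_contacts=ics, final_contacts=np.array(fcs))


# ---------------------------------------------------------------------------
# spatial reconstruction

def compute_vertical_excursion(segment_mps2: np.ndarray, fs: float,
                               highpass_cutoff: float | None = None) -> float:
    """Per-step vertical centre-of-mass excursion from double integration.

    ``segment_mps2`` is the vertical acceleration between two consecutive
    initial contacts (inclusive of both endpoints), in m/s^2, gravity
    already removed or constant.  Drift is controlled by removing the
    segment mean before each integration and a linear trend from the final
    displacement; an optional zero-phase high-pass can be applied first.
    Returns the peak-to-peak displacement (m, >= 0).
    """
    seg = np.asarray(segment_mps2, dtype=float)
    if seg.size < 3:
        raise ValueError("step segment must have at least 3 samples")
    if highpass_cutoff:
        sos = butter(4, highpass_cutoff / (fs / 2), "high", output="sos")
        seg = sosfiltfilt(sos, seg)
    seg = seg - seg[:-1].mean()
    v = cumulative_trapezoid(seg, dx=1.0 / fs, initial=0.0)
    v = v - v[:-1].mean()
    z = cumulative_trapezoid(v, dx=1.0 / fs, initial=0.0)
    z = detrend(z)
    return float(z.max() - z.min())


def step_length_from_excursion(h: float, l: float) -> float:
    """Inverted-pendulum step length ``2*sqrt(2*l*h - h^2)``."""
    if h < 0 or h >= l:
        raise ValueError("excursion must satisfy 0 <= h < l")
    return 2.0 * np.sqrt(2.0 * l * h - h * h)


def compute_stride_parameters(
    events: GaitEvents,
    excursions: np.ndarray,
    pendulum_length: float,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-stride temporal and spatial parameters from events and excursions.

    ``excursions[i]`` is the vertical excursion of the step between initial
    contacts i and i+1.  A stride spans initial contacts (i, i+2); its length
    is the sum of the two constituent step lengths.  Strides with infeasible
    geometry (h >= l) or implausible values are dropped; the count of
    rejected strides is returned alongside the table.
    """
    cfg = config or PipelineConfig()
    ics = events.initial_contacts
    if ics.size < 2:
        return empty_stride_table(), 0
    excursions = np.asarray(excursions, dtype=float)
    rows, rejected = [], 0
    t_lo, t_hi = cfg.stride_time_bounds_s
    l_lo, l_hi = cfg.stride_length_bounds_m
    for i in range(ics.size - 2):
        h1, h2 = excursions[i], excursions[i + 1]
        stride_time = float(ics[i + 2] - ics[i])
        if h1 >= pendulum_length or h2 >= pendulum_length:
            rejected += 1
            continue
        sl = (step_length_from_excursion(h1, pendulum_length)
              + step_length_from_excursion(h2, pendulum_length))
        if not (t_lo <= stride_time <= t_hi and l_lo <= sl <= l_hi):
            rejected += 1
            continue
        rows.append({
            "ic_time_s": float(ics[i]),
            "stride_time_s": stride_time,
            "stride_length_m": sl,
            "gait_speed_mps": sl / stride_time,
            "cadence_spm": 120.0 / stride_time,
            "vertical_excursion_m": float((h1 + h2) / 2),
            "pendulum_length_m": pendulum_length,
        })
    if not rows:
        return empty_stride_table(), rejected
    return pd.DataFrame(rows), rejected


# ---------------------------------------------------------------------------
# bout bookkeeping

def filter_bouts(bouts: list[GaitBout], min_duration_s: float = 9.0,
                 min_cycles: int = 4) -> tuple[list[GaitBout], dict]:
    """Discard bouts shorter than ``min_duration_s`` or with fewer than
    ``min_cycles`` complete gait cycles; report how many were removed."""
    kept = [b for b in bouts
            if b.duration_s >= min_duration_s and b.n_cycles >= min_cycles]
    n_removed = len(bouts) - len(kept)
    report = {
        "n_input": len(bouts),
        "n_removed": n_removed,
        "pct_removed": 100.0 * n_removed / len(bouts) if bouts else 0.0,
    }
    return kept, report


def compute_bout_stats(bouts: list[GaitBout]) -> dict:
    """Per-recording bout statistics: mean duration, total walking time,
    number of bouts and total steps (initial contacts)."""
    if not bouts:
        return {"n_bouts": 0, "mean_bout_duration_s": 0.0,
                "total_walking_time_s": 0.0, "total_steps": 0}
    durations = np.array([b.duration_s for b in bouts])
    steps = sum(b.events.n_initial if b.events is not None else 0 for b in bouts)
    return {"n_bouts": len(bouts),
            "mean_bout_duration_s": float(durations.mean()),
            "total_walking_time_s": float(durations.sum()),
            "total_steps": int(steps)}


# ---------------------------------------------------------------------------
# aggregation

ACTIVITY_TASK_NAMES = ("simulated_activities", "outside_activities")


def aggregate_endpoints(strides: pd.DataFrame,
                        activity_tasks: tuple[str, ...] = ACTIVITY_TASK_NAMES,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-stride parameters into study endpoints.

    Per subject x task x visit x location, the median of each endpoint is
    taken over all strides pooled across bouts; for activity tasks the 95th
    percentile of gait speed (linear-interpolation quantile) is added.  The
    cross-visit summary averages the per-visit values; a subject/task cell
    observed in a single visit keeps that visit's value.
    Returns (per-visit table, cross-visit table).
    """
    if strides.empty:
        return pd.DataFrame(), pd.DataFrame()
    keys = ["subject", "task", "location", "visit"]
    endpoints = ["gait_speed_mps", "cadence_spm", "stride_time_s", "stride_length_m"]

    rows = []
    for (subject, task, location, visit), g in strides.groupby(keys, sort=True):
        row = {"subject": subject, "task": task, "location": location,
               "visit": visit}
        row.update({ep: g[ep].median() for ep in endpoints})
        row["n_strides"] = len(g)
        row["gait_speed_p95_mps"] = (
            g["gait_speed_mps"].quantile(0.95, interpolation="linear")
            if task in activity_tasks else np.nan)
        rows.append(row)
    per_visit = pd.DataFrame(rows)
    value_cols = endpoints + ["gait_speed_p95_mps"]
    cross = (per_visit.groupby(["subject", "task", "location"], sort=True)[value_cols]
             .mean().reset_index())
    return per_visit, cross


# ---------------------------------------------------------------------------
# end-to-end

@dataclass
class ExtractionResult:
    strides: pd.DataFrame
    bouts: list[GaitBout]
    log: dict = field(default_factory=dict)


def extract_gait(recording: AccelRecording,
                 config: PipelineConfig | None = None) -> ExtractionResult:
    """Run the full extraction on one recording.

    Returns the per-stride table (with recording metadata columns), the
    detected bouts with their events attached, and a processing log.
    """
    cfg = config or PipelineConfig()
    rec, _ = estimate_vertical_axis(recording)
    bouts = detect_gait_bouts(rec, cfg)
    if recording.sensor_height is not None:
        l = recording.sensor_height
    else:
        frac = HEIGHT_FRACTION.get(recording.location or "lumbar", 0.53)
        l = frac * DEFAULT_BODY_HEIGHT_M

    tables = []
    n_rejected = 0
    vert = rec.vertical
    fs = rec.fs
    for bout_id, bout in enumerate(bouts):
        s = int(round(bout.start_s * fs))
        e = int(round(bout.end_s * fs))
        seg = vert[s:e]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev_local = detect_contact_events(seg, fs, cfg)
        ics = ev_local.initial_contacts
        bout.events = GaitEvents(
            initial_contacts=ics + bout.start_s,
            final_contacts=ev_local.final_contacts + bout.start_s)
        if ics.size < 3:
            continue
        a_dyn = (seg - seg.mean()) * GRAVITY_MPS2
        idx = np.round(ics * fs).astype(int)
        excursions = np.array([
            compute_vertical_excursion(a_dyn[idx[i]:idx[i + 1] + 1], fs,
                                       cfg.highpass_cutoff_hz)
            for i in range(idx.size - 1)])
        table, rej = compute_stride_parameters(ev_local, excursions, l, cfg)
        n_rejected += rej
        if not table.empty:
            table["bout_id"] = bout_id
            table["ic_time_s"] += bout.start_s
            tables.append(table)

    if tables:
        strides = pd.concat(tables, ignore_index=True)
    else:
        strides = empty_stride_table()
    for col, val in (("subject", recording.subject), ("visit", recording.visit),
                     ("task", recording.task), ("location", recording.location)):
        strides[col] = val
    strides = strides.reindex(columns=STRIDE_COLUMNS)
    log = {
        "n_bouts": len(bouts),
        "n_strides": int(len(strides)),
        "n_strides_rejected": int(n_rejected),
        "pendulum_length_m": float(l),
        "window_s": cfg.window_s,
        "bout_min_duration_s": cfg.bout_min_duration_s,
        "bout_min_cycles": cfg.bout_min_cycles,
    }
    return ExtractionResult(strides=strides, bouts=bouts, log=log)
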