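"""Velocity-threshold saccade detection and trial-inclusion rules.

Saccades are detected offline from 1 kHz gaze traces with a velocity-threshold
algorithm in the Engbert–Kliegl family: sample-to-sample velocity is smoothed
with a 20-sample moving average, and samples whose speed exceeds the median of
the smoothed speed by ``k`` robust standard deviations (median-absolute-
deviation based, k = 3 by default) for at least 20 ms form a saccade event.
The scalar speed (Euclidean norm of 2D velocity) is thresholded; an elliptic
component-wise criterion is available via ``criterion="elliptic"``.

Trial inclusion follows the experiment's rules: stable fixation within 1.75°
of the fixation point (until the response phase on fixation trials, until cue
onset on saccade trials); on saccade trials the first saccade after cue onset
must start 150–350 ms after the cue, land within 2.25° of the target centre,
and start only after stimulus offset.  The first violated rule labels the
trial; violating trials are repeated at the end of the block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SaccadeEvent",
    "detect_saccades",
    "classify_trial",
    "summarize_saccades",
    "QC_INCLUDED",
]

QC_INCLUDED = "included"
QC_REFIX = "refix_abort"
QC_LAT_SHORT = "latency_short"
QC_LAT_LONG = "latency_long"
QC_LANDING = "landing_out"
QC_BEFORE_OFFSET = "saccade_before_offset"

QC_STATUSES = (
    QC_INCLUDED,
    QC_REFIX,
    QC_LAT_SHORT,
    QC_LAT_LONG,
    QC_LANDING,
    QC_BEFORE_OFFSET,
)


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade."""

    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    landing_x: float
    landing_y: float
    peak_velocity: float  # deg/s

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.full(window, 1.0 / window)
    # reflect-pad so the average stays centered at the edges
    pad = window // 2
    xp = np.pad(x, (pad, window - 1 - pad), mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def detect_saccades(
    time_ms: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    window: int = 20,
    k: float = 3.0,
    min_duration_ms: float = 20.0,
    criterion: str = "speed",
) -> list[SaccadeEvent]:
    """Detect saccades in a uniformly sampled gaze trace.

    Parameters
    ----------
    time_ms, x, y
        Sample times (ms, uniform spacing) and gaze position (deg).
    window
        Moving-average length in samples for velocity smoothing.
    k
        Threshold in robust standard deviations above the median speed.
    min_duration_ms
        Minimum supra-threshold run length to count as a saccade.
    criterion
        ``"speed"`` thresholds the scalar speed; ``"elliptic"`` uses the
        component-wise elliptic criterion (vx/ηx)² + (vy/ηy)² > 1.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if time_ms.size == 0:
        raise ValueError("empty gaze trace")
    if time_ms.size <= window:
        raise ValueError("gaze trace shorter than the smoothing window")
    dt = float(np.median(np.diff(time_ms)))  # ms per sample

    vx = _moving_average(np.gradient(x, time_ms) * 1000.0, window)  # deg/s
    vy = _moving_average(np.gradient(y, time_ms) * 1000.0, window)

    if criterion == "speed":
        speed = np.hypot(vx, vy)
        med = np.median(speed)
        sigma = 1.4826 * np.median(np.abs(speed - med))
        above = speed > med + k * max(sigma, 1e-12)
    elif criterion == "elliptic":
        eta = []
        for v in (vx, vy):
            med = np.median(v)
            sig = 1.4826 * np.median(np.abs(v - med))
            eta.append((med, k * max(sig, 1e-12)))
        above = ((vx - eta[0][0]) / eta[0][1]) ** 2 + (
            (vy - eta[1][0]) / eta[1][1]
        ) ** 2 > 1.0
        speed = np.hypot(vx, vy)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    min_samples = int(round(min_duration_ms / dt))
    events: list[SaccadeEvent] = []
    # maximal supra-threshold runs
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_samples:
            continue
        stop_i = min(stop, x.size - 1)
        events.append(
            SaccadeEvent(
                onset_ms=float(time_ms[start]),
                offset_ms=float(time_ms[stop_i]),
                amplitude_deg=float(
                    np.hypot(x[stop_i] - x[start], y[stop_i] - y[start])
                ),
                landing_x=float(x[stop_i]),
                landing_y=float(y[stop_i]),
                peak_velocity=float(speed[start:stop].max()),
            )
        )
    return events


def classify_trial(
    time_ms: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    events: list[SaccadeEvent],
    instruction: str,
    cue_onset_ms: float,
    stim_offset_ms: float,
    response_ms: float,
    target_xy: tuple[float, float] | None = None,
    fixation_xy: tuple[float, float] = (0.0, 0.0),
    fixation_radius: float = 1.75,
    target_radius: float = 2.25,
    latency_window_ms: tuple[float, float] = (150.0, 350.0),
) -> dict:
    """Apply the trial-inclusion rules; returns qc_status plus saccade metrics.

    Rules are applied in order and the first violation labels the trial:
    fixation before the cue (both instructions; until the response phase on
    fixation trials), saccade latency in [150, 350] ms, landing within 2.25°
    of the target, onset after stimulus offset.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dist_fix = np.hypot(x - fixation_xy[0], y - fixation_xy[1])

    out = {
        "qc_status": QC_INCLUDED,
        "latency_ms": np.nan,
        "amplitude_deg": np.nan,
        "landing_error_deg": np.nan,
        "peak_velocity": np.nan,
    }

    fix_until = response_ms if instruction == "fixation" else cue_onset_ms
    pre = time_ms < fix_until
    if np.any(dist_fix[pre] > fixation_radius):
        out["qc_status"] = QC_REFIX
        return out
    if instruction == "fixation":
        return out

    if target_xy is None:
        raise ValueError("saccade trial requires a target position")
    post_cue = [e for e in events if e.onset_ms >= cue_onset_ms]
    if not post_cue:
        # no saccade within the trial window: treat as a too-late saccade
        out["qc_status"] = QC_LAT_LONG
        return out
    first = post_cue[0]
    latency = first.onset_ms - cue_onset_ms
    landing_err = float(
        np.hypot(first.landing_x - target_xy[0], first.landing_y - target_xy[1])
    )
    out.update(
        latency_ms=float(latency),
        amplitude_deg=first.amplitude_deg,
        landing_error_deg=landing_err,
        peak_velocity=first.peak_velocity,
    )
    if latency < latency_window_ms[0]:
        out["qc_status"] = QC_LAT_SHORT
    elif latency > latency_window_ms[1]:
        out["qc_status"] = QC_LAT_LONG
    elif landing_err > target_radius:
        out["qc_status"] = QC_LANDING
    elif first.onset_ms <= stim_offset_ms:
        out["qc_status"] = QC_BEFORE_OFFSET
    return out


def summarize_saccades(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-direction saccade parameter summary over included saccade trials.

    Returns one row per saccade direction with per-participant means averaged
    with equal participant weight: latency (ms), amplitude (deg) and landing
    error / precision (deg).  Directions with no included trials are flagged
    with ``n_trials = 0`` and NaN means.
    """
    sac = trials[
        (trials["instruction"] == "saccade") & (trials["qc_status"] == QC_INCLUDED)
    ]
    rows = []
    for direction in sorted(trials.loc[trials["instruction"] == "saccade", "direction"].unique()):
        sub = sac[sac["direction"] == direction]
        per_part = sub.groupby("participant")[
            ["latency_ms", "amplitude_deg", "landing_error_deg"]
        ].mean()
        rows.append(
            {
                "direction": direction,
                "n_trials": int(len(sub)),
                "latency_ms": per_part["latency_ms"].mean(),
                "amplitude_deg": per_part["amplitude_deg"].mean(),
                "landing_error_deg": per_part["landing_error_deg"].mean(),
            }
        )
    return pd.DataFrame(rows)
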