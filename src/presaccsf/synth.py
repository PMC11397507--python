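"""Synthetic observers, Bernoulli trial responses, and 1 kHz gaze traces.

The generator emulates the experiment end-to-end so every analysis stage can
be exercised without any recorded data: 12 participants view Gabor stimuli at
6° eccentricity at four cardinal locations (left/right merged to "horizontal"
for analysis) under a fixation and a saccade-preparation instruction, with
stimuli placed adaptively by the qCSF rule on a 60-contrast x 12-SF grid and
responses drawn from the psychometric model on a ground-truth log-parabola CSF
per (participant, location, instruction) "individual" (12 x 3 x 2 = 72 units).

Ground-truth CSFs build in the known anisotropies and presaccadic effects:
peak-CS ordered horizontal > lower > upper (HVA/VMA), a presaccadic peak-CS
boost that is largest at the horizontal meridian, a presaccadic increase in
peak-SF (hence cutoff-SF) and a bandwidth narrowing.  Effect sizes are
configuration, not code: see :class:`EffectConfig`.

Saccade trials carry a 1 kHz gaze trace with slow ocular drift and one cued
saccade whose latency is drawn per direction (means taken from measured group
latencies: up 209.2, down 228.0, horizontal 217.2 ms) and whose trajectory is
a minimum-jerk position ramp — any profile with a clear velocity peak is
detectable by the velocity-threshold algorithm; minimum jerk is a standard
smooth choice.  Trials excluded by the gaze rules are repeated at the end of
the block and never update the adaptive posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .csf import CSFParams, PARAM_BOUNDS, p_correct
from .eye import QC_INCLUDED, classify_trial, detect_saccades
from .qcsf import ParamGrid, QCSFEngine, StimulusSpace, build_stimulus_space

__all__ = [
    "LOCATIONS",
    "INSTRUCTIONS",
    "DIRECTIONS",
    "ExperimentConfig",
    "EffectConfig",
    "ObserverSpec",
    "GazeTrace",
    "make_population",
    "simulate_response",
    "simulate_gaze_trace",
    "simulate_experiment",
]

LOCATIONS = ("upper", "lower", "horizontal")
INSTRUCTIONS = ("fixation", "saccade")
DIRECTIONS = ("up", "down", "left", "right")
_DIRECTION_VECTORS = {
    "up": (0.0, 1.0),
    "down": (0.0, -1.0),
    "left": (-1.0, 0.0),
    "right": (1.0, 0.0),
}
_LOCATION_DIRECTIONS = {
    "upper": ("up",),
    "lower": ("down",),
    "horizontal": ("left", "right"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Geometry, timing and session-size constants of the experiment."""

    n_participants: int = 12
    trials_per_individual: int = 300
    eccentricity_deg: float = 6.0
    stim_radius_deg: float = 2.0
    cue_to_stim_ms: float = 140.0
    stim_duration_ms: float = 30.0
    response_delay_ms: float = 450.0
    fixation_radius_deg: float = 1.75
    target_radius_deg: float = 2.25
    latency_window_ms: tuple[float, float] = (150.0, 350.0)
    sample_rate_hz: float = 1000.0
    trace_start_ms: float = -300.0
    trace_end_ms: float = 900.0
    max_requeue_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_individual < 1:
            raise ValueError("design sizes must be positive")
        for v in (
            self.cue_to_stim_ms,
            self.stim_duration_ms,
            self.response_delay_ms,
            self.fixation_radius_deg,
            self.target_radius_deg,
        ):
            if v <= 0:
                raise ValueError("durations and windows must be positive")

    @property
    def stim_onset_ms(self) -> float:
        return self.cue_to_stim_ms

    @property
    def stim_offset_ms(self) -> float:
        return self.cue_to_stim_ms + self.stim_duration_ms

    @property
    def response_ms(self) -> float:
        return self.stim_offset_ms + self.response_delay_ms


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth population effects (multiplicative, on linear scales).

    Defaults define the study conditions the generator emulates; all are
    configuration.  ``location_peak_cs`` orders the meridians
    horizontal > lower > upper; ``saccade_peak_cs`` applies only under the
    saccade instruction and is largest at the horizontal meridian;
    ``saccade_peak_sf`` > 1 shifts the CSF to higher SFs and
    ``saccade_bandwidth`` < 1 narrows it.  ``participant_sd_log10`` is the SD
    of lognormal participant noise per parameter (log10 units).
    """

    base_peak_cs: float = 40.0
    base_peak_sf: float = 1.3
    base_bandwidth: float = 2.0
    location_peak_cs: dict = field(
        default_factory=lambda: {"upper": 0.75, "lower": 0.95, "horizontal": 1.25}
    )
    saccade_peak_cs: dict = field(
        default_factory=lambda: {"upper": 1.15, "lower": 1.15, "horizontal": 1.40}
    )
    saccade_peak_sf: float = 1.25
    saccade_bandwidth: float = 0.85
    participant_sd_log10: tuple[float, float, float] = (0.08, 0.05, 0.03)
    latency_mean_ms: dict = field(
        default_factory=lambda: {
            "up": 209.159,
            "down": 228.015,
            "left": 217.178,
            "right": 217.178,
        }
    )
    latency_sd_ms: float = 25.0
    landing_scatter_sd_deg: float = 0.5

    def __post_init__(self) -> None:
        mults = (
            [self.base_peak_cs, self.base_peak_sf, self.base_bandwidth]
            + list(self.location_peak_cs.values())
            + list(self.saccade_peak_cs.values())
            + [self.saccade_peak_sf, self.saccade_bandwidth]
        )
        if any(m <= 0 for m in mults):
            raise ValueError("effect multipliers must be positive")


@dataclass(frozen=True)
class ObserverSpec:
    """Ground truth for one participant: a CSF per (location, instruction)
    plus oculomotor parameters."""

    participant: int
    truth: dict  # (location, instruction) -> CSFParams
    latency_mean_ms: dict  # direction -> ms
    latency_sd_ms: float
    landing_scatter_sd_deg: float


@dataclass
class GazeTrace:
    """1 kHz gaze samples for one trial; time is relative to cue onset."""

    trial_id: int
    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    markers: dict


def _clamped_params(log_vec: np.ndarray) -> CSFParams:
    lo, hi = PARAM_BOUNDS[:, 0], PARAM_BOUNDS[:, 1]
    margin = 1e-6
    if np.any(log_vec < lo) or np.any(log_vec > hi):
        warnings.warn(
            f"ground-truth parameters {log_vec} clamped to truncation bounds",
            stacklevel=3,
        )
        log_vec = np.clip(log_vec, lo + margin, hi - margin)
    return CSFParams(*log_vec)


def make_population(
    config: ExperimentConfig,
    effects: EffectConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[ObserverSpec]:
    """Draw the ground-truth population of observers.

    Per-individual truth = population base x location factors x instruction
    factors x lognormal participant noise, clamped (with a warning) to the
    parameter truncation boxes.
    """
    effects = effects if effects is not None else EffectConfig()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    population = []
    for p in range(1, config.n_participants + 1):
        noise = rng.normal(0.0, effects.participant_sd_log10, size=3)
        truth = {}
        for loc in LOCATIONS:
            for instr in INSTRUCTIONS:
                peak_cs = effects.base_peak_cs * effects.location_peak_cs[loc]
                peak_sf = effects.base_peak_sf
                bandwidth = effects.base_bandwidth
                if instr == "saccade":
                    peak_cs *= effects.saccade_peak_cs[loc]
                    peak_sf *= effects.saccade_peak_sf
                    bandwidth *= effects.saccade_bandwidth
                log_vec = np.log10([peak_cs, peak_sf, bandwidth]) + noise
                truth[(loc, instr)] = _clamped_params(log_vec)
        population.append(
            ObserverSpec(
                participant=p,
                truth=truth,
                latency_mean_ms=dict(effects.latency_mean_ms),
                latency_sd_ms=effects.latency_sd_ms,
                landing_scatter_sd_deg=effects.landing_scatter_sd_deg,
            )
        )
    return population


def simulate_response(
    params: CSFParams, sf: float, contrast: float, rng: np.random.Generator
) -> int:
    """One Bernoulli response with probability p_correct(params, sf, contrast)."""
    return int(rng.random() < float(p_correct(params, sf, contrast)))


def _min_jerk(u: np.ndarray) -> np.ndarray:
    return 10.0 * u**3 - 15.0 * u**4 + 6.0 * u**5


def simulate_gaze_trace(
    trial_id: int,
    instruction: str,
    direction: str | None,
    latency_ms: float | None,
    config: ExperimentConfig,
    spec: ObserverSpec,
    rng: np.random.Generator,
    drift_step_deg: float = 0.0015,
) -> GazeTrace:
    """Simulate one trial's gaze trace (time relative to cue onset = 0 ms).

    Fixation trials contain slow random-walk drift only; saccade trials add,
    at the sampled latency, a minimum-jerk ramp from fixation to the target
    plus isotropic Gaussian landing scatter.  The ramp duration scales with
    amplitude (clipped to 30–50 ms), giving a peak velocity far above the
    detection threshold by construction.
    """
    dt = 1000.0 / config.sample_rate_hz
    time_ms = np.arange(config.trace_start_ms, config.trace_end_ms, dt)
    n = time_ms.size
    drift = np.cumsum(rng.normal(0.0, drift_step_deg, size=(n, 2)), axis=0)
    drift -= drift[0]
    x = drift[:, 0].copy()
    y = drift[:, 1].copy()
    markers = {
        "cue_onset_ms": 0.0,
        "stim_onset_ms": config.stim_onset_ms,
        "stim_offset_ms": config.stim_offset_ms,
        "response_ms": config.response_ms,
    }
    if instruction == "saccade":
        if direction is None or latency_ms is None:
            raise ValueError("saccade trial requires direction and latency")
        ux, uy = _DIRECTION_VECTORS[direction]
        scatter = rng.normal(0.0, spec.landing_scatter_sd_deg, size=2)
        tx = ux * config.eccentricity_deg + scatter[0]
        ty = uy * config.eccentricity_deg + scatter[1]
        amplitude = float(np.hypot(tx, ty))
        duration = float(np.clip(21.0 + 2.2 * amplitude, 30.0, 50.0))
        u = np.clip((time_ms - latency_ms) / duration, 0.0, 1.0)
        ramp = _min_jerk(u)
        x = x + ramp * tx
        y = y + ramp * ty
        markers["true_latency_ms"] = float(latency_ms)
        markers["target_xy"] = (
            ux * config.eccentricity_deg,
            uy * config.eccentricity_deg,
        )
    return GazeTrace(trial_id=trial_id, time_ms=time_ms, x=x, y=y, markers=markers)


def _individual_units(config: ExperimentConfig):
    for p in range(1, config.n_participants + 1):
        for loc in LOCATIONS:
            for instr in INSTRUCTIONS:
                yield p, loc, instr


def simulate_experiment(
    population: list[ObserverSpec],
    config: ExperimentConfig,
    seed: int = 0,
    grid: ParamGrid | None = None,
    space: StimulusSpace | None = None,
    qc: str = "detect",
    keep_gaze: str = "none",
) -> tuple[pd.DataFrame, list[GazeTrace] | None]:
    """Run the full adaptive experiment for every individual unit.

    Per individual (participant x location x instruction) the qCSF engine
    selects each stimulus by maximum expected information gain; the gaze trace
    is simulated and screened by the detection/QC rules; excluded trials are
    repeated at the end of the block (the adaptive posterior is updated only
    on included trials).  The session stops after ``trials_per_individual``
    included trials or ``max_requeue_factor`` times that many presentations.

    Parameters
    ----------
    qc
        ``"detect"`` runs the full gaze simulation + saccade detection + the
        inclusion rules; ``"none"`` skips gaze entirely (all trials included).
    keep_gaze
        ``"none"`` or ``"all"`` (return every simulated trace).

    Returns
    -------
    (trial table, gaze traces or None)
    """
    if qc not in ("detect", "none"):
        raise ValueError("qc must be 'detect' or 'none'")
    if keep_gaze not in ("none", "all"):
        raise ValueError("keep_gaze must be 'none' or 'all'")
    if not population:
        raise ValueError("population is empty")
    space = space if space is not None else build_stimulus_space()
    engine = QCSFEngine(grid=grid, space=space)
    by_participant = {obs.participant: obs for obs in population}

    master = np.random.SeedSequence(seed)
    unit_list = list(_individual_units(config))
    streams = master.spawn(len(unit_list))

    rows = []
    traces: list[GazeTrace] | None = [] if keep_gaze == "all" else None
    trial_id = 0
    cap = int(config.max_requeue_factor * config.trials_per_individual)
    for (p, loc, instr), ss in zip(unit_list, streams):
        obs = by_participant[p]
        params = obs.truth[(loc, instr)]
        rng = np.random.default_rng(ss)
        engine.posterior = engine.grid.uniform_prior()
        engine.n_updates = 0
        included = 0
        attempts = 0
        while included < config.trials_per_individual and attempts < cap:
            attempts += 1
            stim_idx = engine.select_stimulus()
            sf = float(space.sf[stim_idx])
            contrast = float(space.contrast[stim_idx])
            direction = (
                str(rng.choice(_LOCATION_DIRECTIONS[loc]))
                if instr == "saccade"
                else None
            )
            row = {
                "trial_id": trial_id,
                "participant": p,
                "location": loc,
                "instruction": instr,
                "direction": direction if direction else "",
                "sf": sf,
                "contrast": contrast,
                "stim_onset_ms": config.stim_onset_ms,
                "stim_offset_ms": config.stim_offset_ms,
                "true_latency_ms": np.nan,
                "latency_ms": np.nan,
                "amplitude_deg": np.nan,
                "landing_error_deg": np.nan,
                "qc_status": QC_INCLUDED,
            }
            if qc == "detect":
                latency = (
                    float(
                        rng.normal(
                            obs.latency_mean_ms[direction], obs.latency_sd_ms
                        )
                    )
                    if instr == "saccade"
                    else None
                )
                trace = simulate_gaze_trace(
                    trial_id, instr, direction, latency, config, obs, rng
                )
                events = detect_saccades(trace.time_ms, trace.x, trace.y)
                qc_out = classify_trial(
                    trace.time_ms,
                    trace.x,
                    trace.y,
                    events,
                    instr,
                    cue_onset_ms=0.0,
                    stim_offset_ms=config.stim_offset_ms,
                    response_ms=config.response_ms,
                    target_xy=trace.markers.get("target_xy"),
                    fixation_radius=config.fixation_radius_deg,
                    target_radius=config.target_radius_deg,
                    latency_window_ms=config.latency_window_ms,
                )
                row.update(qc_out)
                if latency is not None:
                    row["true_latency_ms"] = latency
                if traces is not None:
                    traces.append(trace)
            response = simulate_response(params, sf, contrast, rng)
            row["response"] = response
            if row["qc_status"] == QC_INCLUDED:
                engine.update(stim_idx, response)
                included += 1
            rows.append(row)
            trial_id += 1

    trials = pd.DataFrame(rows)
    trials["seed"] = seed
    return trials, traces


def config_to_dict(config: ExperimentConfig, effects: EffectConfig) -> dict:
    """Serializable snapshot of the generator configuration."""
    d = {"experiment": asdict(config), "effects": asdict(effects)}
    d["experiment"]["latency_window_ms"] = list(config.latency_window_ms)
    return d
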