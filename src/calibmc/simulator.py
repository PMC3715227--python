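"""Synthetic multi-sensor session generator.

The generator emulates the statistical structure a multi-sensor non-invasive
CGM study produces: 45 sessions over 6 diabetic subjects, ~8 h each sampled
every 20 s on C channels, sparse fingerprick reference glucose (RBG) every
10–20 min, glucose held euglycaemic for a 75-min equilibration and then
induced to follow smooth excursions, sweat events producing a fast rise /
slow decay transient (with a possible persistent offset) on a designated
sweat-sensitive channel and a partial leakage into the glucose-related
channels, and subject-specific calibration baselines spanning roughly
±25 mg/dL.

The generative channel model is, for a glucose-related channel c,

    x_c(t) = gain_c · (g(t) + b_true − G0 + step(t)) + κ_c · s(t)
             + drift_c(t) + noise_c(t)

where g is true glucose, b_true the session's calibration baseline
(realised inside the channels so that the Eq.-2 style calibration recovers
it), G0 a fixed population centring constant, s(t) the sweat transient and
step(t) an optional uncompensated baseline drift step used by the
calibration-scheduling scenario.  The sweat-sensitive channel records s(t)
directly, so with shared gains/κ across subjects the leakage is exactly
representable (hence compensable) by a population linear model; at least
one channel is pure nuisance (gain = κ = 0).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .session_io import (
    DatasetManifest,
    ManifestEntry,
    Session,
    split_dataset,
    write_manifest,
    write_session,
)

__all__ = [
    "SubjectProfile",
    "SweatEventSpec",
    "SimulationConfig",
    "SessionTruth",
    "simulate_glucose",
    "simulate_sweat_signal",
    "simulate_channels",
    "simulate_rbg",
    "make_profiles",
    "exact_population_model",
    "simulate_sessions",
    "generate_dataset",
    "GLUCOSE_CENTER",
    "SWEAT_BASELINE",
]

#: population centring constant for glucose-related channels (mg/dL)
GLUCOSE_CENTER = 120.0
#: resting level of the sweat-sensitive channel (a.u.)
SWEAT_BASELINE = 10.0


@dataclass
class SubjectProfile:
    """Per-subject couplings of the generative channel model.

    ``channel_gains`` and ``sweat_leakage`` are device properties shared
    across the default subjects — a single population regression model can
    only exist if the channel couplings are common; per-subject variation
    would be a model-mismatch study, which is out of scope here.  What *is*
    subject-specific is the calibration baseline: per-session ``b_true`` is
    drawn as ``baseline_offset + N(0, baseline_sd²)``.
    """

    subject_id: str
    baseline_offset: float  # mg/dL, subject mean of the calibration parameter
    baseline_sd: float  # mg/dL, session-to-session spread
    channel_gains: np.ndarray  # a.u. per mg/dL, length C
    sweat_leakage: np.ndarray  # κ, a.u. per a.u. of sweat signal, length C
    noise_sd: np.ndarray  # a.u., length C


@dataclass
class SweatEventSpec:
    """One sweat transient: linear rise, exponential decay, optional offset."""

    onset_s: float
    rise_duration_s: float
    decay_duration_s: float
    amplitude: float  # a.u., > 0
    persistent_offset: float = 0.0  # a.u.; the level does not always return

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("sweat event amplitude must be > 0")
        if self.rise_duration_s <= 0 or self.decay_duration_s <= 0:
            raise ValueError("sweat event durations must be > 0")


@dataclass
class SimulationConfig:
    """Study conditions of the emulated multi-sensor trial."""

    n_subjects: int = 6
    n_sessions: int = 45
    duration_s: float = 8 * 3600.0
    dt_s: float = 20.0
    equilibration_s: float = 75 * 60.0
    rbg_interval_s: tuple[float, float] = (600.0, 1200.0)  # 10–20 min
    rbg_noise_cv: float = 0.02
    sweat_event_rate: float = 2.0  # mean events per session
    n_channels: int = 150
    sweat_channel: int = 36
    n_glucose_channels: int = 30
    channel_noise_sd: float = 0.05  # a.u.
    drift_sd: float = 0.3  # a.u., slow-drift amplitude scale
    baseline_span_mgdl: float = 25.0  # subject means span ±this
    baseline_sd_mgdl: float = 4.0
    sweat_leakage_scale: float = 1.0  # 0 → fully compensated device (κ = 0)
    excursion_amplitude: float = 1.0  # 0 → constant euglycaemic profile
    drift_step_mgdl: float = 0.0  # uncompensated step for the Tc scenario
    drift_step_after_t0_s: float = 55 * 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= self.equilibration_s:
            raise ValueError("equilibration must be shorter than the session")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("durations must be positive")
        lo, hi = self.rbg_interval_s
        if not (0 < lo <= hi < self.duration_s):
            raise ValueError("rbg_interval_s outside (0, duration)")
        if self.n_channels < 3:
            raise ValueError("need ≥3 channels (glucose, sweat, nuisance)")
        if self.sweat_channel >= self.n_channels:
            raise ValueError("sweat_channel index out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s / self.dt_s))

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_s


@dataclass
class SessionTruth:
    """Ground-truth sidecar for one generated session."""

    session_id: str
    subject_id: str
    true_glucose: np.ndarray  # mg/dL on the session grid
    events: list[SweatEventSpec]
    b_true: float  # mg/dL
    drift_step_time_s: float | None = None


def _session_seed(master_seed: int, session_id: str, stream: int) -> np.random.SeedSequence:
    """Stable per-session substream: reproducible independent of order."""
    h = zlib.crc32(session_id.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h, stream])


# ---------------------------------------------------------------------------
# glucose profile
# ---------------------------------------------------------------------------

def simulate_glucose(
    duration_s: float,
    dt_s: float,
    equilibration_s: float,
    seed: int | np.random.SeedSequence,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Simulate an induced glucose profile on the session grid (mg/dL).

    Constant euglycaemic plateau (drawn in 90–140 mg/dL) before the
    equilibration time, then a sum of logistic ramps toward randomly drawn
    plateau levels covering the hypo/eu/hyper range, bounded in
    [40, 400] mg/dL.  ``amplitude`` scales the excursions; 0 gives a
    constant profile.  Deterministic given the seed.
    """
    if equilibration_s >= duration_s:
        raise ValueError("equilibration must be shorter than the session")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s / dt_s))) * dt_s
    level0 = rng.uniform(90.0, 140.0)
    n_ramps = max(1, int((duration_s - equilibration_s) / 3600.0))
    # first ramp centre well past equilibration so the plateau is clean
    centres = equilibration_s + 2700.0 + np.linspace(
        0.0, max(duration_s - equilibration_s - 5400.0, 0.0), n_ramps
    )
    centres = centres + rng.uniform(-600.0, 600.0, n_ramps)
    widths = rng.uniform(240.0, 420.0, n_ramps)
    targets = rng.uniform(60.0, 300.0, n_ramps)
    levels = np.concatenate([[level0], level0 + amplitude * (targets - level0)])
    g = np.full_like(t, level0, dtype=float)
    for k in range(n_ramps):
        g += (levels[k + 1] - levels[k]) * expit((t - centres[k]) / widths[k])
    g[t < equilibration_s] = level0  # exact plateau by construction
    return np.clip(g, 40.0, 400.0)


# ---------------------------------------------------------------------------
# sweat transients and channel matrix
# ---------------------------------------------------------------------------

def simulate_sweat_signal(t: np.ndarray, specs: Sequence[SweatEventSpec]) -> np.ndarray:
    """Superpose sweat transients on a time grid (a.u.).

    Each event rises linearly from 0 to ``amplitude`` over
    ``rise_duration_s`` and decays exponentially toward its
    ``persistent_offset`` with time constant ``decay_duration_s``.
    """
    s = np.zeros_like(t, dtype=float)
    for ev in specs:
        if not (t[0] <= ev.onset_s <= t[-1]):
            raise ValueError(f"event onset {ev.onset_s} outside grid")
        rel = t - ev.onset_s
        rise = np.clip(rel / ev.rise_duration_s, 0.0, 1.0) * ev.amplitude
        after = rel - ev.rise_duration_s
        decay = np.where(
            after > 0,
            ev.persistent_offset
            + (ev.amplitude - ev.persistent_offset)
            * np.exp(-np.maximum(after, 0.0) / ev.decay_duration_s)
            - ev.amplitude,
            0.0,
        )
        s += rise + decay
    return s


def simulate_channels(
    glucose: np.ndarray,
    profile: SubjectProfile,
    sweat_specs: Sequence[SweatEventSpec],
    dt_s: float,
    seed: int | np.random.SeedSequence,
    b_true: float | None = None,
    drift_sd: float = 0.3,
    baseline_step: tuple[float, float] | None = None,
) -> tuple[np.ndarray, int]:
    """Build the C × T channel matrix for one session.

    Glucose-related channels couple the baseline-shifted glucose signal
    with gain ``channel_gains[c]`` plus κ·sweat leakage, a slow sinusoidal
    drift and white noise; the sweat channel (the index with gain 0 and the
    largest direct sweat coupling, by convention the profile's designated
    one) carries the raw transient on a constant resting level; remaining
    channels are pure nuisance.  ``baseline_step`` = (time_s, step_mgdl)
    injects an uncompensated calibration drift into every glucose channel.

    Returns the matrix and the sweat-channel index.
    """
    rng = np.random.default_rng(seed)
    gains = np.asarray(profile.channel_gains, dtype=float)
    kappa = np.asarray(profile.sweat_leakage, dtype=float)
    noise_sd = np.broadcast_to(
        np.asarray(profile.noise_sd, dtype=float), gains.shape
    )
    n_channels = gains.size
    t = np.arange(glucose.size) * dt_s
    sweat_candidates = np.flatnonzero(kappa < 0)  # sentinel κ = −1 marks it
    sweat_idx = int(sweat_candidates[0]) if sweat_candidates.size else -1
    s = simulate_sweat_signal(t, sweat_specs)
    if b_true is None:
        b_true = profile.baseline_offset + rng.normal(0.0, profile.baseline_sd)
    signal = glucose + b_true - GLUCOSE_CENTER
    if baseline_step is not None:
        step_time, step_mgdl = baseline_step
        signal = signal + step_mgdl * (t >= step_time)

    X = np.empty((n_channels, glucose.size))
    # slow sinusoidal drifts, one per channel
    drift_amp = np.abs(rng.normal(0.0, drift_sd, n_channels))
    drift_period = rng.uniform(2 * 3600.0, 8 * 3600.0, n_channels)
    drift_phase = rng.uniform(0.0, 2 * np.pi, n_channels)
    noise = rng.normal(0.0, 1.0, X.shape) * noise_sd[:, None]
    for c in range(n_channels):
        drift = drift_amp[c] * np.sin(2 * np.pi * t / drift_period[c] + drift_phase[c])
        if c == sweat_idx:
            X[c] = SWEAT_BASELINE + s + noise[c]
        else:
            X[c] = gains[c] * signal + kappa[c] * s + drift + noise[c]
    return X, sweat_idx


# ---------------------------------------------------------------------------
# reference glucose sampling
# ---------------------------------------------------------------------------

def simulate_rbg(
    glucose: np.ndarray,
    dt_s: float,
    interval_range_s: tuple[float, float],
    noise_cv: float,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample sparse fingerprick references from a true glucose series.

    Convention: the first RBG is taken at t = 0 (device placement), later
    ones at cumulative gaps drawn i.i.d. uniform in ``interval_range_s``,
    while they fit inside the session.  Values are true glucose at the
    nearest grid sample times (1 + ε), ε ~ N(0, noise_cv²), floored to stay
    positive.
    """
    lo, hi = interval_range_s
    t_end = (glucose.size - 1) * dt_s
    if not (0 < lo <= hi < t_end):
        raise ValueError("interval_range outside (0, duration)")
    rng = np.random.default_rng(seed)
    times = [0.0]
    while True:
        nxt = times[-1] + rng.uniform(lo, hi)
        if nxt > t_end:
            break
        times.append(nxt)
    times = np.asarray(times)
    idx = np.clip(np.rint(times / dt_s).astype(int), 0, glucose.size - 1)
    eps = rng.normal(0.0, noise_cv, times.size) if noise_cv > 0 else 0.0
    values = np.maximum(glucose[idx] * (1.0 + eps), 1.0)
    return times, values


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def exact_population_model(profile: SubjectProfile):
    """The population model implied by the generative couplings.

    Equal weights over the glucose-related channels, a compensating weight
    on the sweat channel cancelling the κ leakage, and an intercept undoing
    the population centring — so that beta·x + intercept = g + b_true
    exactly in the noiseless limit.  Useful as ground truth in tests.
    """
    from .glucose_model import RegressionModel

    gains = np.asarray(profile.channel_gains, dtype=float)
    kappa = np.asarray(profile.sweat_leakage, dtype=float)
    glu = np.flatnonzero(gains > 0)
    if glu.size == 0:
        raise ValueError("profile has no glucose-related channels")
    beta = np.zeros(gains.size)
    beta[glu] = 1.0 / (gains[glu] * glu.size)
    intercept = GLUCOSE_CENTER
    sweat = np.flatnonzero(kappa < 0)
    if sweat.size:
        sw = int(sweat[0])
        beta[sw] = -float(beta[glu] @ kappa[glu])
        intercept -= beta[sw] * SWEAT_BASELINE
    return RegressionModel(
        beta=beta, intercept=float(intercept), lam=0.0, channel_count=gains.size
    )


def make_profiles(config: SimulationConfig) -> list[SubjectProfile]:
    """Device couplings + subject baselines for the default study.

    Subject baseline means are spread evenly over
    ±``baseline_span_mgdl`` (the per-subject clustering of the calibration
    parameter).  Gains and sweat leakages are device properties drawn once
    from a device stream of the master seed and shared across subjects; the
    sweat channel is marked with the sentinel κ = −1.
    """
    cfg = config
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 0xDE71CE])
    )
    gains = np.zeros(cfg.n_channels)
    kappa = np.zeros(cfg.n_channels)
    candidates = [c for c in range(cfg.n_channels) if c != cfg.sweat_channel]
    n_glu = min(cfg.n_glucose_channels, cfg.n_channels - 2)
    glu_channels = rng.choice(candidates, size=n_glu, replace=False)
    gains[glu_channels] = rng.uniform(0.01, 0.03, n_glu)
    # half of the glucose-related channels also pick up the sweat signal
    leaky = rng.choice(glu_channels, size=max(1, n_glu // 2), replace=False)
    kappa[leaky] = cfg.sweat_leakage_scale * rng.uniform(0.05, 0.2, leaky.size)
    kappa[cfg.sweat_channel] = -1.0  # sentinel: designated sweat channel
    offsets = np.linspace(
        -cfg.baseline_span_mgdl, cfg.baseline_span_mgdl, cfg.n_subjects
    )
    return [
        SubjectProfile(
            subject_id=f"subj{j + 1:02d}",
            baseline_offset=float(offsets[j]),
            baseline_sd=cfg.baseline_sd_mgdl,
            channel_gains=gains,
            sweat_leakage=kappa,
            noise_sd=np.full(cfg.n_channels, cfg.channel_noise_sd),
        )
        for j in range(cfg.n_subjects)
    ]


def _draw_events(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[SweatEventSpec]:
    """Well-separated sweat events; count uniform in rate ± 1 (≈1–3/session)."""
    lo_n = max(0, int(round(cfg.sweat_event_rate)) - 1)
    n = int(rng.integers(lo_n, int(round(cfg.sweat_event_rate)) + 2))
    lo, hi = 1800.0, cfg.duration_s - 1800.0
    onsets: list[float] = []
    for _ in range(200):
        if len(onsets) >= n:
            break
        cand = rng.uniform(lo, hi)
        if all(abs(cand - o) >= 1800.0 for o in onsets):
            onsets.append(cand)
    return [
        SweatEventSpec(
            onset_s=o,
            rise_duration_s=rng.uniform(60.0, 180.0),
            decay_duration_s=rng.uniform(600.0, 1800.0),
            amplitude=rng.uniform(3.0, 8.0),
            persistent_offset=(
                rng.uniform(0.5, 1.5) if rng.random() < 0.5 else 0.0
            ),
        )
        for o in sorted(onsets)
    ]


def simulate_sessions(
    config: SimulationConfig,
) -> tuple[list[Session], list[SessionTruth], list[SubjectProfile]]:
    """Generate all sessions of the configured study in memory.

    Sessions are dealt round-robin over subjects (near-even counts).  Each
    session gets independent substreams keyed on (master seed, session_id)
    so regeneration is order-independent.  Ground truth (true glucose,
    event specs, b_true) is returned alongside.
    """
    profiles = make_profiles(config)
    sessions: list[Session] = []
    truths: list[SessionTruth] = []
    counters: dict[str, int] = {}
    for i in range(config.n_sessions):
        prof = profiles[i % config.n_subjects]
        rep = counters.get(prof.subject_id, 0) + 1
        counters[prof.subject_id] = rep
        sid = f"{prof.subject_id}_r{rep:02d}"
        g = simulate_glucose(
            config.duration_s,
            config.dt_s,
            config.equilibration_s,
            _session_seed(config.seed, sid, 1),
            amplitude=config.excursion_amplitude,
        )
        rng_meta = np.random.default_rng(_session_seed(config.seed, sid, 2))
        b_true = float(prof.baseline_offset + rng_meta.normal(0.0, prof.baseline_sd))
        events = _draw_events(config, rng_meta)
        rbg_t, rbg_v = simulate_rbg(
            g,
            config.dt_s,
            config.rbg_interval_s,
            config.rbg_noise_cv,
            _session_seed(config.seed, sid, 3),
        )
        step = None
        step_time = None
        if config.drift_step_mgdl != 0.0:
            after = rbg_t[rbg_t >= config.equilibration_s]
            if after.size == 0:
                raise ValueError("no RBG after equilibration; cannot place drift step")
            step_time = float(after[0] + config.drift_step_after_t0_s)
            step = (step_time, config.drift_step_mgdl)
        X, _ = simulate_channels(
            g,
            prof,
            events,
            config.dt_s,
            _session_seed(config.seed, sid, 4),
            b_true=b_true,
            drift_sd=config.drift_sd,
            baseline_step=step,
        )
        sessions.append(
            Session(
                session_id=sid,
                subject_id=prof.subject_id,
                t=config.time_grid,
                X=X,
                rbg_times=rbg_t,
                rbg_values=rbg_v,
            )
        )
        truths.append(
            SessionTruth(
                session_id=sid,
                subject_id=prof.subject_id,
                true_glucose=g,
                events=events,
                b_true=b_true,
                drift_step_time_s=step_time,
            )
        )
    return sessions, truths, profiles


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> DatasetManifest:
    """Generate the study to disk: session/RBG/truth CSVs plus a manifest.

    Files are byte-identical across runs with the same master seed.  The
    manifest already carries an identification/test split (derived from the
    master seed).  Ground-truth sidecars per session
    (``<sid>_truth.csv``: ``time_s,true_glucose_mgdl``), a pooled events
    file and a truth manifest with ``b_true`` support downstream testing.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions, truths, _ = simulate_sessions(config)
    entries = []
    ev_rows = []
    truth_rows = []
    for sess, truth in zip(sessions, truths):
        sfile = f"{sess.session_id}_session.csv"
        rfile = f"{sess.session_id}_rbg.csv"
        write_session(sess, out / sfile, out / rfile)
        pd.DataFrame(
            {"time_s": sess.t, "true_glucose_mgdl": truth.true_glucose}
        ).to_csv(out / f"{sess.session_id}_truth.csv", index=False)
        for ev in truth.events:
            ev_rows.append((sess.session_id, ev.onset_s, ev.persistent_offset))
        truth_rows.append((sess.session_id, truth.b_true))
        entries.append(
            ManifestEntry(sess.session_id, sess.subject_id, sfile, rfile)
        )
    pd.DataFrame(
        ev_rows, columns=["session_id", "onset_s", "persistent_offset"]
    ).to_csv(out / "events_truth.csv", index=False)
    pd.DataFrame(truth_rows, columns=["session_id", "b_true"]).to_csv(
        out / "manifest_truth.csv", index=False
    )
    manifest = DatasetManifest(entries)
    split_dataset(manifest, int(config.seed) & 0x7FFFFFFF)
    write_manifest(manifest, out / "manifest.csv")
    return manifest
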