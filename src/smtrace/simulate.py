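"""Stochastic simulator for one- and two-color fluorescence time traces.

Traces are generated in four stages: (1) sample a Markov kinetic model,
(2) run the state path and render the noiseless donor/acceptor intensities,
(3) apply photophysics (photobleaching, donor blinking, acceptor brightness),
(4) add Gaussian noise plus a constant background offset.  Every trace
carries a :class:`GroundTruth` with the labels needed by all training tasks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "KineticModel",
    "PhotophysicsConfig",
    "NoiseConfig",
    "SimulatorConfig",
    "GroundTruth",
    "Trace",
    "sample_kinetic_model",
    "simulate_state_path",
    "render_ideal_trace",
    "apply_photophysics",
    "add_noise",
    "simulate_trace",
    "generate_dataset",
    "stationary_distribution",
    "mean_transition_rate",
    "recompute_labels",
]

NO_BLEACH = -1  # sentinel bleach frame: channel never bleached within T


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotophysicsConfig:
    """Ranges for photophysical lifetime parameters, in frames."""

    tau_bleach_range: tuple[float, float] = (1.0, 2000.0)
    tau_blink_range: tuple[float, float] = (1.0, 20.0)
    tau_nonblink_range: tuple[float, float] = (200.0, 2000.0)
    acceptor_brightness_range: tuple[float, float] = (0.9, 1.0)

    def validate(self) -> None:
        for name in ("tau_bleach_range", "tau_blink_range", "tau_nonblink_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got {(lo, hi)}")
        lo, hi = self.acceptor_brightness_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(
                f"acceptor_brightness_range must lie within [0, 1], got {(lo, hi)}"
            )


@dataclass(frozen=True)
class NoiseConfig:
    """Target SNR and background-offset ranges for the noise stage.

    SNR is defined as I_max / sigma with a shared Gaussian sigma in both
    channels; the offset is expressed as a fraction of I_max.
    """

    snr_range: tuple[float, float] = (1.8, 6.0)
    offset_fraction_range: tuple[float, float] = (0.0, 0.2)

    def validate(self) -> None:
        lo, hi = self.snr_range
        if not (0 < lo <= hi):
            raise ValueError(f"snr_range must be positive and ordered, got {(lo, hi)}")
        lo, hi = self.offset_fraction_range
        if not (0 <= lo <= hi):
            raise ValueError("offset_fraction_range must be non-negative and ordered")


@dataclass(frozen=True)
class SimulatorConfig:
    """Full simulator configuration with the documented defaults."""

    n_frames: int = 2000
    n_states_range: tuple[int, int] = (1, 4)
    i_max_range: tuple[float, float] = (100.0, 1000.0)
    min_state_separation: float = 0.1
    one_color_fraction: float = 0.25
    max_fluorophores: int = 6  # one-color staircase traces
    frame_period: float = 0.1  # seconds per frame, metadata only
    photophysics: PhotophysicsConfig = field(default_factory=PhotophysicsConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        lo, hi = self.n_states_range
        if not (1 <= lo <= hi <= 4):
            raise ValueError("n_states_range must lie within {1..4}")
        lo, hi = self.i_max_range
        if not (0 < lo <= hi):
            raise ValueError("i_max_range must be positive and ordered")
        if not (0 <= self.one_color_fraction <= 1):
            raise ValueError("one_color_fraction must lie in [0, 1]")
        self.photophysics.validate()
        self.noise.validate()


@dataclass(frozen=True)
class KineticModel:
    """Markov kinetic model of a trace: states, transition rules, emission."""

    n_states: int
    p_init: np.ndarray          # (S,) probability vector
    p_transfer: np.ndarray      # (S, S) row-stochastic per-frame matrix
    state_fret: np.ndarray      # (S,) FRET efficiency (or relative intensity)
    i_max: float

    def validate(self) -> None:
        if self.n_states not in (1, 2, 3, 4):
            raise ValueError("n_states must be in {1, 2, 3, 4}")
        if self.p_init.shape != (self.n_states,):
            raise ValueError("p_init shape mismatch")
        if self.p_transfer.shape != (self.n_states, self.n_states):
            raise ValueError("p_transfer shape mismatch")
        if not np.allclose(self.p_init.sum(), 1.0):
            raise ValueError("p_init must sum to 1")
        if not np.allclose(self.p_transfer.sum(axis=1), 1.0):
            raise ValueError("p_transfer rows must sum to 1")


@dataclass
class GroundTruth:
    """Complete per-trace ground truth recorded during simulation."""

    state_path: np.ndarray            # (T,) int state indices
    ideal_fret: np.ndarray            # (T,) noiseless FRET (0 after bleach)
    active_mask: np.ndarray           # (T,) bool, True pre-bleach
    n_states: int
    snr: float
    mean_transition_rate: float       # expected per-frame leave probability
    bleach_frame: tuple[int, int]     # per channel, NO_BLEACH if none
    n_bleach_steps: tuple[int, int]   # per channel
    blink_events: int
    state_fret_values: np.ndarray     # (S,)
    tau_bleach: tuple[float, float] = (np.inf, np.inf)  # sampled expected lifetimes
    i_max: float = 0.0
    offset: float = 0.0
    one_color: bool = False
    n_fluorophores: int = 1
    bleach_steps_so_far: Optional[np.ndarray] = None  # (T,) one-color staircase


@dataclass
class Trace:
    """A (T, 2) intensity trace; one-color traces zero-fill channel 1."""

    intensities: np.ndarray
    frame_period: float = 0.1
    condition_tag: Optional[str] = None
    ground_truth: Optional[GroundTruth] = None
    trace_id: Optional[str] = None

    @property
    def n_frames(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def is_one_color(self) -> bool:
        if self.ground_truth is not None:
            return self.ground_truth.one_color
        return bool(np.all(self.intensities[:, 1] == 0.0))


# ---------------------------------------------------------------------------
# kinetic model sampling
# ---------------------------------------------------------------------------

def _sample_separated_levels(
    rng: np.random.Generator, n: int, min_sep: float, low: float = 0.0, high: float = 1.0
) -> np.ndarray:
    """Uniform levels on [low, high] with minimum pairwise separation."""
    for _ in range(1000):
        levels = rng.uniform(low, high, size=n)
        if n == 1 or np.min(np.diff(np.sort(levels))) >= min_sep:
            return levels
    raise RuntimeError("could not sample separated levels; relax min_state_separation")


def sample_kinetic_model(rng: np.random.Generator, cfg: SimulatorConfig) -> KineticModel:
    """Draw a random kinetic model per the documented sampling rules.

    The state count is uniform on ``cfg.n_states_range``; initial and
    transition probabilities are i.i.d. uniform draws normalized to sum 1;
    FRET levels are uniform on [0, 1] with minimum pairwise separation.
    """
    cfg.validate()
    lo, hi = cfg.n_states_range
    n_states = int(rng.integers(lo, hi + 1))
    p_init = rng.uniform(size=n_states)
    p_init = p_init / p_init.sum()
    p_transfer = rng.uniform(size=(n_states, n_states))
    p_transfer = p_transfer / p_transfer.sum(axis=1, keepdims=True)
    # sorted ascending: state index doubles as FRET rank
    state_fret = np.sort(
        _sample_separated_levels(rng, n_states, cfg.min_state_separation)
    )
    i_max = float(rng.uniform(*cfg.i_max_range))
    model = KineticModel(n_states, p_init, p_transfer, state_fret, i_max)
    model.validate()
    return model


def stationary_distribution(p_transfer: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (eigen method)."""
    vals, vecs = np.linalg.eig(p_transfer.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    total = pi.sum()
    if total <= 0 or not np.isfinite(total):
        pi = np.full(p_transfer.shape[0], 1.0 / p_transfer.shape[0])
    else:
        pi = pi / total
    return pi


def mean_transition_rate(model: KineticModel) -> float:
    """Expected per-frame probability of leaving the current state.

    Averaged over the stationary distribution of ``p_transfer``; this is the
    quantity thresholded by the atlas "fast"/"slow" rate classes.
    """
    if model.n_states == 1:
        return 0.0
    pi = stationary_distribution(model.p_transfer)
    leave = 1.0 - np.diag(model.p_transfer)
    return float(np.dot(pi, leave))


# ---------------------------------------------------------------------------
# state path and noiseless rendering
# ---------------------------------------------------------------------------

def simulate_state_path(model: KineticModel, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a length-T Markov state path from the kinetic model."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    model.validate()
    path = np.empty(n_frames, dtype=np.int64)
    if model.n_states == 1:
        path[:] = 0
        return path
    cum_init = np.cumsum(model.p_init)
    cum_trans = np.cumsum(model.p_transfer, axis=1)
    u = rng.uniform(size=n_frames)
    state = int(np.searchsorted(cum_init, u[0]))
    path[0] = state
    for t in range(1, n_frames):
        state = int(np.searchsorted(cum_trans[state], u[t]))
        path[t] = state
    return path


def render_ideal_trace(model: KineticModel, state_path: np.ndarray) -> np.ndarray:
    """Noiseless (T, 2) donor/acceptor intensities from a state path.

    Acceptor = I_max * fret(state); donor = I_max - acceptor, so the two
    channels always sum to I_max.
    """
    fret = model.state_fret[state_path]
    acceptor = model.i_max * fret
    donor = model.i_max - acceptor
    return np.stack([donor, acceptor], axis=1)


# ---------------------------------------------------------------------------
# photophysics
# ---------------------------------------------------------------------------

def _sample_bleach_frame(rng: np.random.Generator, tau: float, n_frames: int) -> int:
    t = rng.exponential(tau)
    return int(t) if t < n_frames else NO_BLEACH


def _blink_mask(
    rng: np.random.Generator,
    n_frames: int,
    tau_on: float,
    tau_off: float,
) -> tuple[np.ndarray, int]:
    """Alternating on/off exponential segments; True where emitting."""
    mask = np.ones(n_frames, dtype=bool)
    events = 0
    t = rng.exponential(tau_on)
    while t < n_frames:
        off = rng.exponential(tau_off)
        lo, hi = int(t), min(n_frames, int(np.ceil(t + off)))
        if hi > lo:
            mask[lo:hi] = False
            events += 1
        t = t + off + rng.exponential(tau_on)
    return mask, events


def apply_photophysics(
    ideal: np.ndarray,
    phys: PhotophysicsConfig,
    rng: np.random.Generator,
    blinking: bool = True,
) -> tuple[np.ndarray, dict]:
    """Apply photobleaching, donor blinking and acceptor brightness.

    After acceptor bleach the acceptor's emission is redirected to the donor
    channel (total intensity conserved); after donor bleach both channels
    drop to zero.  Donor blinking darkens both channels during off segments.
    Returns the modified trace and a dict of photophysics ground truth.
    """
    phys.validate()
    n_frames = ideal.shape[0]
    out = ideal.astype(np.float64).copy()
    i_total = float(ideal[0].sum())

    tau_d = float(rng.uniform(*phys.tau_bleach_range))
    tau_a = float(rng.uniform(*phys.tau_bleach_range))
    bleach_d = _sample_bleach_frame(rng, tau_d, n_frames)
    bleach_a = _sample_bleach_frame(rng, tau_a, n_frames)

    # acceptor bleach first (if it precedes donor bleach): emission moves to donor
    if bleach_a != NO_BLEACH and (bleach_d == NO_BLEACH or bleach_a < bleach_d):
        out[bleach_a:, 0] = i_total
        out[bleach_a:, 1] = 0.0
    elif bleach_a != NO_BLEACH:
        out[bleach_a:, 1] = 0.0

    brightness = float(rng.uniform(*phys.acceptor_brightness_range))
    out[:, 1] *= brightness

    blink_events = 0
    if blinking:
        tau_on = float(rng.uniform(*phys.tau_nonblink_range))
        tau_off = float(rng.uniform(*phys.tau_blink_range))
        mask, blink_events = _blink_mask(rng, n_frames, tau_on, tau_off)
        out[~mask] = 0.0

    if bleach_d != NO_BLEACH:
        out[bleach_d:] = 0.0

    info = {
        "bleach_frame": (bleach_d, bleach_a),
        "tau_bleach": (tau_d, tau_a),
        "acceptor_brightness": brightness,
        "blink_events": blink_events,
        "n_bleach_steps": (
            int(bleach_d != NO_BLEACH),
            int(bleach_a != NO_BLEACH),
        ),
    }
    return out, info


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise(
    clean: np.ndarray,
    noise: NoiseConfig,
    rng: np.random.Generator,
    i_max: float,
) -> tuple[np.ndarray, float]:
    """Add i.i.d. Gaussian noise (sigma = I_max / SNR) and a constant offset."""
    noise.validate()
    if not np.all(np.isfinite(clean)):
        raise ValueError("clean trace must be finite")
    snr = float(rng.uniform(*noise.snr_range))
    sigma = i_max / snr
    offset = float(rng.uniform(*noise.offset_fraction_range)) * i_max
    noisy = clean + rng.normal(0.0, sigma, size=clean.shape) + offset
    return noisy, snr


# ---------------------------------------------------------------------------
# full trace assembly
# ---------------------------------------------------------------------------

def _first_bleach(bleach_frames: Sequence[int]) -> int:
    real = [b for b in bleach_frames if b != NO_BLEACH]
    return min(real) if real else NO_BLEACH


def _two_color_trace(cfg: SimulatorConfig, rng: np.random.Generator) -> Trace:
    model = sample_kinetic_model(rng, cfg)
    path = simulate_state_path(model, cfg.n_frames, rng)
    ideal = render_ideal_trace(model, path)
    photo, info = apply_photophysics(ideal, cfg.photophysics, rng)
    noisy, snr = add_noise(photo, cfg.noise, rng, model.i_max)

    first = _first_bleach(info["bleach_frame"])
    ideal_fret = model.state_fret[path].copy()
    active = np.ones(cfg.n_frames, dtype=bool)
    if first != NO_BLEACH:
        ideal_fret[first:] = 0.0
        active[first:] = False

    offset_used = float(noisy.mean() - photo.mean())  # informational only
    gt = GroundTruth(
        state_path=path,
        ideal_fret=ideal_fret,
        active_mask=active,
        n_states=model.n_states,
        snr=snr,
        mean_transition_rate=mean_transition_rate(model),
        bleach_frame=tuple(info["bleach_frame"]),
        n_bleach_steps=tuple(info["n_bleach_steps"]),
        blink_events=info["blink_events"],
        state_fret_values=model.state_fret.copy(),
        tau_bleach=tuple(info["tau_bleach"]),
        i_max=model.i_max,
        offset=offset_used,
        one_color=False,
    )
    return Trace(noisy.astype(np.float32), cfg.frame_period, ground_truth=gt)


def _one_color_trace(cfg: SimulatorConfig, rng: np.random.Generator) -> Trace:
    """Intensity-level Markov chain times a photobleach staircase, no FRET."""
    model = sample_kinetic_model(rng, cfg)
    path = simulate_state_path(model, cfg.n_frames, rng)
    # state_fret reinterpreted as relative intensity level; keep it off zero
    levels = 0.3 + 0.7 * model.state_fret
    n_fluor = int(rng.integers(1, cfg.max_fluorophores + 1))
    tau = float(rng.uniform(*cfg.photophysics.tau_bleach_range))
    bleach_times = np.sort(rng.exponential(tau, size=n_fluor))
    active_count = n_fluor - np.searchsorted(
        bleach_times, np.arange(cfg.n_frames), side="right"
    )
    signal = model.i_max * levels[path] * active_count / n_fluor
    clean = np.stack([signal, np.zeros_like(signal)], axis=1)
    noisy, snr = add_noise(clean[:, :1], cfg.noise, rng, model.i_max)
    out = np.concatenate([noisy, np.zeros_like(noisy)], axis=1)

    n_steps = int(np.sum(bleach_times < cfg.n_frames))
    first = int(bleach_times[-1]) if n_steps == n_fluor else NO_BLEACH
    active = active_count > 0
    gt = GroundTruth(
        state_path=path,
        ideal_fret=np.zeros(cfg.n_frames),
        active_mask=active,
        n_states=model.n_states,
        snr=snr,
        mean_transition_rate=mean_transition_rate(model),
        bleach_frame=(first, NO_BLEACH),
        n_bleach_steps=(n_steps, 0),
        blink_events=0,
        state_fret_values=model.state_fret.copy(),
        tau_bleach=(tau, np.inf),
        i_max=model.i_max,
        one_color=True,
        n_fluorophores=n_fluor,
        bleach_steps_so_far=np.searchsorted(
            bleach_times, np.arange(cfg.n_frames), side="right"
        ).astype(np.int64),
    )
    return Trace(out.astype(np.float32), cfg.frame_period, ground_truth=gt)


def simulate_trace(cfg: SimulatorConfig, rng: np.random.Generator) -> Trace:
    """Simulate a single trace, choosing one- vs two-color per config."""
    if rng.uniform() < cfg.one_color_fraction:
        return _one_color_trace(cfg, rng)
    return _two_color_trace(cfg, rng)


def generate_dataset(
    n: int,
    cfg: Optional[SimulatorConfig] = None,
    seed: int = 0,
    condition_tag: Optional[str] = None,
) -> list[Trace]:
    """Generate ``n`` fully labeled traces, deterministic given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or SimulatorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    traces = []
    for i in range(n):
        tr = simulate_trace(cfg, rng)
        tr.trace_id = f"trace_{i:06d}"
        tr.condition_tag = condition_tag
        traces.append(tr)
    return traces


# ---------------------------------------------------------------------------
# independent label recomputation (used as a test oracle hook)
# ---------------------------------------------------------------------------

def recompute_labels(trace: Trace) -> dict:
    """Recompute derivable labels from the stored state path and metadata.

    Serves as an internal consistency check: labels recomputed here must
    match the ones recorded during simulation.
    """
    gt = trace.ground_truth
    if gt is None:
        raise ValueError("trace has no ground truth")
    path = gt.state_path
    n_states = int(np.max(path)) + 1 if path.size else 0
    first = _first_bleach(gt.bleach_frame)
    active = np.ones(path.shape[0], dtype=bool)
    if not gt.one_color and first != NO_BLEACH:
        active[first:] = False
    out = {
        "n_states_observed_le": n_states <= gt.n_states,
        "active_mask": active,
    }
    if not gt.one_color:
        ideal = gt.state_fret_values[path].copy()
        if first != NO_BLEACH:
            ideal[first:] = 0.0
        out["ideal_fret"] = ideal
    return out
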