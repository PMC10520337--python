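"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here: critical /
subcritical branching-process avalanches (the canonical mean-field model whose
size and duration statistics the avalanche analysis is meant to recover),
bounded power-law samples for fit testing, cyclic NREM-REM hypnograms, CAP
(cyclic alternating pattern) annotations, and surrogate multichannel
recordings in which high-amplitude bursts are injected at a rate modulated by
sleep stage and CAP phase.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coupling import CapAnnotation, Hypnogram
from .ingest import MultichannelRecording

__all__ = [
    "BranchingConfig",
    "AvalancheSample",
    "ArchitectureConfig",
    "CouplingConfig",
    "simulate_branching_process",
    "estimate_branching_ratio",
    "sample_power_law",
    "simulate_hypnogram",
    "simulate_cap_annotations",
    "synthesize_recording",
]

NREM_STAGES = ("N1", "N2", "N3")


@dataclass(frozen=True)
class BranchingConfig:
    """Fully-connected (mean-field) branching process.

    ``offspring_mean`` is the expected number of descendants per active unit;
    1.0 is the critical point where avalanche sizes follow P(s) ~ s^-3/2 and
    durations P(T) ~ T^-2 (mean-field directed percolation).  ``n_units``
    caps the number of simultaneously active units, emulating the finite-size
    cutoff of a finite sensor array.
    """

    offspring_mean: float = 1.0
    n_units: int = 100_000
    n_avalanches: int = 100_000
    max_generations: Optional[int] = 2000
    dt_step: float = 0.01  # seconds per generation, for the detector's axis
    offspring_dist: str = "geometric"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offspring_mean < 0:
            raise ValueError("offspring_mean must be >= 0")
        if self.offspring_dist not in ("geometric", "poisson"):
            raise ValueError("offspring_dist must be 'geometric' or 'poisson'")
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.n_avalanches < 1:
            raise ValueError("n_avalanches must be >= 1")
        if self.offspring_mean > 1 and self.max_generations is None:
            raise ValueError(
                "supercritical offspring_mean > 1 requires a max_generations cap"
            )


@dataclass
class AvalancheSample:
    """Ground-truth avalanches: total activations (size) and generation
    counts (duration, in generations; multiply by ``dt_step`` for seconds)."""

    sizes: np.ndarray
    durations: np.ndarray
    generation_counts: list  # list of int arrays, one per avalanche
    dt_step: float = 0.01

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.durations = np.asarray(self.durations, dtype=np.int64)

    @property
    def durations_s(self) -> np.ndarray:
        return self.durations * self.dt_step


def simulate_branching_process(config: BranchingConfig) -> AvalancheSample:
    """Run ``config.n_avalanches`` independent avalanches.

    Each avalanche starts from a single active unit; every active unit
    independently spawns offspring with mean ``offspring_mean`` (fully
    connected mean-field limit), and the total activation per generation is
    absorbed at ``n_units``.  An avalanche ends at extinction or after
    ``max_generations`` generations.

    The default offspring law is geometric on {0, 1, 2, ...} (the classical
    exactly-solvable Galton-Watson choice; total offspring of ``a`` parents
    is negative binomial).  Its offspring variance m(1 + m) is twice the
    Poisson variance at criticality, which halves the finite-duration
    corrections to the <s>(T) ~ T^2 scaling and puts durations of a few
    generations inside the scaling regime; 'poisson' is available as an
    option.  Both laws are critical at offspring_mean = 1 and share the
    mean-field exponents tau = 3/2, alpha = 2, k = 2.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_avalanches
    m = config.offspring_mean
    max_gen = config.max_generations or np.inf
    if config.offspring_dist == "geometric":
        p = 1.0 / (1.0 + m)
        draw = lambda a: rng.negative_binomial(a, p)  # noqa: E731
    else:
        draw = lambda a: rng.poisson(m * a)  # noqa: E731

    sizes = np.ones(n, dtype=np.int64)
    durations = np.ones(n, dtype=np.int64)
    # per-generation records: (original indices, activation counts)
    records: list[tuple[np.ndarray, np.ndarray]] = []

    idx = np.arange(n)
    active = np.ones(n, dtype=np.int64)
    gen = 1
    while idx.size and gen < max_gen:
        offspring = draw(active)
        offspring = np.minimum(offspring, config.n_units)
        alive = offspring > 0
        idx = idx[alive]
        active = offspring[alive]
        if idx.size == 0:
            break
        sizes[idx] += active
        durations[idx] += 1
        records.append((idx, active))
        gen += 1

    gen_counts: list[list[int]] = [[1] for _ in range(n)]
    for rec_idx, rec_act in records:
        for i, a in zip(rec_idx, rec_act):
            gen_counts[i].append(int(a))
    generation_counts = [np.asarray(g, dtype=np.int64) for g in gen_counts]
    return AvalancheSample(sizes, durations, generation_counts, config.dt_step)


def estimate_branching_ratio(sample: AvalancheSample) -> float:
    """Branching-ratio estimate from ground-truth generation counts.

    Averages (activations in generation 2) / (activations in generation 1)
    over *all* avalanches; an avalanche extinct after generation 1
    contributes a ratio of 0.  With this convention the estimator is an
    unbiased estimate of the offspring mean, so it reads ~1 at criticality.
    """
    ratios = np.array(
        [g[1] / g[0] if g.size >= 2 else 0.0 for g in sample.generation_counts]
    )
    return float(ratios.mean())


def sample_power_law(
    exponent: float,
    xmin: float,
    xmax: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """i.i.d. draws from the bounded continuous power law p(x) ~ x^-exponent
    on [xmin, xmax], by inverse-CDF sampling."""
    if not xmax > xmin > 0:
        raise ValueError("require xmax > xmin > 0")
    if exponent <= 1 and np.isinf(xmax):
        raise ValueError("exponent <= 1 with unbounded support is not normalizable")
    if n == 0:
        return np.empty(0)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    u = rng.random(n)
    if exponent == 1.0:
        return xmin * (xmax / xmin) ** u
    g = 1.0 - exponent
    if np.isinf(xmax):
        return xmin * (1.0 - u) ** (1.0 / g)
    return (xmin**g + u * (xmax**g - xmin**g)) ** (1.0 / g)


def power_law_cdf(x: np.ndarray, exponent: float, xmin: float, xmax: float) -> np.ndarray:
    """Analytic CDF of the bounded power law (oracle for the sampler/fits)."""
    x = np.asarray(x, dtype=float)
    if exponent == 1.0:
        return np.clip(np.log(x / xmin) / np.log(xmax / xmin), 0.0, 1.0)
    g = 1.0 - exponent
    if np.isinf(xmax):
        return np.clip(1.0 - (x / xmin) ** g, 0.0, 1.0)
    return np.clip((x**g - xmin**g) / (xmax**g - xmin**g), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Sleep architecture
# ---------------------------------------------------------------------------


def _default_stage_fractions() -> dict:
    # cohort-average stage shares of total sleep time
    return {"N1": 0.0723, "N2": 0.4847, "N3": 0.2399, "REM": 0.2031}


def _default_dwell_means() -> dict:
    # seconds per stage visit; N2 is visited twice per cycle (descending and
    # ascending slope), so its per-visit dwell is half its share
    return {"N1": 180.0, "N2": 610.0, "N3": 600.0, "REM": 500.0}


def _default_cap_rates() -> dict:
    return {"N1": 0.4169, "N2": 0.4836, "N3": 0.5337}


def _default_subtype_mix() -> dict:
    # (pA1, pA2, pA3): A1 dominates deep sleep, A2/A3 dominate light sleep
    return {
        "N1": (0.10, 0.30, 0.60),
        "N2": (0.50, 0.25, 0.25),
        "N3": (0.85, 0.10, 0.05),
    }


def _default_phase_params() -> dict:
    # normal(mean, sd) seconds, clipped to [2, 60]
    return {
        "A1": (6.42, 2.0),
        "A2": (8.63, 2.0),
        "A3": (12.72, 2.0),
        "B": (20.67, 5.0),
    }


@dataclass(frozen=True)
class ArchitectureConfig:
    """Parameters of the synthetic sleep macro-/micro-architecture.

    Defaults reproduce the cohort-average architecture: N2 ~48.5% of sleep
    time, stage-wise CAP rates ~42-53%, phase-A/B lengths ~8.6/20.7 s with
    every phase clipped to [2, 60] s.
    """

    n_cycles: int = 5
    epoch_length: float = 30.0
    stage_fraction_targets: dict = field(default_factory=_default_stage_fractions)
    stage_dwell_means: dict = field(default_factory=_default_dwell_means)
    cap_rate_by_stage: dict = field(default_factory=_default_cap_rates)
    phase_duration_params: dict = field(default_factory=_default_phase_params)
    subtype_mix_by_stage: dict = field(default_factory=_default_subtype_mix)
    cap_sequence_mean_s: float = 273.0  # ~4.55 min
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.stage_fraction_targets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("stage_fraction_targets must sum to 1")
        for stage, mix in self.subtype_mix_by_stage.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"subtype mix for {stage} must sum to 1")
        for stage, rate in self.cap_rate_by_stage.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"cap rate for {stage} outside [0, 1]")


def simulate_hypnogram(config: ArchitectureConfig) -> Hypnogram:
    """Semi-Markov hypnogram of 30-s epochs.

    Each NREM-REM cycle follows the descending slope N1 -> N2 -> N3, then the
    ascending slope N3 -> N2 -> REM.  Stage dwell times are exponential with
    the configured means, truncated at one epoch.
    """
    if config.n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(config.seed)
    epochs: list[str] = []
    template = ["N1", "N2", "N3", "N2", "REM"]
    for _ in range(config.n_cycles):
        for stage in template:
            dwell = rng.exponential(config.stage_dwell_means[stage])
            n_ep = max(1, int(round(dwell / config.epoch_length)))
            epochs.extend([stage] * n_ep)
    return Hypnogram(epochs, epoch_length=config.epoch_length)


def _draw_phase_duration(rng, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 2.0, 60.0))


def simulate_cap_annotations(
    hyp: Hypnogram, config: ArchitectureConfig
) -> CapAnnotation:
    """Place CAP sequences (alternating A/B cycles) inside NREM sleep.

    Each maximal same-stage NREM run is tiled with a stationary alternating
    renewal process of CAP sequences and NCAP gaps: the run starts inside a
    sequence with probability equal to the stage's target CAP rate, and gap
    lengths are sized so the expected CAP fraction matches
    ``cap_rate_by_stage``; gaps are at least 65 s, so they are NCAP by
    construction.  A-phase subtypes follow the stage's subtype mix; every
    phase duration lies in [2, 60] s.  A sequence holds at least two A-B
    cycles and never crosses a stage boundary.
    """
    stages = hyp.epoch_stages
    if not any(s in NREM_STAGES for s in stages):
        raise ValueError("hypnogram contains no NREM epochs")
    rng = np.random.default_rng(config.seed)
    phases: list[tuple[float, float, str]] = []

    # maximal same-stage runs
    run_start = 0
    runs: list[tuple[int, int, str]] = []
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[run_start]:
            runs.append((run_start, i, stages[run_start]))
            run_start = i

    ep = hyp.epoch_length
    for start_ep, end_ep, stage in runs:
        if stage not in NREM_STAGES:
            continue
        rate = config.cap_rate_by_stage.get(stage, 0.0)
        if rate <= 0.0:
            continue
        t = hyp.start_s + start_ep * ep
        t_end = hyp.start_s + end_ep * ep
        # expected NCAP gap between sequences for the target CAP fraction
        gap_mean = max(65.0, config.cap_sequence_mean_s * (1.0 - rate) / rate)
        # stationary start: inside a sequence with probability `rate`
        # (exponential lengths are memoryless, so the residual has the same
        # law as a fresh draw)
        in_cap = rng.random() < rate
        if not in_cap:
            t += max(65.0, rng.exponential(gap_mean))
        while t < t_end:
            seq_len = 0.0
            target_len = rng.exponential(config.cap_sequence_mean_s)
            n_cycles = 0
            while (seq_len < target_len or n_cycles < 2) and t < t_end:
                mix = config.subtype_mix_by_stage[stage]
                sub = rng.choice(("A1", "A2", "A3"), p=mix)
                da = _draw_phase_duration(rng, *config.phase_duration_params[sub])
                db = _draw_phase_duration(rng, *config.phase_duration_params["B"])
                if t + da + db > t_end:
                    # close the run with a final A phase if it fits; the
                    # sequence is truncated by the stage boundary
                    if n_cycles >= 1 and t + da <= t_end:
                        phases.append((t, da, sub))
                        t += da
                    break
                phases.append((t, da, sub))
                phases.append((t + da, db, "B"))
                t += da + db
                seq_len += da + db
                n_cycles += 1
            t += max(65.0, rng.exponential(gap_mean))
    return CapAnnotation(phases)


# ---------------------------------------------------------------------------
# Surrogate recordings
# ---------------------------------------------------------------------------


def _default_stage_multipliers() -> dict:
    return {"W": 0.0, "N1": 1.0, "N2": 2.0, "N3": 3.0, "REM": 0.5}


def _default_phase_multipliers() -> dict:
    return {"A1": 6.0, "A2": 4.0, "A3": 2.5, "B": 0.4, "NCAP": 0.7}


@dataclass(frozen=True)
class CouplingConfig:
    """How injected bursts couple to the architecture.

    The injection process is Poisson with rate ``base_rate`` (bursts per
    second) multiplied by the current stage multiplier and, within NREM, the
    current CAP-phase multiplier.  Each burst is a clipped half-sine envelope
    of amplitude ``burst_amplitude`` (in background-SD units) added to a
    random ``burst_channel_fraction`` of channels; burst durations follow a
    bounded power law.
    """

    base_rate: float = 0.06
    stage_multipliers: dict = field(default_factory=_default_stage_multipliers)
    phase_multipliers: dict = field(default_factory=_default_phase_multipliers)
    burst_amplitude: float = 20.0
    burst_channel_fraction: float = 0.5
    burst_duration_range: tuple = (0.2, 5.0)
    burst_duration_exponent: float = 2.0
    envelope_floor: float = 0.75  # fraction of amplitude at burst edges
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.stage_multipliers.values()):
            raise ValueError("stage multipliers must be >= 0")
        if any(v < 0 for v in self.phase_multipliers.values()):
            raise ValueError("phase multipliers must be >= 0")
        if not 0 < self.burst_channel_fraction <= 1:
            raise ValueError("burst_channel_fraction must be in (0, 1]")


def synthesize_recording(
    hyp: Hypnogram,
    cap: Optional[CapAnnotation],
    coupling: CouplingConfig,
    n_channels: int = 8,
    fs: float = 128.0,
    seed: int = 0,
) -> tuple[MultichannelRecording, np.ndarray]:
    """Surrogate multichannel recording with architecture-coupled bursts.

    Returns the recording (unit-variance Gaussian background plus injected
    bursts, raw units) and the ground-truth injected intervals as an array of
    (onset_s, offset_s) rows.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    duration_s = hyp.duration_s
    n_samples = int(round(duration_s * fs))
    signal = rng.standard_normal((n_channels, n_samples))

    # per-sample injection rate from stage and CAP phase
    stage_per_sample = hyp.stage_indicator_names(fs, n_samples)
    rate = np.empty(n_samples)
    for stage, mult in coupling.stage_multipliers.items():
        rate[stage_per_sample == stage] = coupling.base_rate * mult
    if cap is not None:
        phase_mult = np.ones(n_samples)
        nrem = np.isin(stage_per_sample, NREM_STAGES)
        phase_mult[nrem] = coupling.phase_multipliers.get("NCAP", 1.0)
        for onset, dur, label in cap.phases:
            i0 = int(round(onset * fs))
            i1 = min(n_samples, int(round((onset + dur) * fs)))
            phase_mult[i0:i1] = coupling.phase_multipliers.get(label, 1.0)
        rate *= phase_mult

    # thin a homogeneous Poisson process by the local rate
    rate_max = rate.max()
    truth: list[tuple[float, float]] = []
    if rate_max > 0:
        n_cand = rng.poisson(rate_max * duration_s)
        t_cand = np.sort(rng.random(n_cand) * duration_s)
        keep = rng.random(n_cand) < rate[
            np.minimum((t_cand * fs).astype(int), n_samples - 1)
        ] / rate_max
        n_burst_ch = max(1, int(round(coupling.burst_channel_fraction * n_channels)))
        for t0 in t_cand[keep]:
            dur = float(
                sample_power_law(
                    coupling.burst_duration_exponent,
                    *coupling.burst_duration_range,
                    1,
                    rng,
                )[0]
            )
            i0 = int(round(t0 * fs))
            i1 = min(n_samples, i0 + max(2, int(round(dur * fs))))
            if i0 >= n_samples:
                continue
            n_pts = i1 - i0
            env = np.sin(np.pi * (np.arange(n_pts) + 0.5) / n_pts)
            env = coupling.burst_amplitude * np.clip(
                env, coupling.envelope_floor, 1.0
            )
            chans = rng.choice(n_channels, size=n_burst_ch, replace=False)
            sign = rng.choice((-1.0, 1.0))
            signal[np.ix_(chans, np.arange(i0, i1))] += sign * env
            truth.append((i0 / fs, i1 / fs))

    labels = [f"CH{i + 1}" for i in range(n_channels)]
    rec = MultichannelRecording(signal, fs, channel_labels=labels)
    truth_arr = np.asarray(truth, dtype=float).reshape(-1, 2)
    # merge overlapping ground-truth intervals
    if truth_arr.shape[0] > 1:
        order = np.argsort(truth_arr[:, 0])
        merged = [truth_arr[order[0]].tolist()]
        for a, b in truth_arr[order[1:]]:
            if a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        truth_arr = np.asarray(merged)
    return rec, truth_arr
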