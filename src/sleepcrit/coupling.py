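"""Sleep macro-/micro-architecture and its coupling with avalanches.

The macro-architecture is a hypnogram of 30-s epochs labeled W, N1, N2, N3,
REM.  The micro-architecture is the cyclic alternating pattern (CAP): within
NREM sleep, sequences of alternating activation phases A (subtypes A1, A2,
A3) and background phases B, each lasting 2-60 s; NREM time not covered by a
CAP sequence is non-CAP (NCAP).  Coupling with avalanche occurrence is
quantified by the avalanche density F_av(t) (fraction of a sliding window,
default 10 s, occupied by avalanches) and by phi coefficients (Pearson
correlations of binary per-sample indicators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STAGES",
    "Hypnogram",
    "CapAnnotation",
    "BinaryIndicator",
    "DensitySeries",
    "read_hypnogram",
    "write_hypnogram",
    "read_cap_annotations",
    "write_cap_annotations",
    "build_indicators",
    "avalanche_density",
    "stage_density_summary",
    "phi_correlation",
    "occupancy_fraction",
    "cap_metrics",
    "group_comparison",
    "interval_jaccard",
]

STAGES = ("W", "N1", "N2", "N3", "REM")
NREM = ("N1", "N2", "N3")
CAP_LABELS = ("A1", "A2", "A3", "B")


@dataclass
class Hypnogram:
    """Ordered 30-s epoch labels in {W, N1, N2, N3, REM}."""

    epoch_stages: list
    epoch_length: float = 30.0
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.epoch_stages = list(self.epoch_stages)
        bad = [s for s in self.epoch_stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(set(bad))}")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length

    def stage_indicator_names(self, fs: float, n_samples: int) -> np.ndarray:
        """Per-sample stage label (epochs upsampled to the sample grid)."""
        idx = np.minimum(
            (np.arange(n_samples) / fs // self.epoch_length).astype(int),
            self.n_epochs - 1,
        )
        return np.asarray(self.epoch_stages, dtype=object)[idx]

    def stage_runs(self, stage: str) -> list:
        """Maximal contiguous runs of ``stage`` as (start_s, end_s)."""
        runs = []
        start = None
        for i, s in enumerate(self.epoch_stages + [None]):
            if s == stage and start is None:
                start = i
            elif s != stage and start is not None:
                runs.append(
                    (
                        self.start_s + start * self.epoch_length,
                        self.start_s + i * self.epoch_length,
                    )
                )
                start = None
        return runs


@dataclass
class CapAnnotation:
    """CAP phases as (onset_s, duration_s, label in {A1, A2, A3, B})."""

    phases: list
    min_cycles: int = 2  # cycles required for a run of phases to count as a
    # CAP sequence (atlas convention; sequences are typically 5-6 cycles)
    max_gap_s: float = 60.0

    def __post_init__(self) -> None:
        self.phases = sorted(
            [(float(o), float(d), str(l)) for o, d, l in self.phases]
        )
        for o, d, l in self.phases:
            if l not in CAP_LABELS:
                raise ValueError(f"unknown CAP label: {l}")
        for (o1, d1, _), (o2, _, _) in zip(self.phases, self.phases[1:]):
            if o2 < o1 + d1 - 1e-9:
                raise ValueError(
                    f"overlapping CAP phases at {o1:.2f}s and {o2:.2f}s"
                )

    @property
    def a_phases(self) -> list:
        return [p for p in self.phases if p[2].startswith("A")]

    def sequence_spans(self) -> list:
        """Maximal CAP sequences as (start_s, end_s).

        Consecutive phases with inter-phase gaps <= ``max_gap_s`` are grouped;
        a group qualifies as a sequence when it contains at least
        ``min_cycles`` A-B cycles (an A phase immediately followed by a B).
        """
        spans = []
        group: list = []
        for p in self.phases:
            if group and p[0] - (group[-1][0] + group[-1][1]) > self.max_gap_s:
                spans.extend(self._qualify(group))
                group = []
            group.append(p)
        if group:
            spans.extend(self._qualify(group))
        return spans

    def _qualify(self, group: list) -> list:
        cycles = sum(
            1
            for p, q in zip(group, group[1:])
            if p[2].startswith("A") and q[2] == "B"
        )
        if cycles >= self.min_cycles:
            return [(group[0][0], group[-1][0] + group[-1][1])]
        return []


@dataclass
class BinaryIndicator:
    """Per-sample 0/1 series on the recording grid; 0 on masked samples."""

    values: np.ndarray
    retained: np.ndarray
    feature_name: str
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool) & np.asarray(
            self.retained, dtype=bool
        )
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class DensitySeries:
    """Sliding-window avalanche density F_av, count N_av and mean duration."""

    t: np.ndarray  # window centers, s
    Fav: np.ndarray
    Nav: np.ndarray
    meanT: np.ndarray  # NaN where the window holds no onset
    valid: np.ndarray  # False where the window intersects masked time
    u0: float
    stride: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "Fav": self.Fav,
                "Nav": self.Nav,
                "meanT": self.meanT,
                "valid": self.valid,
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_hypnogram(path: str) -> Hypnogram:
    """TSV with columns (epoch_index, stage)."""
    df = pd.read_csv(path, sep="\t")
    if "stage" not in df.columns:
        raise ValueError(f"{path}: expected columns epoch_index, stage")
    for line, s in enumerate(df["stage"], start=2):
        if s not in STAGES:
            raise ValueError(f"{path}:{line}: unknown stage label {s!r}")
    return Hypnogram(list(df["stage"]))


def write_hypnogram(hyp: Hypnogram, path: str) -> None:
    pd.DataFrame(
        {"epoch_index": range(hyp.n_epochs), "stage": hyp.epoch_stages}
    ).to_csv(path, sep="\t", index=False)


def read_cap_annotations(path: str, hyp: Optional[Hypnogram] = None) -> CapAnnotation:
    """CSV with columns (onset_s, duration_s, label).

    Phases outside NREM (given a hypnogram) are dropped with a warning;
    durations outside [2, 60] s are retained with a warning; overlapping
    phases are an error.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        return CapAnnotation([])
    phases = []
    for _, row in df.iterrows():
        o, d, l = float(row["onset_s"]), float(row["duration_s"]), str(row["label"])
        if not 2.0 - 1e-9 <= d <= 60.0 + 1e-9:
            warnings.warn(
                f"CAP phase at {o:.1f}s has duration {d:.1f}s outside [2, 60]s"
            )
        if hyp is not None:
            mid = o + d / 2
            ep = int(mid // hyp.epoch_length)
            if ep >= hyp.n_epochs or hyp.epoch_stages[ep] not in NREM:
                warnings.warn(f"CAP phase at {o:.1f}s outside NREM; dropped")
                continue
        phases.append((o, d, l))
    return CapAnnotation(phases)


def write_cap_annotations(cap: CapAnnotation, path: str) -> None:
    pd.DataFrame(cap.phases, columns=["onset_s", "duration_s", "label"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------


def _intervals_to_indicator(
    intervals: Sequence[tuple], fs: float, n_samples: int
) -> np.ndarray:
    out = np.zeros(n_samples, dtype=bool)
    for start, end in intervals:
        i0 = max(0, int(round(start * fs)))
        i1 = min(n_samples, int(round(end * fs)))
        out[i0:i1] = True
    return out


def build_indicators(catalog, hyp: Hypnogram, cap: Optional[CapAnnotation], rec):
    """Binary per-sample indicators for avalanche occurrence, sleep stages
    and CAP features on the recording's sample grid.

    Features: avalanche, W, N1, N2, N3, REM, CAP (qualifying sequence spans),
    NCAP (NREM minus CAP), A, A1, A2, A3, B.  All indicators are 0 on masked
    samples.
    """
    fs, n = rec.fs, rec.n_samples
    if n < int(hyp.duration_s * fs) - 1:
        raise ValueError("recording shorter than hypnogram")
    retained = rec.mask
    out = {}

    av = np.zeros(n, dtype=bool)
    if catalog is not None:
        for a in catalog.avalanches:
            av[a.onset_sample : a.offset_sample] = True
    out["avalanche"] = BinaryIndicator(av, retained, "avalanche", fs)

    stage_names = hyp.stage_indicator_names(fs, n)
    for stage in STAGES:
        out[stage] = BinaryIndicator(stage_names == stage, retained, stage, fs)
    nrem = np.isin(stage_names, NREM)

    if cap is not None:
        cap_ind = _intervals_to_indicator(cap.sequence_spans(), fs, n) & nrem
        sub = {
            l: _intervals_to_indicator(
                [(o, o + d) for o, d, lab in cap.phases if lab == l], fs, n
            )
            & nrem
            for l in CAP_LABELS
        }
    else:
        cap_ind = np.zeros(n, dtype=bool)
        sub = {l: np.zeros(n, dtype=bool) for l in CAP_LABELS}
    out["CAP"] = BinaryIndicator(cap_ind, retained, "CAP", fs)
    out["NCAP"] = BinaryIndicator(nrem & ~cap_ind, retained, "NCAP", fs)
    for l in CAP_LABELS:
        out[l] = BinaryIndicator(sub[l], retained, l, fs)
    out["A"] = BinaryIndicator(
        sub["A1"] | sub["A2"] | sub["A3"], retained, "A", fs
    )
    return out


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------


def avalanche_density(
    catalog,
    rec,
    u0: float = 10.0,
    stride: Optional[float] = None,
) -> DensitySeries:
    """F_av(t) = (time occupied by avalanches in a sliding window of length
    u0) / u0, plus per-window avalanche count N_av (by onset) and mean
    duration of those avalanches.  Windows intersecting masked time are
    marked invalid.  Default stride is one sample."""
    fs = rec.fs
    w = int(round(u0 * fs))
    if w < 2:
        raise ValueError("u0 must cover at least 2 samples")
    if stride is None:
        stride = 1.0 / fs
    step = max(1, int(round(stride * fs)))
    n = rec.n_samples
    if n < w:
        raise ValueError("recording shorter than one window")

    in_av = np.zeros(n, dtype=np.float64)
    onset = np.zeros(n, dtype=np.float64)
    onset_T = np.zeros(n, dtype=np.float64)
    for a in catalog.avalanches:
        in_av[a.onset_sample : a.offset_sample] = 1.0
        onset[a.onset_sample] += 1.0
        onset_T[a.onset_sample] += a.duration

    bad = (~rec.mask).astype(np.float64)

    def win_sum(x: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(x)))
        return c[w:] - c[:-w]

    starts = np.arange(0, n - w + 1, step)
    occ = win_sum(in_av)[starts]
    n_on = win_sum(onset)[starts]
    sum_T = win_sum(onset_T)[starts]
    n_bad = win_sum(bad)[starts]

    with np.errstate(invalid="ignore", divide="ignore"):
        meanT = np.where(n_on > 0, sum_T / np.maximum(n_on, 1), np.nan)
    return DensitySeries(
        t=rec.t0 + (starts + w / 2) / fs,
        Fav=occ / w,
        Nav=n_on,
        meanT=meanT,
        valid=n_bad == 0,
        u0=u0,
        stride=step / fs,
    )


def stage_density_summary(density: DensitySeries, hyp: Hypnogram) -> dict:
    """Mean F_av per sleep stage plus a first-vs-last-N3 comparison.

    Stage membership is by window center.  The first/last N3 are the first
    and last maximal contiguous N3 runs; their window densities are compared
    with a two-sample t statistic.
    """
    idx = np.minimum(
        (density.t // hyp.epoch_length).astype(int), hyp.n_epochs - 1
    )
    stage_of_win = np.asarray(hyp.epoch_stages, dtype=object)[idx]
    out = {"stage_means": {}}
    for stage in STAGES:
        sel = (stage_of_win == stage) & density.valid
        out["stage_means"][stage] = (
            float(density.Fav[sel].mean()) if sel.any() else np.nan
        )
    runs = hyp.stage_runs("N3")
    if not runs:
        out["first_vs_last_N3"] = None
        return out
    if len(runs) == 1:
        raise ValueError("only one N3 run; first-vs-last comparison undefined")

    def run_densities(run):
        sel = (density.t >= run[0]) & (density.t < run[1]) & density.valid
        return density.Fav[sel]

    first, last = run_densities(runs[0]), run_densities(runs[-1])
    t, p = stats.ttest_ind(first, last, equal_var=False)
    out["first_vs_last_N3"] = {
        "mean_first": float(first.mean()),
        "mean_last": float(last.mean()),
        "t": float(t),
        "p": float(p),
    }
    return out


# ---------------------------------------------------------------------------
# Correlation and occupancy
# ---------------------------------------------------------------------------


def phi_correlation(x: BinaryIndicator, y: BinaryIndicator) -> float:
    """Pearson correlation of two binary indicators over retained samples
    (equivalently the 2x2 contingency-table phi coefficient)."""
    if x.values.shape != y.values.shape:
        raise ValueError("indicators on different grids")
    if not np.array_equal(x.retained, y.retained):
        raise ValueError("indicators with different retained-sample sets")
    xv = x.values[x.retained]
    yv = y.values[y.retained]
    if xv.all() or (~xv).all():
        raise ValueError(f"indicator {x.feature_name!r} is constant")
    if yv.all() or (~yv).all():
        raise ValueError(f"indicator {y.feature_name!r} is constant")
    return float(np.corrcoef(xv, yv)[0, 1])


def occupancy_fraction(a: BinaryIndicator, b: BinaryIndicator) -> float:
    """Fraction of b's positive (retained) samples where a is also positive,
    e.g. the fraction of CAP phase-A time occupied by avalanches."""
    bv = b.values[b.retained]
    if not bv.any():
        raise ValueError(f"indicator {b.feature_name!r} has no positive samples")
    av = a.values[a.retained]
    return float((av & bv).sum() / bv.sum())


def interval_jaccard(
    truth: np.ndarray, detected: Sequence[tuple]
) -> float:
    """Area Jaccard between the union of ground-truth intervals and the union
    of detected intervals that intersect at least one ground-truth interval.

    Detections that touch no ground-truth interval are excluded, so the
    metric measures boundary fidelity and misses rather than the background
    false-alarm rate (which has its own dedicated statistics)."""
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if truth.shape[0] == 0:
        raise ValueError("no ground-truth intervals")
    det = np.asarray(list(detected), dtype=float).reshape(-1, 2)
    matched = []
    for a, b in det:
        if np.any((a < truth[:, 1]) & (b > truth[:, 0])):
            matched.append((a, b))
    events = []
    for a, b in truth:
        events.append((a, 1, 0))
        events.append((b, -1, 0))
    for a, b in matched:
        events.append((a, 0, 1))
        events.append((b, 0, -1))
    events.sort()
    inter = union = 0.0
    ct = cd = 0
    prev = events[0][0]
    for t, dt_, dd in events:
        seg = t - prev
        if ct > 0 and cd > 0:
            inter += seg
        if ct > 0 or cd > 0:
            union += seg
        ct += dt_
        cd += dd
        prev = t
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# CAP metrics and group statistics
# ---------------------------------------------------------------------------


def cap_metrics(cap: CapAnnotation, hyp: Hypnogram) -> dict:
    """Summary metrics of the CAP annotation.

    CAP time = total length of qualifying CAP sequences; CAP rate = CAP time
    over total NREM time; plus sequence/cycle counts and per-subtype phase
    statistics."""
    nrem_s = sum(
        hyp.epoch_length for s in hyp.epoch_stages if s in NREM
    )
    if nrem_s == 0:
        raise ValueError("hypnogram has no NREM time")
    spans = cap.sequence_spans()
    cap_time = sum(e - s for s, e in spans)
    cycles = sum(
        1
        for p, q in zip(cap.phases, cap.phases[1:])
        if p[2].startswith("A") and q[2] == "B"
    )
    out = {
        "cap_time_s": cap_time,
        "cap_rate": cap_time / nrem_s,
        "n_sequences": len(spans),
        "mean_sequence_length_s": cap_time / len(spans) if spans else np.nan,
        "n_cycles": cycles,
        "nrem_time_s": nrem_s,
    }
    durs = {l: [d for _, d, lab in cap.phases if lab == l] for l in CAP_LABELS}
    a_durs = [d for _, d, lab in cap.phases if lab.startswith("A")]
    out["phase_A_mean_s"] = float(np.mean(a_durs)) if a_durs else np.nan
    out["phase_B_mean_s"] = float(np.mean(durs["B"])) if durs["B"] else np.nan
    a_total = sum(a_durs)
    for l in ("A1", "A2", "A3"):
        out[f"{l}_mean_duration_s"] = (
            float(np.mean(durs[l])) if durs[l] else np.nan
        )
        out[f"{l}_count"] = len(durs[l])
        out[f"{l}_time_share_of_cap"] = (
            sum(durs[l]) / cap_time if cap_time > 0 else np.nan
        )
    return out


def group_comparison(
    groups: Sequence[Sequence[float]],
    paired: bool = False,
    alpha_normality: float = 0.05,
) -> dict:
    """Omnibus + pairwise group comparison with a normality gate.

    Each group is Shapiro-Wilk tested at ``alpha_normality``; if all pass,
    the omnibus test is one-way ANOVA and pairwise tests are Welch t tests,
    otherwise Kruskal-Wallis and Mann-Whitney.  Pairwise p values are
    Bonferroni-adjusted.  A paired two-group design uses the paired t test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 3:
            raise ValueError("each group needs n >= 3")
    normal = all(
        stats.shapiro(g).pvalue > alpha_normality if np.ptp(g) > 0 else False
        for g in groups
    )
    out = {"normal": bool(normal)}
    if paired:
        if len(groups) != 2:
            raise ValueError("paired design requires exactly 2 groups")
        t, p = stats.ttest_rel(groups[0], groups[1])
        out.update(test="paired t", statistic=float(t), p=float(p))
        return out
    if normal:
        f, p = stats.f_oneway(*groups)
        out.update(test="one-way ANOVA", statistic=float(f), p=float(p))
    else:
        h, p = stats.kruskal(*groups)
        out.update(test="Kruskal-Wallis", statistic=float(h), p=float(p))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if normal:
                _, pp = stats.ttest_ind(groups[i], groups[j], equal_var=False)
            else:
                _, pp = stats.mannwhitneyu(
                    groups[i], groups[j], alternative="two-sided"
                )
            pairwise[(i, j)] = min(1.0, float(pp) * n_pairs)
    out["pairwise_bonferroni"] = pairwise
    return out
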