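"""Avalanche detection.

An avalanche is a maximal run of samples in which at least one channel shows
a supra-threshold excursion; it is preceded and followed by samples with no
excursion on any channel.  Its duration T is the run length in seconds.  Its
size s sums |z| over all supra-threshold (channel, sample) cells — per
sample in 'sample_sum' mode (units SD) or multiplied by the sample interval
in the default 'integrated' mode (units SD*s), which makes sizes comparable
across recordings with different sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import DetectionConfig, ExcursionRaster, MultichannelRecording

__all__ = [
    "Avalanche",
    "AvalancheCatalog",
    "BranchingEstimate",
    "extract_avalanches",
    "estimate_branching_parameter",
    "filter_catalog_by_intervals",
    "write_catalog",
    "read_catalog",
]


@dataclass(frozen=True)
class Avalanche:
    onset_sample: int
    offset_sample: int  # half-open
    duration: float  # seconds
    size: float  # SD*s (integrated) or SD (sample_sum)
    n_channels_involved: int


@dataclass
class AvalancheCatalog:
    """Ordered, disjoint avalanches with the detection context."""

    avalanches: list
    fs: float
    theta: float
    size_mode: str
    total_retained_time: float  # seconds

    def __len__(self) -> int:
        return len(self.avalanches)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([a.size for a in self.avalanches])

    @property
    def durations(self) -> np.ndarray:
        return np.array([a.duration for a in self.avalanches])

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([a.onset_sample / self.fs for a in self.avalanches])

    @property
    def total_avalanche_time(self) -> float:
        return float(self.durations.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [a.onset_sample / self.fs for a in self.avalanches],
                "offset_s": [a.offset_sample / self.fs for a in self.avalanches],
                "duration_s": [a.duration for a in self.avalanches],
                "size": [a.size for a in self.avalanches],
                "n_channels": [a.n_channels_involved for a in self.avalanches],
            }
        )


@dataclass(frozen=True)
class BranchingEstimate:
    sigma_hat: float
    bin_width: float
    n_avalanches_used: int


def _runs(any_beyond: np.ndarray) -> tuple:
    padded = np.concatenate(([False], any_beyond, [False]))
    d = np.diff(padded.astype(np.int8))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def extract_avalanches(
    raster: ExcursionRaster,
    rec: MultichannelRecording,
    cfg: DetectionConfig = DetectionConfig(),
) -> AvalancheCatalog:
    """Cluster the excursion raster into avalanches.

    Runs adjacent to a masked sample are discarded (a truncated run would
    bias both s and T); runs touching the first or last sample of the
    recording are kept.
    """
    if raster.beyond.shape != rec.signal.shape:
        raise ValueError("raster and recording grids differ")
    beyond = raster.beyond
    n = rec.n_samples
    any_beyond = beyond.any(axis=0)
    starts, ends = _runs(any_beyond)

    keep = np.ones(starts.size, dtype=bool)
    prev = starts - 1
    has_prev = prev >= 0
    keep[has_prev] &= rec.mask[prev[has_prev]]
    has_next = ends < n
    keep[has_next] &= rec.mask[ends[has_next]]
    starts, ends = starts[keep], ends[keep]

    contrib = (np.abs(rec.signal) * beyond).sum(axis=0)
    csum = np.concatenate(([0.0], np.cumsum(contrib)))
    sizes = csum[ends] - csum[starts]
    if cfg.size_mode == "integrated":
        sizes = sizes / rec.fs
    # channels involved per run
    ch_csum = np.concatenate(
        [np.zeros((rec.n_channels, 1)), np.cumsum(beyond, axis=1)], axis=1
    )
    n_ch = ((ch_csum[:, ends] - ch_csum[:, starts]) > 0).sum(axis=0)

    avalanches = [
        Avalanche(int(s), int(e), (e - s) / rec.fs, float(sz), int(nc))
        for s, e, sz, nc in zip(starts, ends, sizes, n_ch)
    ]
    return AvalancheCatalog(
        avalanches,
        rec.fs,
        raster.theta,
        cfg.size_mode,
        total_retained_time=float(rec.mask.sum() / rec.fs),
    )


def estimate_branching_parameter(
    catalog: AvalancheCatalog,
    raster: ExcursionRaster,
    bin_width: Optional[float] = None,
) -> BranchingEstimate:
    """Branching parameter from the catalog.

    Each avalanche is discretized into bins of ``bin_width`` (default 4
    sample intervals) from its onset.  A channel-event is one channel's
    contiguous supra-threshold run, assigned to the bin in which it starts.
    sigma_hat is the mean, over avalanches spanning at least two bins, of
    (channel-events starting in bin 2) / (channel-events starting in bin 1).
    """
    fs = catalog.fs
    if bin_width is None:
        bin_width = 4.0 / fs
    if bin_width <= 1.0 / fs:
        raise ValueError("bin_width must exceed one sample interval")
    bw = int(round(bin_width * fs))

    # channel-run start samples, pooled over channels, sorted
    starts_all = []
    for c in range(raster.beyond.shape[0]):
        s, _ = _runs(raster.beyond[c])
        starts_all.append(s)
    ev = np.sort(np.concatenate(starts_all)) if starts_all else np.empty(0)

    ratios = []
    for a in catalog.avalanches:
        if a.offset_sample - a.onset_sample <= bw:
            continue
        b0 = a.onset_sample
        e1 = np.searchsorted(ev, b0 + bw) - np.searchsorted(ev, b0)
        e2 = np.searchsorted(ev, min(b0 + 2 * bw, a.offset_sample)) - np.searchsorted(
            ev, b0 + bw
        )
        if e1 > 0:
            ratios.append(e2 / e1)
    if not ratios:
        raise ValueError("no avalanche spans two bins; cannot estimate sigma")
    return BranchingEstimate(float(np.mean(ratios)), bw / fs, len(ratios))


def filter_catalog_by_intervals(
    catalog: AvalancheCatalog, intervals: Sequence[tuple]
) -> AvalancheCatalog:
    """Keep avalanches whose onset lies in any half-open [start, end) interval
    (e.g. the first or last N3 run)."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("empty interval list")
    onsets = catalog.onsets_s
    keep = np.zeros(len(catalog.avalanches), dtype=bool)
    for start, end in intervals:
        keep |= (onsets >= start) & (onsets < end)
    # union length of the intervals
    merged: list = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    union = sum(b - a for a, b in merged)
    return AvalancheCatalog(
        [a for a, k in zip(catalog.avalanches, keep) if k],
        catalog.fs,
        catalog.theta,
        catalog.size_mode,
        total_retained_time=float(union),
    )


def write_catalog(catalog: AvalancheCatalog, path: str) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog(path: str, fs: float, theta: float = 2.0, size_mode: str = "integrated") -> AvalancheCatalog:
    df = pd.read_csv(path, sep="\t")
    avs = [
        Avalanche(
            int(round(r.onset_s * fs)),
            int(round(r.offset_s * fs)),
            float(r.duration_s),
            float(r.size),
            int(r.n_channels),
        )
        for r in df.itertuples()
    ]
    return AvalancheCatalog(avs, fs, theta, size_mode, total_retained_time=np.nan)
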