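"""Recording ingestion and normalization.

The detector operates on per-channel z-scored signals: each channel is
standardized to zero mean and unit SD over the artifact-free (retained)
samples, and a supra-threshold excursion is any sample with |z| strictly
greater than the threshold theta (default 2 SD).  The threshold choice is
justified by the Gaussian-deviation check: the pooled amplitude density of
sleep EEG departs from its best Gaussian fit around +/-2 SD, so smaller
thresholds admit noise while larger ones miss genuine collective events.
"""

from __future__ import annotations

import os
import struct
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultichannelRecording",
    "DetectionConfig",
    "ExcursionRaster",
    "GaussianityReport",
    "read_recording",
    "write_recording_tsv",
    "write_recording_edf",
    "apply_artifact_mask",
    "zscore_normalize",
    "detect_excursions",
    "gaussianity_report",
]


@dataclass
class MultichannelRecording:
    """channels x samples signal with sampling rate and per-sample mask.

    ``mask`` is True for retained samples.  The time axis is preserved when
    artifact intervals are masked; masked samples are excluded from all
    downstream statistics.
    """

    signal: np.ndarray
    fs: float
    channel_labels: Optional[Sequence[str]] = None
    mask: Optional[np.ndarray] = None
    t0: float = 0.0
    is_zscored: bool = False

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.mask is None:
            self.mask = np.ones(self.signal.shape[1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.signal.shape[1],):
                raise ValueError("mask length must equal number of samples")
        if self.channel_labels is None:
            self.channel_labels = [f"CH{i + 1}" for i in range(self.n_channels)]
        elif len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "MultichannelRecording":
        return MultichannelRecording(
            self.signal.copy(),
            self.fs,
            list(self.channel_labels),
            self.mask.copy(),
            self.t0,
            self.is_zscored,
        )


@dataclass(frozen=True)
class DetectionConfig:
    """theta in SD units; size_mode 'integrated' (SD*s) or 'sample_sum' (SD)."""

    theta: float = 2.0
    size_mode: str = "integrated"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.size_mode not in ("integrated", "sample_sum"):
            raise ValueError("size_mode must be 'integrated' or 'sample_sum'")


@dataclass
class ExcursionRaster:
    """Boolean channels x samples raster: True where |z| > theta and the
    sample is retained."""

    beyond: np.ndarray
    theta: float
    fs: float


@dataclass
class GaussianityReport:
    bin_centers: np.ndarray
    amplitude_density: np.ndarray
    gaussian_fit: tuple  # (mean, sd) of the least-squares Gaussian
    deviation_onset_sd: float  # np.inf if no persistent deviation found


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_recording(
    path: str,
    format: Optional[str] = None,
    fs_override: Optional[float] = None,
) -> MultichannelRecording:
    """Read an EDF/EDF+ or TSV-matrix recording (raw units, all-true mask).

    TSV matrices are samples x channels with a header row of channel labels
    and require ``fs_override``; EDF supplies its own sampling rate.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "edf" if ext == ".edf" else "tsv_matrix"
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        picks = [
            i
            for i, ch in enumerate(raw.ch_names)
            if "annotation" not in ch.lower()
        ]
        data = raw.get_data(picks=picks, units="uV")
        labels = [raw.ch_names[i] for i in picks]
        return MultichannelRecording(data, float(raw.info["sfreq"]), labels)
    if format == "tsv_matrix":
        if fs_override is None:
            raise ValueError("TSV matrix input requires fs_override")
        df = pd.read_csv(path, sep="\t")
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"empty recording file: {path}")
        return MultichannelRecording(
            df.to_numpy(dtype=float).T, fs_override, list(df.columns)
        )
    raise ValueError(f"unknown format: {format}")


def write_recording_tsv(rec: MultichannelRecording, path: str) -> None:
    pd.DataFrame(rec.signal.T, columns=list(rec.channel_labels)).to_csv(
        path, sep="\t", index=False
    )


def write_recording_edf(rec: MultichannelRecording, path: str) -> None:
    """Write a minimal EDF file (16-bit, per-channel physical scaling).

    One data record per second; the recording is truncated to a whole number
    of seconds, and the sampling rate must be integral.
    """
    fs = int(rec.fs)
    if fs != rec.fs:
        raise ValueError("EDF export requires an integer sampling rate")
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels
    data = rec.signal[:, : n_records * fs]
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = np.where(pmax > pmin, pmax - pmin, 1.0)
    dmin, dmax = -32768, 32767
    digital = np.round(
        (data - pmin[:, None]) / span[:, None] * (dmax - dmin) + dmin
    ).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("synthetic", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * nch), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(nch), 4),
        ]
    )
    fields = [
        (16, [str(lbl) for lbl in rec.channel_labels]),
        (80, [""] * nch),
        (8, ["uV"] * nch),
        (8, [f"{v:.6g}" for v in pmin]),
        (8, [f"{v:.6g}" for v in pmin + span]),
        (8, [str(dmin)] * nch),
        (8, [str(dmax)] * nch),
        (80, [""] * nch),
        (8, [str(fs)] * nch),
        (32, [""] * nch),
    ]
    with open(path, "wb") as f:
        f.write(header)
        for width, values in fields:
            for v in values:
                f.write(pad(v, width))
        for r in range(n_records):
            chunk = digital[:, r * fs : (r + 1) * fs]
            f.write(chunk.tobytes())


# ---------------------------------------------------------------------------
# Masking and normalization
# ---------------------------------------------------------------------------


def apply_artifact_mask(
    rec: MultichannelRecording, intervals: Sequence[tuple]
) -> MultichannelRecording:
    """Mask half-open [start_s, end_s) intervals (artifact/wake segments).

    The time axis is preserved; masked samples are simply excluded from every
    downstream statistic.
    """
    out = rec.copy()
    for start, end in intervals:
        if end <= start:
            raise ValueError(f"interval end {end} <= start {start}")
        if start < rec.t0 - 1e-9 or end > rec.t0 + rec.duration_s + 1e-9:
            raise ValueError(f"interval ({start}, {end}) outside recording span")
        i0 = max(0, int(np.floor((start - rec.t0) * rec.fs)))
        i1 = min(rec.n_samples, int(np.floor((end - rec.t0) * rec.fs)))
        out.mask[i0:i1] = False
    return out


def zscore_normalize(rec: MultichannelRecording) -> MultichannelRecording:
    """Standardize each channel to zero mean / unit SD over retained samples."""
    out = rec.copy()
    retained = rec.signal[:, rec.mask]
    if retained.shape[1] == 0:
        raise ValueError("no retained samples to normalize over")
    mu = retained.mean(axis=1)
    sd = retained.std(axis=1)
    for c, s in enumerate(sd):
        if s == 0:
            raise ValueError(
                f"channel {rec.channel_labels[c]} has zero variance over "
                "retained samples"
            )
    out.signal = (rec.signal - mu[:, None]) / sd[:, None]
    out.is_zscored = True
    return out


def detect_excursions(
    rec: MultichannelRecording, cfg: DetectionConfig = DetectionConfig()
) -> ExcursionRaster:
    """Supra-threshold excursions: |z| strictly greater than theta, on
    retained samples only."""
    if not rec.is_zscored:
        raise ValueError("recording must be z-scored before excursion detection")
    beyond = (np.abs(rec.signal) > cfg.theta) & rec.mask[None, :]
    return ExcursionRaster(beyond, cfg.theta, rec.fs)


# ---------------------------------------------------------------------------
# Gaussian-deviation check
# ---------------------------------------------------------------------------


def gaussianity_report(
    rec: MultichannelRecording,
    tolerance: float = 0.5,
    bin_width: float = 0.1,
    z_max: float = 6.0,
    persistence_bins: int = 3,
    min_count: int = 5,
) -> GaussianityReport:
    """Compare the pooled amplitude density with its best Gaussian fit.

    ``deviation_onset_sd`` is the smallest |z| at which the empirical density
    exceeds the fitted Gaussian by a relative excess > ``tolerance`` for
    ``persistence_bins`` consecutive bins (on either tail, requiring at least
    ``min_count`` samples per bin); infinity if no such onset exists.
    """
    from scipy.optimize import curve_fit
    from scipy.stats import norm

    z = rec.signal[:, rec.mask].ravel()
    if z.size < 10_000:
        raise ValueError("need at least 1e4 retained samples")
    edges = np.arange(-z_max, z_max + bin_width / 2, bin_width)
    counts, _ = np.histogram(z, bins=edges)
    density = counts / (z.size * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, mu, sd):
        return norm.pdf(x, mu, sd)

    core = np.abs(centers) <= 4.0
    (mu, sd), _ = curve_fit(
        gauss, centers[core], density[core], p0=(0.0, 1.0)
    )
    fit = gauss(centers, mu, sd)

    if not np.isfinite(tolerance):
        return GaussianityReport(centers, density, (mu, sd), np.inf)

    onset = np.inf
    for side in (centers >= 0, centers < 0):
        idx = np.flatnonzero(side)
        idx = idx[np.argsort(np.abs(centers[idx]))]  # inside -> out
        excess = (density[idx] - fit[idx]) / np.maximum(fit[idx], 1e-300)
        ok = (excess > tolerance) & (counts[idx] >= min_count)
        run = 0
        for j, flag in enumerate(ok):
            run = run + 1 if flag else 0
            if run >= persistence_bins:
                cand = abs(centers[idx[j - persistence_bins + 1]])
                onset = min(onset, cand)
                break
    return GaussianityReport(centers, density, (mu, sd), onset)
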