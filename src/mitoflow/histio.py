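"""Per-cell fluorescence events and intensity histograms.

Flow cytometers report per-cell total fluorescence either as raw event
lists or as pre-binned histograms; most instruments use a logarithmic
amplifier, so histograms frequently arrive with log-spaced bins.  This
module provides the two containers (:class:`EventList`,
:class:`IntensityHistogram`), plain-text readers/writers for both, event
binning, log-to-linear rebinning, and histogram summaries.

Binning convention: bins are half-open ``[lo, hi)`` with the final bin
closed, so binned counts partition the in-range events exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EventList",
    "IntensityHistogram",
    "HistioError",
    "MissingColumnError",
    "NoValidEventsError",
    "EmptyRangeError",
    "linear_edges",
    "log_edges",
    "infer_scale",
    "read_events",
    "write_events",
    "read_histogram",
    "write_histogram",
    "bin_events",
    "log_to_linear_rebin",
    "rebin",
    "mean_intensity",
]

#: relative tolerance used to decide whether consecutive edge ratios are constant
LOG_EDGE_RTOL = 1e-9


class HistioError(ValueError):
    """Base error for histogram / event-list handling."""


class MissingColumnError(HistioError):
    """The requested column is absent from the input table."""


class NoValidEventsError(HistioError):
    """No row of the input parses to a positive, finite intensity."""


class EmptyRangeError(HistioError):
    """No event falls inside the requested bin range."""


@dataclass(frozen=True)
class EventList:
    """Per-cell total fluorescence intensities for one sample.

    Parameters
    ----------
    intensities
        One value per cell, arbitrary fluorescence units (AU).  Every
        value must be finite and strictly positive.
    label
        Free-text sample identifier.
    time_h
        Measurement time in hours relative to the first measurement.
    """

    intensities: np.ndarray
    label: str = ""
    time_h: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise NoValidEventsError("event list must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
            raise HistioError("all intensities must be finite and > 0")
        object.__setattr__(self, "intensities", arr)

    def __len__(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class IntensityHistogram:
    """Binned cell counts over fluorescence intensity.

    ``counts[i]`` is the number of cells with intensity in
    ``[bin_edges[i], bin_edges[i+1])`` (final bin closed).  Counts may be
    fractional after rebinning or forward-model application; only raw
    event binning yields integers.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    scale: str = "linear"
    time_h: float = 0.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise HistioError("need at least two bin edges")
        if counts.shape != (edges.size - 1,):
            raise HistioError("counts length must be len(bin_edges) - 1")
        if not np.all(np.diff(edges) > 0):
            raise HistioError("bin edges must be strictly increasing")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise HistioError("counts must be finite and non-negative")
        if not np.any(counts > 0):
            raise HistioError("histogram must contain at least one cell")
        if self.scale not in ("linear", "log"):
            raise HistioError(f"unknown scale {self.scale!r}")
        if self.scale == "log":
            if edges[0] <= 0:
                raise HistioError("log-scale edges must be positive")
            ratios = edges[1:] / edges[:-1]
            if not np.allclose(ratios, ratios[0], rtol=LOG_EDGE_RTOL, atol=0):
                raise HistioError("log-scale edges must have constant ratio")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def midpoints(self) -> np.ndarray:
        """Representative intensity per bin: arithmetic midpoint for linear
        bins, geometric midpoint for log bins (unbiased for log-uniform
        mass within a bin)."""
        lo, hi = self.bin_edges[:-1], self.bin_edges[1:]
        if self.scale == "log":
            return np.sqrt(lo * hi)
        return 0.5 * (lo + hi)

    def normalized(self) -> np.ndarray:
        """Counts rescaled to sum to 1."""
        return self.counts / self.total


def linear_edges(lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Equally spaced edges over ``[lo, hi]``."""
    if n_bins < 1 or hi <= lo:
        raise HistioError("need n_bins >= 1 and hi > lo")
    return np.linspace(lo, hi, n_bins + 1)


def log_edges(lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Geometrically spaced edges over ``[lo, hi]`` (lo > 0)."""
    if n_bins < 1 or lo <= 0 or hi <= lo:
        raise HistioError("need n_bins >= 1 and hi > lo > 0")
    return np.geomspace(lo, hi, n_bins + 1)


def infer_scale(edges: Sequence[float]) -> str:
    """Guess whether an edge vector is linear or log spaced.

    Constant consecutive-edge ratio (and non-constant spacing) is read as
    log; anything else as linear.  Two-edge histograms are ambiguous and
    default to linear.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.size < 3 or edges[0] <= 0:
        return "linear"
    diffs = np.diff(edges)
    ratios = edges[1:] / edges[:-1]
    ratio_const = np.allclose(ratios, ratios[0], rtol=1e-6, atol=0)
    diff_const = np.allclose(diffs, diffs[0], rtol=1e-6, atol=0)
    return "log" if ratio_const and not diff_const else "linear"


def read_events(path: str | Path, column: str = "intensity") -> EventList:
    """Read an event CSV (one row per cell) into an :class:`EventList`.

    Rows whose intensity is missing, non-numeric, non-finite or not
    strictly positive are dropped, and the number dropped is logged.
    ``sample`` and ``time_h`` columns, when present and constant, populate
    the corresponding metadata fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event file not found: {path}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if column not in df.columns:
        raise MissingColumnError(
            f"column {column!r} not in {path.name} (has: {', '.join(df.columns)})"
        )
    raw = pd.to_numeric(df[column], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(raw) & (raw > 0)
    n_dropped = int(raw.size - keep.sum())
    if keep.sum() == 0:
        raise NoValidEventsError(
            f"no positive finite intensities in column {column!r} of {path.name}"
        )
    if n_dropped:
        logger.warning(
            "%s: dropped %d of %d rows (non-numeric, non-finite or <= 0 intensity)",
            path.name, n_dropped, raw.size,
        )
    label = ""
    if "sample" in df.columns:
        vals = df.loc[keep, "sample"].astype(str).unique()
        label = vals[0] if len(vals) == 1 else ""
    time_h = 0.0
    if "time_h" in df.columns:
        tvals = pd.to_numeric(df.loc[keep, "time_h"], errors="coerce").dropna().unique()
        if len(tvals) == 1:
            time_h = float(tvals[0])
    return EventList(raw[keep], label=label, time_h=time_h)


def write_events(events: EventList, path: str | Path) -> None:
    """Write an :class:`EventList` as the canonical event CSV."""
    df = pd.DataFrame({"intensity": events.intensities})
    if events.label:
        df["sample"] = events.label
    df["time_h"] = events.time_h
    # shortest exact representation so write -> read round-trips bitwise
    df.to_csv(path, index=False, float_format="%.17g")


def read_histogram(path: str | Path) -> IntensityHistogram:
    """Read a histogram CSV (``bin_lo,bin_hi,count`` plus ``# scale=``,
    ``# time_h=`` comment lines)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"histogram file not found: {path}")
    scale, time_h = None, 0.0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("scale="):
                scale = body.split("=", 1)[1].strip()
            elif body.startswith("time_h="):
                time_h = float(body.split("=", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("bin_lo", "bin_hi", "count"):
        if col not in df.columns:
            raise MissingColumnError(f"column {col!r} not in {path.name}")
    lo = df["bin_lo"].to_numpy(dtype=float)
    hi = df["bin_hi"].to_numpy(dtype=float)
    if not np.allclose(lo[1:], hi[:-1], rtol=1e-12):
        raise HistioError("histogram bins must be contiguous")
    edges = np.append(lo, hi[-1])
    if scale is None:
        scale = infer_scale(edges)
    return IntensityHistogram(edges, df["count"].to_numpy(dtype=float), scale, time_h)


def write_histogram(hist: IntensityHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale={hist.scale}\n")
        fh.write(f"# time_h={hist.time_h:g}\n")
        fh.write("bin_lo,bin_hi,count\n")
        for lo, hi, c in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
            fh.write(f"{lo:.17g},{hi:.17g},{c:.17g}\n")


def _bin_array(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # np.histogram uses half-open bins with the last bin closed -- exactly
    # the convention adopted here.
    counts, _ = np.histogram(values, bins=edges)
    return counts.astype(float)


def bin_events(
    events: EventList,
    edges: Sequence[float],
    scale: str | None = None,
) -> IntensityHistogram:
    """Bin an event list onto the given edges.

    Counts are integer and sum to the number of events inside
    ``[edges[0], edges[-1]]``.  ``scale`` is inferred from the edge
    spacing when not given.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise HistioError("edges must be strictly increasing with at least 2 values")
    counts = _bin_array(events.intensities, edges)
    if counts.sum() == 0:
        raise EmptyRangeError(
            f"no events inside [{edges[0]:g}, {edges[-1]:g}]"
        )
    if scale is None:
        scale = infer_scale(edges)
    return IntensityHistogram(edges, counts, scale, events.time_h)


def _overlap_rebin(src_edges: np.ndarray, counts: np.ndarray,
                   dst_edges: np.ndarray) -> np.ndarray:
    """Redistribute per-bin mass assuming it is uniform in intensity
    within each source bin.  Exactly mass-conserving when the destination
    edges cover the source range."""
    lo_s, hi_s = src_edges[:-1], src_edges[1:]
    lo_d, hi_d = dst_edges[:-1], dst_edges[1:]
    # overlap length between every (src, dst) bin pair
    left = np.maximum(lo_s[:, None], lo_d[None, :])
    right = np.minimum(hi_s[:, None], hi_d[None, :])
    overlap = np.clip(right - left, 0.0, None)
    frac = overlap / (hi_s - lo_s)[:, None]
    return counts @ frac


def log_to_linear_rebin(hist: IntensityHistogram, n_bins: int) -> IntensityHistogram:
    """Convert a log-binned histogram to ``n_bins`` linear bins over the
    same intensity range.

    Mass within each log bin is spread uniformly in intensity over the
    overlapping linear bins; the total count is preserved exactly (up to
    floating point) and counts become fractional.
    """
    if hist.scale != "log":
        raise HistioError("input histogram must be log-scale")
    if n_bins < 2:
        raise HistioError("n_bins must be >= 2")
    dst = linear_edges(hist.bin_edges[0], hist.bin_edges[-1], n_bins)
    new_counts = _overlap_rebin(hist.bin_edges, hist.counts, dst)
    return IntensityHistogram(dst, new_counts, "linear", hist.time_h)


def rebin(hist: IntensityHistogram, edges: Sequence[float],
          scale: str | None = None) -> IntensityHistogram:
    """General uniform-spreading rebin onto arbitrary destination edges."""
    edges = np.asarray(edges, dtype=float)
    new_counts = _overlap_rebin(hist.bin_edges, hist.counts, edges)
    if scale is None:
        scale = infer_scale(edges)
    return IntensityHistogram(edges, new_counts, scale, hist.time_h)


def mean_intensity(hist: IntensityHistogram) -> float:
    """Count-weighted mean of the bin representative intensities."""
    if hist.total <= 0:
        raise HistioError("cannot take the mean of an empty histogram")
    return float(np.sum(hist.midpoints * hist.counts) / hist.total)
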