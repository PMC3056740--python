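"""Mitotic partitioning model and the histogram transfer operator.

At mitosis a labelled parent cell splits its material between two
daughters in proportion ``x : (1 - x)``.  Across many divisions the
splitting ratio ``x`` is modelled as an equal-weight mixture of two
normal densities with means ``alpha`` and ``1 - alpha`` and common
standard deviation ``delta_alpha``, truncated to the physical range
``[0, 1]`` and renormalized::

    P(x) = [ N(x; alpha, delta_alpha^2) + N(x; 1 - alpha, delta_alpha^2) ] / (2 Z)

The truncation is symmetric about 1/2, so the mean splitting ratio stays
exactly 1/2 and the population mean intensity obeys the moment identity
``<I_t> = (1 - f_t/2) <I_0>``, where ``f_t`` is the fraction of cells
that divided during the measurement interval.

The transfer operator maps the parent-intensity histogram onto the
later histogram.  A cell of intensity ``I'`` that divides yields a
randomly sampled daughter with intensity density ``(1/I') P(I/I')``; a
cell that does not divide keeps its intensity (a Dirac term, here the
destination bin containing ``I'``).  Discretized on histogram bins this
is a column-stochastic kernel: each parent cell is accounted for exactly
once, so total cell count is conserved — the cytometer samples a fixed
number of cells, it does not see the population double.

Because ``alpha`` and ``1 - alpha`` generate identical models, ``alpha``
is always reported in the canonical half ``[0.5, 1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import ndtr

from .histio import HistioError, IntensityHistogram, mean_intensity

__all__ = [
    "PartitionParams",
    "TransferParams",
    "TransferKernel",
    "TransferModelError",
    "KernelRangeError",
    "partition_pdf",
    "partition_cdf",
    "build_kernel",
    "apply_transfer",
    "estimate_dividing_fraction",
    "FtEstimate",
    "multigeneration_ratio_pdf",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class TransferModelError(ValueError):
    """Invalid parameters or inputs to the transfer model."""


class KernelRangeError(TransferModelError):
    """The destination bin range loses too much divided mass."""


@dataclass(frozen=True)
class PartitionParams:
    """Mean and spread of the mitotic splitting-ratio distribution.

    ``alpha`` lives in the canonical half ``[0.5, 1]`` (``alpha = 0.5``
    is symmetric division); ``delta_alpha`` is the common standard
    deviation of the two mixture components, ``0 < delta_alpha <= 0.5``.
    """

    alpha: float
    delta_alpha: float

    def __post_init__(self) -> None:
        if not (0.5 <= self.alpha <= 1.0):
            raise TransferModelError(
                f"alpha must lie in [0.5, 1] (got {self.alpha}); "
                "use PartitionParams.canonical to fold alpha < 0.5"
            )
        if not (0.0 < self.delta_alpha <= 0.5):
            raise TransferModelError(
                f"delta_alpha must lie in (0, 0.5] (got {self.delta_alpha})"
            )

    @classmethod
    def canonical(cls, alpha: float, delta_alpha: float) -> "PartitionParams":
        """Build params, folding ``alpha < 0.5`` onto the equivalent
        ``1 - alpha`` (the model is invariant under this reflection)."""
        if alpha < 0.5:
            alpha = 1.0 - alpha
        return cls(alpha, delta_alpha)


@dataclass(frozen=True)
class TransferParams:
    """Full parameter set of the transfer operator.

    ``dividing_fraction`` is the fraction of cells that underwent one
    mitosis during the ``interval_h`` hours between measurements.  For
    ``generations > 1`` the operator is iterated once per generation with
    the per-generation fractions in ``generation_fractions``.
    """

    partition: PartitionParams
    dividing_fraction: float
    interval_h: float = 19.0
    generations: int = 1
    generation_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dividing_fraction <= 1.0):
            raise TransferModelError(
                f"dividing_fraction must lie in [0, 1] (got {self.dividing_fraction})"
            )
        if self.generations < 1:
            raise TransferModelError("generations must be >= 1")
        if self.generation_fractions is not None:
            gf = tuple(float(f) for f in self.generation_fractions)
            if len(gf) != self.generations:
                raise TransferModelError(
                    "generation_fractions must have length == generations"
                )
            if any(not (0.0 <= f <= 1.0) for f in gf):
                raise TransferModelError("generation fractions must lie in [0, 1]")
            object.__setattr__(self, "generation_fractions", gf)
        elif self.generations > 1:
            raise TransferModelError(
                "generation_fractions required when generations > 1"
            )

    @property
    def fractions(self) -> tuple[float, ...]:
        """Per-generation dividing fractions (length == generations)."""
        if self.generation_fractions is not None:
            return self.generation_fractions
        return (self.dividing_fraction,)

    def to_dict(self) -> dict:
        d = {
            "alpha": self.partition.alpha,
            "delta_alpha": self.partition.delta_alpha,
            "dividing_fraction": self.dividing_fraction,
            "interval_h": self.interval_h,
            "generations": self.generations,
        }
        if self.generation_fractions is not None:
            d["generation_fractions"] = list(self.generation_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransferParams":
        gf = d.get("generation_fractions")
        return cls(
            partition=PartitionParams(float(d["alpha"]), float(d["delta_alpha"])),
            dividing_fraction=float(d["dividing_fraction"]),
            interval_h=float(d.get("interval_h", 19.0)),
            generations=int(d.get("generations", 1)),
            generation_fractions=tuple(gf) if gf is not None else None,
        )


@dataclass(frozen=True)
class TransferKernel:
    """Discretized transfer operator: ``matrix[i, j]`` is the probability
    that a cell from source bin ``j`` (parent intensity) is observed in
    destination bin ``i`` after the interval.  Columns sum to 1."""

    matrix: np.ndarray
    source_edges: np.ndarray
    dest_edges: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if np.any(m < 0):
            raise TransferModelError("kernel entries must be non-negative")
        colsums = m.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6, rtol=0):
            raise TransferModelError("kernel columns must sum to 1 within 1e-6")
        object.__setattr__(self, "matrix", m)

    def __matmul__(self, counts: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(counts, dtype=float)


# ---------------------------------------------------------------------------
# splitting-ratio density


def _truncation_mass(params: PartitionParams) -> float:
    """Mass of the untruncated equal-weight mixture inside [0, 1]."""
    a, s = params.alpha, params.delta_alpha
    # both components carry equal mass in [0, 1] by the alpha <-> 1-alpha symmetry
    return float(
        0.5 * (ndtr((1.0 - a) / s) - ndtr(-a / s))
        + 0.5 * (ndtr(a / s) - ndtr((a - 1.0) / s))
    )


def partition_pdf(x, params: PartitionParams):
    """Splitting-ratio probability density at ``x`` (0 outside [0, 1]).

    Equal-weight two-component normal mixture with means ``alpha`` and
    ``1 - alpha`` and standard deviation ``delta_alpha``, truncated to
    ``[0, 1]`` and renormalized to unit integral.  Symmetric about 1/2.
    """
    x_arr = np.asarray(x, dtype=float)
    a, s = params.alpha, params.delta_alpha
    z = _truncation_mass(params)
    t1 = (x_arr - a) / s
    t2 = (x_arr - (1.0 - a)) / s
    dens = 0.5 * (np.exp(-0.5 * t1 * t1) + np.exp(-0.5 * t2 * t2)) / (s * _SQRT_2PI)
    dens = np.where((x_arr >= 0.0) & (x_arr <= 1.0), dens / z, 0.0)
    return float(dens) if np.isscalar(x) or x_arr.ndim == 0 else dens


def partition_cdf(x, params: PartitionParams):
    """CDF of the truncated splitting-ratio mixture (0 below 0, 1 above 1)."""
    x_arr = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    a, s = params.alpha, params.delta_alpha

    def untrunc(v):
        return 0.5 * (ndtr((v - a) / s) + ndtr((v - (1.0 - a)) / s))

    g0 = untrunc(0.0)
    z = _truncation_mass(params)
    out = (untrunc(x_arr) - g0) / z
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# discretized transfer operator

#: maximum fraction of divided daughter mass that may fall outside the
#: destination range before the kernel refuses to silently renormalize
MAX_TRUNCATION_LOSS = 0.05


def _midpoints(edges: np.ndarray) -> np.ndarray:
    return 0.5 * (edges[:-1] + edges[1:])


def _divided_weights(ratio_edges: np.ndarray, partition: PartitionParams) -> np.ndarray:
    """Per-source-bin destination weights of the divided component.

    ``ratio_edges[j, i]`` is ``dest_edge[i] / I'_j`` clipped to [0, 1];
    the weight of destination bin ``i`` for source bin ``j`` is the
    splitting-ratio CDF increment across the bin, i.e. the exact integral
    of the daughter-intensity density ``(1/I') P(I/I')`` over the bin.
    """
    F = partition_cdf(ratio_edges, partition)
    return np.diff(F, axis=1)  # (n_src, n_dst)


def build_kernel(
    source_edges: Sequence[float],
    dest_edges: Sequence[float],
    params: TransferParams,
) -> TransferKernel:
    """Discretize the single-generation transfer operator on linear bins.

    Each source bin is represented by its arithmetic midpoint ``I'``.
    With probability ``f_t`` the cell divides and a random daughter is
    observed, with daughter intensity distributed as ``(1/I') P(I/I')``;
    with probability ``1 - f_t`` it stays in the bin containing ``I'``.
    Columns are renormalized to sum to exactly 1 to absorb edge-rounding;
    a destination range losing more than 5% of the divided mass raises
    :class:`KernelRangeError` instead of being silently renormalized.
    """
    if params.generations != 1:
        raise TransferModelError("build_kernel is single-generation; iterate apply_transfer")
    src = np.asarray(source_edges, dtype=float)
    dst = np.asarray(dest_edges, dtype=float)
    if src.size < 2 or dst.size < 2 or np.any(np.diff(src) <= 0) or np.any(np.diff(dst) <= 0):
        raise TransferModelError("edges must be strictly increasing, length >= 2")
    ft = params.dividing_fraction
    mids = _midpoints(src)
    if np.any(mids <= 0):
        raise TransferModelError("source bin midpoints must be positive")

    ratio_edges = np.clip(dst[None, :] / mids[:, None], 0.0, 1.0)
    W = _divided_weights(ratio_edges, params.partition)  # (n_src, n_dst)
    colmass = W.sum(axis=1)
    if np.any(colmass < 1.0 - MAX_TRUNCATION_LOSS):
        worst = float(1.0 - colmass.min())
        raise KernelRangeError(
            f"{worst:.1%} of divided daughter mass falls outside the destination "
            f"range [{dst[0]:g}, {dst[-1]:g}]; widen the destination range"
        )

    idx = np.searchsorted(dst, mids, side="right") - 1
    idx[mids == dst[-1]] = dst.size - 2  # last bin closed
    if np.any(idx < 0) or np.any(idx > dst.size - 2):
        raise KernelRangeError(
            "a source bin midpoint lies outside the destination range; widen it"
        )

    matrix = ft * W.T  # (n_dst, n_src)
    matrix[idx, np.arange(mids.size)] += 1.0 - ft
    matrix /= matrix.sum(axis=0, keepdims=True)
    return TransferKernel(matrix, src, dst)


def apply_transfer(
    hist: IntensityHistogram,
    params: TransferParams,
    dest_edges: Sequence[float] | None = None,
) -> IntensityHistogram:
    """Apply the transfer operator to a linear-scale histogram.

    Returns the model-predicted histogram after the measurement interval,
    on ``dest_edges`` (default: the input edges).  Total count is
    conserved.  For ``generations > 1`` the single-generation kernel is
    applied once per generation with that generation's dividing fraction.
    Log-scale inputs must be rebinned first (``log_to_linear_rebin``).
    """
    if hist.scale != "linear":
        raise TransferModelError(
            "apply_transfer requires a linear-scale histogram; "
            "convert log inputs with histio.log_to_linear_rebin first"
        )
    edges = hist.bin_edges
    dst = np.asarray(dest_edges, dtype=float) if dest_edges is not None else edges
    counts = hist.counts.astype(float)
    kernels: dict[float, TransferKernel] = {}
    for gen, f in enumerate(params.fractions):
        key = f if gen > 0 and np.array_equal(edges, dst) else None
        if key is not None and key in kernels:
            kern = kernels[key]
        else:
            single = TransferParams(params.partition, f, params.interval_h)
            kern = build_kernel(edges, dst, single)
            if key is not None:
                kernels[key] = kern
        counts = kern.matrix @ counts
        edges = dst
    return IntensityHistogram(dst, counts, "linear", hist.time_h + params.interval_h)


# ---------------------------------------------------------------------------
# moment estimator


class FtEstimate(NamedTuple):
    """Moment estimate of the dividing fraction.

    ``raw`` is ``2 (1 - <I_t>/<I_0>)`` before clamping; ``ft`` is the
    estimate clamped to ``[0, 1]``; ``clamped`` flags when clamping
    changed the value (e.g. the later mean fell below half the initial
    mean, which the single-division model cannot produce).
    """

    ft: float
    raw: float
    clamped: bool

    def __float__(self) -> float:
        return self.ft


def estimate_dividing_fraction(
    h0: IntensityHistogram, ht: IntensityHistogram
) -> FtEstimate:
    """Estimate the dividing fraction from the pair of mean intensities.

    Each division halves the expected daughter intensity regardless of
    partitioning asymmetry, so ``<I_t> = (1 - f_t/2) <I_0>`` and
    ``f_t = 2 (1 - <I_t>/<I_0>)``.  Valid when both histograms sample
    equal cell numbers.
    """
    m0 = mean_intensity(h0)
    mt = mean_intensity(ht)
    if m0 <= 0:
        raise TransferModelError("initial mean intensity must be positive")
    raw = 2.0 * (1.0 - mt / m0)
    ft = min(1.0, max(0.0, raw))
    return FtEstimate(ft=ft, raw=raw, clamped=(ft != raw))


# ---------------------------------------------------------------------------
# multi-generation splitting-ratio density

#: grid resolution of the log-ratio convolution, as a fraction of delta_alpha
_LOG_GRID_STEP_FRACTION = 0.01
_MAX_GRID_POINTS = 1 << 18


@lru_cache(maxsize=32)
def _multigen_grid(alpha: float, delta_alpha: float, k: int) -> tuple[np.ndarray, float]:
    """Convolved log-ratio density grid for ``k`` generations (cached --
    evaluation points vary while the grid depends only on the params)."""
    f1, d = _log_ratio_grid(PartitionParams(alpha, delta_alpha))
    fk = f1
    for _ in range(k - 1):
        fk = fftconvolve(fk, f1)
        fk = np.clip(fk, 0.0, None) * d
        fk /= np.trapezoid(fk, dx=d)
    return fk, d


def _log_ratio_grid(params: PartitionParams) -> tuple[np.ndarray, float]:
    """Density of ``L = -log x`` for one generation, on a uniform grid.

    The grid extends to where the ratio density is negligible; the
    sampled density is renormalized to unit trapezoidal mass so repeated
    convolution does not accumulate discretization bias.
    """
    a, s = params.alpha, params.delta_alpha
    x_floor = max((1.0 - a) - 10.0 * s, 0.0)
    l_max = 25.0 if x_floor <= 1e-10 else -math.log(x_floor)
    d = s * _LOG_GRID_STEP_FRACTION
    n = int(math.ceil(l_max / d)) + 1
    if n > _MAX_GRID_POINTS:
        n = _MAX_GRID_POINTS
        d = l_max / (n - 1)
    l = np.arange(n) * d
    x = np.exp(-l)
    f = partition_pdf(x, params) * x  # change of variables to L = -log x
    mass = np.trapezoid(f, dx=d)
    return f / mass, d


def multigeneration_ratio_pdf(x, params: PartitionParams, k: int):
    """Density of the cumulative splitting ratio after ``k`` generations.

    The cumulative ratio is the product of ``k`` independent draws from
    the single-division ratio density; the product density is computed by
    numerical convolution in log-ratio space (FFT on a uniform grid with
    step ``delta_alpha / 100``).  ``k = 1`` returns the single-division
    density exactly.
    """
    if k < 1:
        raise TransferModelError("generation count k must be >= 1")
    if k == 1:
        return partition_pdf(x, params)
    fk, d = _multigen_grid(params.alpha, params.delta_alpha, k)
    l_grid = np.arange(fk.size) * d
    scalar_in = np.isscalar(x) or np.asarray(x).ndim == 0
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x_arr)
    ok = (x_arr > 0.0) & (x_arr <= 1.0)
    lq = -np.log(x_arr[ok])
    out[ok] = np.interp(lq, l_grid, fk, left=0.0, right=0.0) / x_arr[ok]
    return float(out[0]) if scalar_in else out
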