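"""Monte-Carlo single-cell population generator and brute-force oracle.

Emulates the dye-dilution experiment: a labelled parent population with
a broad unimodal (log-normal) intensity distribution is measured, then
remeasured after an interval during which each cell divides at most once
with probability ``f_t``.  A divided cell draws a splitting ratio ``x``
from the truncated two-component mixture and ONE daughter is retained
uniformly at random — the cytometer samples a fixed number of cells, so
the sample size stays constant and the population-mean identity
``<I_t> = (1 - f_t/2) <I_0>`` holds exactly in expectation.

Two partitioning modes are provided:

* ``ratio`` — intensities are continuous; a divided cell's retained
  intensity is exactly ``ratio * I_0``.
* ``organelle`` — the label sits in discrete organelles (e.g. dye-loaded
  endosomes); each of a cell's organelles goes to daughter A
  independently with probability ``x`` (binomial partitioning layered on
  the mixture-drawn bias), and measured intensity is exactly
  ``organelle count * unit_intensity`` — the linearity between
  fluorescence and labelled-organelle number built in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from . import histio
from .histio import EventList, IntensityHistogram
from .transfer import PartitionParams, TransferModelError, TransferParams

__all__ = [
    "SimConfig",
    "PopulationSample",
    "simulate_pair",
    "simulate_multigeneration",
    "sample_to_histograms",
    "draw_partition_ratios",
    "write_sample",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the population simulator.

    ``init_log_mean`` / ``init_log_sd`` parameterize the log-normal
    parent intensity distribution (natural-log scale, AU).  In organelle
    mode the per-cell organelle count is Poisson with a log-normally
    mixed mean (``organelles_mean`` on average, same relative spread as
    the ratio-mode parents), and ``unit_intensity`` converts counts to
    fluorescence.
    """

    n_cells: int
    params: TransferParams
    init_log_mean: float = math.log(1000.0)
    init_log_sd: float = 0.5
    partition_mode: str = "ratio"
    organelles_mean: float = 50.0
    unit_intensity: float = 20.0
    seed: int = 0
    keep_both_daughters: bool = False
    fixed_bias: bool = False  # organelle mode: use x = alpha instead of mixture draws

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise TransferModelError("n_cells must be >= 1")
        if self.init_log_sd <= 0:
            raise TransferModelError("init_log_sd must be > 0")
        if self.partition_mode not in ("ratio", "organelle"):
            raise TransferModelError(f"unknown partition_mode {self.partition_mode!r}")
        if self.partition_mode == "organelle":
            if self.unit_intensity <= 0:
                raise TransferModelError("unit_intensity must be > 0")
            if self.organelles_mean <= 0:
                raise TransferModelError("organelles_mean must be > 0")
        if self.keep_both_daughters and len(self.params.fractions) > 1:
            raise TransferModelError(
                "keep_both_daughters is single-generation only"
            )

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(
            n_cells=self.n_cells,
            init_log_mean=self.init_log_mean,
            init_log_sd=self.init_log_sd,
            partition_mode=self.partition_mode,
            organelles_mean=self.organelles_mean,
            unit_intensity=self.unit_intensity,
            seed=self.seed,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(
            n_cells=int(d["n_cells"]),
            params=TransferParams.from_dict(d),
            init_log_mean=float(d.get("init_log_mean", math.log(1000.0))),
            init_log_sd=float(d.get("init_log_sd", 0.5)),
            partition_mode=str(d.get("partition_mode", "ratio")),
            organelles_mean=float(d.get("organelles_mean", 50.0)),
            unit_intensity=float(d.get("unit_intensity", 20.0)),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class PopulationSample:
    """Event-level outcome of a simulated measurement pair.

    ``realized_ratios`` holds, for each divided cell (in cell order), the
    cumulative fraction of the initial material retained by the sampled
    descendant; undivided cells are excluded.
    """

    intensities_t0: np.ndarray
    intensities_t: np.ndarray
    divided: np.ndarray
    realized_ratios: np.ndarray
    n_divisions: np.ndarray

    def __post_init__(self) -> None:
        n = self.intensities_t0.size
        if not (self.intensities_t.size == self.divided.size == self.n_divisions.size == n):
            raise TransferModelError("per-cell arrays must have equal length")
        if self.realized_ratios.size != int(np.count_nonzero(self.divided)):
            raise TransferModelError("one realized ratio per divided cell")


def draw_partition_ratios(
    rng: np.random.Generator, partition: PartitionParams, n: int
) -> np.ndarray:
    """Draw ``n`` splitting ratios from the truncated mixture.

    Component-wise sampling: the two components carry equal mass inside
    [0, 1] by symmetry, so an equal-probability component choice followed
    by an inverse-CDF truncated-normal draw reproduces the truncated
    mixture exactly (and is fully deterministic given the generator).
    """
    if n == 0:
        return np.empty(0)
    a, s = partition.alpha, partition.delta_alpha
    mu = np.where(rng.random(n) < 0.5, a, 1.0 - a)
    u = rng.random(n)
    lo = (0.0 - mu) / s
    hi = (1.0 - mu) / s
    return truncnorm.ppf(u, lo, hi, loc=mu, scale=s)


def _division_step(
    rng: np.random.Generator,
    partition: PartitionParams,
    fraction: float,
    intensities: np.ndarray,
    counts: np.ndarray | None,
    fixed_bias: bool,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """One synchronous division round; returns updated intensities,
    updated organelle counts (or None), the divided mask and the
    per-divided-cell retained ratio."""
    n = intensities.size
    div = rng.random(n) < fraction
    m = int(div.sum())
    if m == 0:
        return intensities, counts, div, np.empty(0)
    if fixed_bias:
        x = np.full(m, alpha)
    else:
        x = draw_partition_ratios(rng, partition, m)
    keep_a = rng.random(m) < 0.5
    if counts is None:
        ratio = np.where(keep_a, x, 1.0 - x)
        out = intensities.copy()
        out[div] = out[div] * ratio
        return out, None, div, ratio
    parent = counts[div]
    k_a = rng.binomial(parent, x)
    kept = np.where(keep_a, k_a, parent - k_a)
    ratio = kept / parent
    new_counts = counts.copy()
    new_counts[div] = kept
    return None, new_counts, div, ratio


def _initial_population(cfg: SimConfig, rng: np.random.Generator):
    """Parent intensities (and organelle counts in organelle mode)."""
    if cfg.partition_mode == "ratio":
        i0 = rng.lognormal(cfg.init_log_mean, cfg.init_log_sd, cfg.n_cells)
        return i0, None
    # log-normally mixed Poisson keeps the broad unimodal shape while the
    # material itself stays discrete; mean-preserving mixing factor
    lam = cfg.organelles_mean * rng.lognormal(
        -0.5 * cfg.init_log_sd**2, cfg.init_log_sd, cfg.n_cells
    )
    counts = np.maximum(rng.poisson(lam), 1)
    return counts.astype(float) * cfg.unit_intensity, counts


def _simulate(cfg: SimConfig, fractions: Sequence[float]) -> PopulationSample:
    rng = np.random.default_rng(cfg.seed)
    i0, counts = _initial_population(cfg, rng)
    cur = i0.copy()
    n_div = np.zeros(cfg.n_cells, dtype=int)
    cum_ratio = np.ones(cfg.n_cells)
    for f in fractions:
        if counts is None:
            cur, _, div, ratio = _division_step(
                rng, cfg.params.partition, f, cur, None,
                cfg.fixed_bias, cfg.params.partition.alpha,
            )
        else:
            _, counts, div, ratio = _division_step(
                rng, cfg.params.partition, f, cur, counts,
                cfg.fixed_bias, cfg.params.partition.alpha,
            )
            cur = counts.astype(float) * cfg.unit_intensity
        cum_ratio[div] *= ratio
        n_div[div] += 1
    divided = n_div > 0
    return PopulationSample(
        intensities_t0=i0,
        intensities_t=cur,
        divided=divided,
        realized_ratios=cum_ratio[divided],
        n_divisions=n_div,
    )


def simulate_pair(config: SimConfig) -> PopulationSample:
    """Simulate one measurement pair with a single division round.

    With ``keep_both_daughters`` the divided cells contribute both
    daughters (population grows); by default one daughter is retained at
    random so the later sample has the same size as the initial one.
    """
    if not config.keep_both_daughters:
        return _simulate(config, (config.params.dividing_fraction,))
    # both-daughter variant for sensitivity studies (ratio mode)
    if config.partition_mode != "ratio":
        raise TransferModelError("keep_both_daughters supports ratio mode only")
    rng = np.random.default_rng(config.seed)
    i0, _ = _initial_population(config, rng)
    div = rng.random(config.n_cells) < config.params.dividing_fraction
    m = int(div.sum())
    x = draw_partition_ratios(rng, config.params.partition, m)
    it = np.concatenate([i0[~div], i0[div] * x, i0[div] * (1.0 - x)])
    i0_out = np.concatenate([i0[~div], i0[div], i0[div]])
    divided = np.concatenate(
        [np.zeros(config.n_cells - m, bool), np.ones(2 * m, bool)]
    )
    return PopulationSample(
        intensities_t0=i0_out,
        intensities_t=it,
        divided=divided,
        realized_ratios=np.concatenate([x, 1.0 - x]),
        n_divisions=divided.astype(int),
    )


def simulate_multigeneration(config: SimConfig, k: int) -> PopulationSample:
    """Iterate the division step over ``k`` generations.

    Uses ``config.params.generation_fractions`` when of length ``k``,
    else the single dividing fraction for every generation.  One random
    descendant per lineage is retained; the realized per-cell cumulative
    ratio is the product of the per-generation draws.  ``k = 1``
    reproduces :func:`simulate_pair` exactly at the same seed.
    """
    if k < 1:
        raise TransferModelError("generation count k must be >= 1")
    gf = config.params.generation_fractions
    if gf is not None and len(gf) == k:
        fractions = gf
    else:
        fractions = (config.params.dividing_fraction,) * k
    return _simulate(config, fractions)


def sample_to_histograms(
    sample: PopulationSample,
    edges: Sequence[float],
    time_h: float = 0.0,
    interval_h: float = 19.0,
) -> tuple[IntensityHistogram, IntensityHistogram]:
    """Bin the two measurements onto a shared edge set."""
    edges = np.asarray(edges, dtype=float)
    scale = histio.infer_scale(edges)
    c0 = histio._bin_array(sample.intensities_t0, edges)
    ct = histio._bin_array(sample.intensities_t, edges)
    if c0.sum() == 0 or ct.sum() == 0:
        raise histio.EmptyRangeError(
            f"no events inside [{edges[0]:g}, {edges[-1]:g}]"
        )
    h0 = IntensityHistogram(edges, c0, scale, time_h)
    ht = IntensityHistogram(edges, ct, scale, time_h + interval_h)
    return h0, ht


def default_edges(sample: PopulationSample, n_bins: int = 256) -> np.ndarray:
    """Shared linear edges covering both measurements from zero."""
    hi = float(max(sample.intensities_t0.max(), sample.intensities_t.max()))
    return histio.linear_edges(0.0, hi * (1.0 + 1e-9), n_bins)


def write_sample(sample: PopulationSample, prefix: str | Path,
                 interval_h: float = 19.0, label: str = "") -> tuple[Path, Path]:
    """Write the pair as two event CSVs (``<prefix>_t0.csv``,
    ``<prefix>_t.csv``); non-positive intensities (possible only for
    organelle-mode daughters that inherited nothing) are dropped."""
    prefix = Path(prefix)
    paths = []
    for suffix, values, t in (
        ("_t0", sample.intensities_t0, 0.0),
        ("_t", sample.intensities_t, interval_h),
    ):
        keep = values > 0
        ev = EventList(values[keep], label=label, time_h=t)
        out = prefix.parent / (prefix.name + suffix + ".csv")
        histio.write_events(ev, out)
        paths.append(out)
    return paths[0], paths[1]
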