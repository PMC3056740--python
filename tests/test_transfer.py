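"""Splitting-ratio density, transfer kernel and moment estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.signal import argrelmax

from mitoflow.histio import IntensityHistogram, linear_edges, mean_intensity
from mitoflow.simulate import SimConfig, default_edges, sample_to_histograms, simulate_pair
from mitoflow.transfer import (
    KernelRangeError,
    PartitionParams,
    TransferModelError,
    TransferParams,
    apply_transfer,
    build_kernel,
    estimate_dividing_fraction,
    multigeneration_ratio_pdf,
    partition_cdf,
    partition_pdf,
)


class TestPartitionPdf:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        alpha=st.floats(0.5, 1.0),
        dalpha=st.floats(0.01, 0.5),
        x=st.floats(0.0, 1.0),
    )
    def test_symmetric_about_half(self, alpha, dalpha, x):
        p = PartitionParams(alpha, dalpha)
        assert partition_pdf(x, p) == pytest.approx(partition_pdf(1.0 - x, p), rel=1e-9)

    def test_symmetric_division_peaks_at_half(self):
        p = PartitionParams(0.5, 0.1)
        xs = np.linspace(0, 1, 2001)
        assert xs[np.argmax(partition_pdf(xs, p))] == pytest.approx(0.5, abs=1e-3)

    def test_modes_at_fitted_u2os_values(self):
        # dense-grid mode search at the fitted operating point
        p = PartitionParams(0.71, 0.11)
        xs = np.linspace(0, 1, 20001)
        modes = xs[argrelmax(partition_pdf(xs, p))[0]]
        assert len(modes) == 2
        assert modes[0] == pytest.approx(0.29, abs=0.01)
        assert modes[1] == pytest.approx(0.71, abs=0.01)

    @pytest.mark.parametrize(
        "alpha,dalpha", [(0.5, 0.1), (0.71, 0.11), (0.95, 0.3), (0.99, 0.02)]
    )
    def test_unit_integral(self, alpha, dalpha):
        p = PartitionParams(alpha, dalpha)
        integral, _ = quad(
            partition_pdf, 0.0, 1.0, args=(p,),
            points=[1 - alpha, 0.5, alpha], limit=200,
        )
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_zero_outside_unit_interval(self):
        p = PartitionParams(0.7, 0.2)
        assert partition_pdf(-0.01, p) == 0.0
        assert partition_pdf(1.01, p) == 0.0

    def test_cdf_matches_quadrature(self):
        p = PartitionParams(0.8, 0.15)
        for x in (0.1, 0.4, 0.9):
            expected, _ = quad(partition_pdf, 0.0, x, args=(p,), limit=200)
            assert partition_cdf(x, p) == pytest.approx(expected, abs=1e-10)

    def test_alpha_reflection_gives_identical_model(self):
        folded = PartitionParams.canonical(0.29, 0.11)
        direct = PartitionParams(0.71, 0.11)
        xs = np.linspace(0, 1, 501)
        np.testing.assert_array_equal(
            partition_pdf(xs, folded), partition_pdf(xs, direct)
        )

    @pytest.mark.parametrize(
        "alpha,dalpha", [(0.4, 0.1), (1.2, 0.1), (0.7, 0.0), (0.7, 0.6)]
    )
    def test_invalid_params_rejected(self, alpha, dalpha):
        with pytest.raises(TransferModelError):
            PartitionParams(alpha, dalpha)


class TestKernel:
    def test_no_division_is_identity(self):
        edges = linear_edges(0.0, 100.0, 32)
        params = TransferParams(PartitionParams(0.7, 0.1), 0.0)
        k = build_kernel(edges, edges, params)
        np.testing.assert_allclose(k.matrix, np.eye(32), atol=1e-12)

    def test_full_near_symmetric_division_halves(self):
        edges = linear_edges(0.0, 120.0, 120)  # unit-width bins
        params = TransferParams(PartitionParams(0.5, 0.01), 1.0)
        k = build_kernel(edges, edges, params)
        src = np.searchsorted(edges, 100.0, side="right") - 1
        col = k.matrix[:, src]
        mids = 0.5 * (edges[:-1] + edges[1:])
        assert mids[np.argmax(col)] == pytest.approx(50.0, abs=1.5)
        assert col[(mids > 45) & (mids < 55)].sum() > 0.99

    def test_column_sums_for_random_params(self, rng):
        edges = linear_edges(0.0, 400.0, 64)
        for _ in range(100):
            params = TransferParams(
                PartitionParams(rng.uniform(0.5, 1.0), rng.uniform(0.01, 0.5)),
                rng.uniform(0.0, 1.0),
            )
            k = build_kernel(edges, edges, params)
            np.testing.assert_allclose(k.matrix.sum(axis=0), 1.0, atol=1e-6)
            assert np.all(k.matrix >= 0)

    def test_narrow_destination_range_errors(self):
        src = linear_edges(0.0, 200.0, 40)
        dst = linear_edges(0.0, 60.0, 12)
        params = TransferParams(PartitionParams(0.5, 0.01), 1.0)
        with pytest.raises(KernelRangeError, match="widen"):
            build_kernel(src, dst, params)


class TestApplyTransfer:
    def test_no_division_identity(self, make_pair, u2os_params):
        h0, _, _ = make_pair(u2os_params, 5000, seed=21)
        out = apply_transfer(h0, TransferParams(u2os_params.partition, 0.0))
        np.testing.assert_allclose(out.counts, h0.counts, rtol=1e-12)

    def test_mean_identity_and_conservation(self, make_pair, rng, u2os_params):
        h0, _, _ = make_pair(u2os_params, 20_000, seed=23)
        for _ in range(20):
            ft = rng.uniform(0.0, 1.0)
            params = TransferParams(
                PartitionParams(rng.uniform(0.5, 1.0), rng.uniform(0.01, 0.5)), ft
            )
            out = apply_transfer(h0, params)
            assert out.total == pytest.approx(h0.total, rel=1e-6)
            ratio = mean_intensity(out) / mean_intensity(h0)
            assert ratio == pytest.approx(1.0 - ft / 2.0, rel=0.01)

    def test_monotone_dilution_in_dividing_fraction(self, make_pair, u2os_params):
        h0, _, _ = make_pair(u2os_params, 10_000, seed=25)
        means = [
            mean_intensity(
                apply_transfer(h0, TransferParams(u2os_params.partition, ft))
            )
            for ft in np.linspace(0.0, 1.0, 11)
        ]
        assert np.all(np.diff(means) < 0)

    def test_matches_event_level_simulation(self, u2os_params):
        cfg = SimConfig(n_cells=100_000, params=u2os_params, seed=27)
        sample = simulate_pair(cfg)
        h0, ht = sample_to_histograms(sample, default_edges(sample, 256))
        model = apply_transfer(h0, u2os_params)
        ks = np.max(np.abs(
            np.cumsum(model.normalized()) - np.cumsum(ht.normalized())
        ))
        assert ks < 0.02

    def test_rejects_log_scale_input(self, u2os_params):
        h = IntensityHistogram([1.0, 10.0, 100.0], [5.0, 5.0], scale="log")
        with pytest.raises(TransferModelError, match="log_to_linear_rebin"):
            apply_transfer(h, u2os_params)


class TestMomentEstimator:
    def test_identical_histograms_give_zero(self):
        h = IntensityHistogram(linear_edges(0, 10, 5), [1.0, 2.0, 3.0, 2.0, 1.0])
        est = estimate_dividing_fraction(h, h)
        assert est.ft == 0.0 and not est.clamped

    def test_half_mean_gives_one(self):
        h0 = IntensityHistogram([0.0, 2.0, 4.0], [0.0, 1.0])  # mean 3
        ht = IntensityHistogram([0.0, 2.0, 4.0], [1.0, 0.0])  # mean 1 -> ratio 1/3
        est = estimate_dividing_fraction(h0, ht)
        assert est.ft == 1.0 and est.clamped and est.raw > 1.0

    def test_recovers_generating_fraction(self, make_pair):
        params = TransferParams(PartitionParams(0.71, 0.11), 0.7)
        h0, ht, _ = make_pair(params, 10_000, seed=29)
        est = estimate_dividing_fraction(h0, ht)
        assert est.ft == pytest.approx(0.7, abs=0.03)


class TestMultigenerationPdf:
    def test_single_generation_reduces_exactly(self):
        p = PartitionParams(0.71, 0.11)
        xs = np.linspace(0, 1, 64)
        np.testing.assert_allclose(
            multigeneration_ratio_pdf(xs, p, 1), partition_pdf(xs, p), atol=1e-6
        )

    def test_two_generation_modes_near_ratio_products(self):
        # grid mode search against the products {a^2, a(1-a), (1-a)^2}
        p = PartitionParams(0.71, 0.05)
        xs = np.linspace(1e-4, 1.0, 40001)
        dens = multigeneration_ratio_pdf(xs, p, 2)
        modes = xs[argrelmax(dens, order=50)[0]]
        expected = [0.29**2, 0.71 * 0.29, 0.71**2]
        assert len(modes) == 3
        for m, e in zip(sorted(modes), expected):
            assert m == pytest.approx(e, abs=0.01)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_unit_integral(self, k):
        p = PartitionParams(0.71, 0.11)
        integral, _ = quad(
            multigeneration_ratio_pdf, 0.0, 1.0, args=(p, k), limit=400
        )
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_invalid_generation_count(self):
        with pytest.raises(TransferModelError):
            multigeneration_ratio_pdf(0.5, PartitionParams(0.7, 0.1), 0)


class TestTransferParams:
    def test_round_trips_through_flat_dict(self):
        params = TransferParams(
            PartitionParams(0.71, 0.11), 0.98, interval_h=19.0,
            generations=2, generation_fractions=(0.9, 0.5),
        )
        assert TransferParams.from_dict(params.to_dict()) == params

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dividing_fraction": 1.5},
            {"dividing_fraction": 0.5, "generations": 0},
            {"dividing_fraction": 0.5, "generations": 2},
            {"dividing_fraction": 0.5, "generations": 2,
             "generation_fractions": (0.5,)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(TransferModelError):
            TransferParams(PartitionParams(0.7, 0.1), **kwargs)
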