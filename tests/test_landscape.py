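import numpy as np
import pytest

from volscape.landscape import (
    build_landscape,
    compare_landscapes,
    find_minima_and_barrier,
)
from volscape.synthetic import EnergyFunctionSpec


def _two_point_landscape(counts, smoothing=0.0):
    coeffs = np.array([[-1.0, 0.0], [1.0, 0.0]])
    return build_landscape(coeffs, counts, bins=8, smoothing_sigma=smoothing)


class TestBuildLandscape:
    def test_equal_counts_both_zero(self):
        scape = _two_point_landscape([100, 100])
        energies = scape.energy[scape.defined]
        np.testing.assert_allclose(energies, 0.0, atol=1e-12)

    def test_boltzmann_ratio_exact_without_smoothing(self):
        # -ln(135/1000) = 2.0025...
        scape = _two_point_landscape([1000, 135])
        energies = np.sort(scape.energy[scape.defined])
        assert energies[0] == pytest.approx(0.0, abs=1e-12)
        assert energies[1] == pytest.approx(2.0025, abs=0.01)

    def test_single_class_single_bin(self):
        scape = build_landscape(np.array([[0.3, -0.2]]), [500], bins=8, smoothing_sigma=0.0)
        assert scape.defined.sum() == 1
        assert scape.energy[scape.defined][0] == 0.0
        assert scape.occupancy.sum() == 500

    def test_occupancy_preserves_total(self, rng):
        coeffs = rng.normal(size=(12, 2))
        counts = rng.integers(1, 500, size=12)
        scape = build_landscape(coeffs, counts, bins=16, smoothing_sigma=1.0)
        assert scape.occupancy.sum() == counts.sum()

    def test_energy_invariant_to_count_scaling(self, rng):
        coeffs = rng.normal(size=(10, 2))
        counts = rng.integers(1, 100, size=10)
        a = build_landscape(coeffs, counts, bins=8, smoothing_sigma=0.0)
        b = build_landscape(coeffs, counts * 7, bins=8, smoothing_sigma=0.0)
        np.testing.assert_allclose(
            a.energy[a.defined], b.energy[b.defined], atol=1e-12
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            build_landscape(np.array([[0.0, 1.0]]), [0])
        with pytest.raises(ValueError):
            build_landscape(np.array([[0.0, 1.0]]), [5], components=(0, 5))
        with pytest.raises(ValueError):
            build_landscape(np.array([[0.0, 1.0]]), [-1, 2])


def _double_well_landscape(total=100_000, smoothing=0.0, seed=0, barrier=3.0):
    efun = EnergyFunctionSpec(
        kind="double_well_barrier", well_centers=(-15.0, 15.0), barrier_height=barrier
    )
    thetas = np.linspace(-25, 25, 41)
    p = np.exp(-efun(thetas))
    p /= p.sum()
    counts = np.random.default_rng(seed).multinomial(total, p)
    coeffs = np.column_stack([thetas, 0.02 * thetas**2])  # curved 1D manifold
    # bin width matched to the class spacing: one class per bin, and few bins
    # on the curvature axis keep consecutive classes 8-connected
    scape = build_landscape(coeffs, counts, bins=(44, 8), smoothing_sigma=smoothing)
    return scape, efun, thetas


class TestMinimaAndBarrier:
    def test_flat_landscape_zero_barrier(self):
        coeffs = np.column_stack([np.linspace(-1, 1, 10), np.zeros(10)])
        scape = build_landscape(coeffs, np.full(10, 100), bins=10, smoothing_sigma=0.0)
        report = find_minima_and_barrier(scape)
        assert report.barrier_height == pytest.approx(0.0, abs=1e-12)

    def test_double_well_barrier_recovered(self):
        scape, _, _ = _double_well_landscape()
        report = find_minima_and_barrier(scape)
        assert report.barrier_height == pytest.approx(3.0, abs=0.3)
        assert len(report.minima) >= 2
        assert report.path, "a connecting path must be reported"

    def test_disconnected_minima_flagged(self):
        coeffs = np.array([[-1.0, -1.0], [1.0, 1.0]])
        scape = build_landscape(coeffs, [100, 80], bins=8, smoothing_sigma=0.0)
        report = find_minima_and_barrier(scape)
        assert report.disconnected
        assert np.isinf(report.barrier_height)

    def test_single_bin_no_barrier(self):
        scape = build_landscape(np.array([[0.0, 0.0]]), [10], bins=4, smoothing_sigma=0.0)
        report = find_minima_and_barrier(scape)
        assert report.barrier_height is None
        assert len(report.minima) == 1

    def test_smoothing_never_deepens_barrier(self):
        barriers = []
        for sigma in (0.5, 1.0, 2.0):
            scape, _, _ = _double_well_landscape(smoothing=sigma)
            barriers.append(find_minima_and_barrier(scape).barrier_height)
        assert barriers[1] <= barriers[0] + 1e-9
        assert barriers[2] <= barriers[1] + 1e-9


class TestCompareLandscapes:
    def test_self_comparison_is_null(self):
        scape, _, _ = _double_well_landscape()
        diff, summary = compare_landscapes(scape, scape)
        assert summary["max_abs_delta_energy"] == 0.0
        assert summary["occupied_area_ratio"] == 1.0

    def test_stiffer_harmonic_occupies_less_area(self):
        thetas = np.linspace(-25, 25, 41)
        landscapes = []
        for kappa in (0.02, 0.08):
            efun = EnergyFunctionSpec(kind="harmonic", stiffness=kappa)
            p = np.exp(-efun(thetas))
            p /= p.sum()
            counts = np.random.default_rng(3).multinomial(100_000, p)
            coeffs = np.column_stack([thetas, 0.02 * thetas**2])
            # common binning: fixed component grid via identical coefficients
            landscapes.append(
                build_landscape(coeffs, counts, bins=16, smoothing_sigma=0.0)
            )
        a, b = landscapes
        # rebin b onto a's edges by construction they share coefficients
        _, summary = compare_landscapes(a, b)
        assert summary["occupied_area_ratio"] < 1.0

    def test_incompatible_binning_rejected(self):
        a, _, _ = _double_well_landscape()
        coeffs = np.array([[-0.5, 0.1], [0.5, -0.1]])
        b = build_landscape(coeffs, [10, 10], bins=8, smoothing_sigma=0.0)
        with pytest.raises(ValueError):
            compare_landscapes(a, b)
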