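"""WHAM solver, unbinding free energy and barrier extraction."""

import numpy as np
import pytest

from kdelsolv.toy_models import Window, WindowSampleSet, sample_umbrella_windows
from kdelsolv.units import kbt
from kdelsolv.wham import (
    BarrierReport,
    ConvergenceError,
    PMFProfile,
    barrier_heights,
    pmf_from_repeats,
    read_pmf_tsv,
    unbinding_free_energy,
    wham_solve,
    write_pmf_tsv,
)

T = 298.15
KT = kbt(T)


def bin_averaged_reference(potential, bin_range, n_bins):
    """Independent oracle: −kT ln of the bin-averaged Boltzmann density."""
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    out = []
    for i in range(n_bins):
        xs = np.linspace(edges[i], edges[i + 1], 64)
        mass = np.trapezoid(np.exp(-potential(xs) / KT), xs)
        out.append(-KT * np.log(mass / (edges[i + 1] - edges[i])))
    return np.asarray(out)


def aligned_max_err(pmf, ref):
    d = pmf.free_energy - ref
    d = d - d.mean()
    return np.max(np.abs(d))


def make_harmonic_set(seed=7, n=30000):
    centers = np.arange(-1.8, 1.8 + 1e-9, 0.15)
    return sample_umbrella_windows(
        lambda x: 0.5 * 2.0 * x**2, [(c, 30.0) for c in centers], n,
        temperature=T, seed=seed,
    )


def make_doublewell_set(seed=8, n=30000):
    centers = np.arange(-1.8, 1.8 + 1e-9, 0.15)
    return sample_umbrella_windows(
        lambda x: 3.0 * (x**2 - 1) ** 2, [(c, 30.0) for c in centers], n,
        temperature=T, seed=seed,
    )


class TestWhamSolve:
    def test_uniform_unbiased_window_gives_flat_pmf(self):
        rng = np.random.default_rng(0)
        samples = rng.uniform(0.0, 1.0, 200000)
        ws = WindowSampleSet(
            windows=(Window(center=0.5, force_constant=1e-9, samples=samples),),
            temperature=T,
        )
        pmf = wham_solve(ws, n_bins=10, bin_range=(0.0, 1.0))
        assert pmf.free_energy.max() - pmf.free_energy.min() < 0.05 * KT

    def test_harmonic_recovery_curvature(self):
        pmf = wham_solve(make_harmonic_set(), n_bins=100, bin_range=(-1.5, 1.5))
        curvature = 2 * np.polyfit(pmf.bin_centers, pmf.free_energy, 2)[0]
        assert curvature == pytest.approx(2.0, rel=0.05)

    def test_doublewell_matches_quadrature_oracle(self):
        pot = lambda x: 3.0 * (x**2 - 1) ** 2
        pmf = wham_solve(
            make_doublewell_set(n=60000), n_bins=100, bin_range=(-1.5, 1.5)
        )
        ref = bin_averaged_reference(pot, (-1.5, 1.5), 100)
        assert aligned_max_err(pmf, ref) < 0.05 * KT

    def test_window_permutation_invariance(self):
        ws = make_doublewell_set(n=5000)
        pmf = wham_solve(ws, n_bins=60, bin_range=(-1.5, 1.5))
        idx = np.random.default_rng(1).permutation(len(ws.windows))
        ws_p = WindowSampleSet(
            windows=tuple(ws.windows[i] for i in idx), temperature=T
        )
        pmf_p = wham_solve(ws_p, n_bins=60, bin_range=(-1.5, 1.5))
        assert np.max(np.abs(pmf.free_energy - pmf_p.free_energy)) < 1e-6

    def test_duplicating_whole_window_set_invariant(self):
        ws = make_harmonic_set(n=3000)
        pmf = wham_solve(ws, n_bins=60, bin_range=(-1.5, 1.5))
        ws_d = WindowSampleSet(windows=ws.windows + ws.windows, temperature=T)
        pmf_d = wham_solve(ws_d, n_bins=60, bin_range=(-1.5, 1.5))
        assert np.max(np.abs(pmf.free_energy - pmf_d.free_energy)) < 1e-6

    def test_kj_force_constants_converted(self):
        ws = make_harmonic_set(n=20000)
        in_kj = WindowSampleSet(
            windows=tuple(
                Window(w.center, w.force_constant * 4.184, w.samples)
                for w in ws.windows
            ),
            temperature=T,
            k_unit="kJ/mol",
        )
        a = wham_solve(ws, n_bins=40, bin_range=(-1.5, 1.5))
        b = wham_solve(in_kj, n_bins=40, bin_range=(-1.5, 1.5))
        np.testing.assert_allclose(a.free_energy, b.free_energy, atol=1e-9)

    def test_nonconvergence_reports_residual(self):
        ws = make_harmonic_set(n=2000)
        with pytest.raises(ConvergenceError) as err:
            wham_solve(ws, max_iter=2, tolerance=1e-15)
        assert err.value.residual > 0

    def test_interior_empty_bin_masked_with_warning(self):
        rng = np.random.default_rng(3)
        left = rng.uniform(0.0, 0.4, 2000)
        right = rng.uniform(0.6, 1.0, 2000)
        ws = WindowSampleSet(
            windows=(
                Window(0.2, 1e-9, left),
                Window(0.8, 1e-9, right),
            ),
            temperature=T,
        )
        with pytest.warns(UserWarning, match="empty bin"):
            pmf = wham_solve(ws, n_bins=10, bin_range=(0.0, 1.0))
        assert np.isnan(pmf.free_energy).any()

    def test_repeat_error_bars_bracket_truth(self):
        pot = lambda x: 3.0 * (x**2 - 1) ** 2
        repeats = [make_doublewell_set(seed=100 + r, n=20000) for r in range(3)]
        pmf = pmf_from_repeats(repeats, n_bins=60, bin_range=(-1.5, 1.5))
        ref = bin_averaged_reference(pot, (-1.5, 1.5), 60)
        d = pmf.free_energy - ref
        d -= d.mean()
        covered = np.abs(d) <= 2 * np.maximum(pmf.error, 1e-3)
        assert covered.mean() >= 0.90


class TestPMFReductions:
    @staticmethod
    def synthetic_pmf(F, lo=1.8, hi=3.3):
        F = np.asarray(F, dtype=float)
        x = np.linspace(lo, hi, len(F))
        return PMFProfile(bin_centers=x, free_energy=F - F.min(), temperature=T)

    def test_unbinding_from_constructed_plateau(self):
        x = np.linspace(1.8, 3.3, 100)
        F = np.where(x < 3.0, 5.0 * (1 - np.exp(-8 * (x - 1.9) ** 2)), 5.0)
        F[np.argmin(np.abs(x - 1.9))] = 0.0
        pmf = PMFProfile(bin_centers=x, free_energy=F - F.min(), temperature=T)
        assert unbinding_free_energy(pmf, (3.0, 3.3)) == pytest.approx(5.0, abs=0.05)

    def test_flat_pmf_unbinds_for_free(self):
        pmf = self.synthetic_pmf(np.zeros(50))
        assert unbinding_free_energy(pmf, (3.0, 3.3)) == 0.0

    def test_plateau_overlapping_minimum_rejected(self):
        pmf = self.synthetic_pmf(np.linspace(0, 5, 50))
        with pytest.raises(ValueError, match="minimum"):
            unbinding_free_energy(pmf, (1.8, 2.5))

    def test_protonation_ordering_of_fixture_profiles(self):
        # stronger bound well when the histidine is protonated
        x = np.linspace(1.8, 3.3, 100)
        well = lambda depth: depth * (1 - np.exp(-12 * (x - 2.0) ** 2))
        hip = PMFProfile(x, well(12.0) - well(12.0).min(), temperature=T)
        hie = PMFProfile(x, well(6.0) - well(6.0).min(), temperature=T)
        dg_hip = unbinding_free_energy(hip, (3.1, 3.3))
        dg_hie = unbinding_free_energy(hie, (3.1, 3.3))
        assert dg_hip > dg_hie

    def test_barriers_from_constructed_profile(self):
        x = np.linspace(-0.4, 0.1, 101)
        F = np.full_like(x, 3.0)
        F[np.abs(x + 0.35) < 0.03] = -2.0
        F[np.abs(x - 0.05) < 0.03] = 0.0
        pmf = PMFProfile(x, F - F.min(), temperature=T)
        rep = barrier_heights(pmf, (0.0, 0.1), (-0.4, -0.3))
        assert rep.forward_barrier == pytest.approx(3.0)
        assert rep.reverse_barrier == pytest.approx(5.0)
        assert -0.3 < rep.ts_position < 0.0

    def test_symmetric_double_well_equal_barriers(self):
        x = np.linspace(-1.5, 1.5, 121)
        F = 3.0 * (x**2 - 1) ** 2
        pmf = PMFProfile(x, F - F.min(), temperature=T)
        rep = barrier_heights(pmf, (-1.2, -0.8), (0.8, 1.2))
        assert rep.forward_barrier == pytest.approx(rep.reverse_barrier, abs=1e-9)

    def test_bound_state_raises_reverse_barrier(self):
        # apo vs bound proton-transfer fixtures: deeper product well when
        # the peptide stabilizes the protonated aspartate
        x = np.linspace(-0.4, 0.1, 101)
        barrier = 4.0 * np.exp(-((x + 0.15) ** 2) / 0.002)
        apo = barrier - 1.0 * np.exp(-((x + 0.35) ** 2) / 0.002)
        bound = barrier - 4.0 * np.exp(-((x + 0.35) ** 2) / 0.002)
        rep_apo = barrier_heights(
            PMFProfile(x, apo - apo.min(), temperature=T), (0.0, 0.1), (-0.4, -0.3)
        )
        rep_bound = barrier_heights(
            PMFProfile(x, bound - bound.min(), temperature=T), (0.0, 0.1), (-0.4, -0.3)
        )
        assert rep_bound.reverse_barrier > rep_apo.reverse_barrier

    def test_no_interior_maximum_rejected(self):
        x = np.linspace(0.0, 1.0, 50)
        pmf = PMFProfile(x, x * 4.0, temperature=T)
        with pytest.raises(ValueError, match="maximum"):
            barrier_heights(pmf, (0.0, 0.2), (0.8, 1.0))

    def test_negative_barrier_forbidden_in_report(self):
        with pytest.raises(ValueError, match="non-negative"):
            BarrierReport(
                forward_barrier=-1.0, reverse_barrier=0.0,
                state_A_range=(0, 1), state_B_range=(2, 3), ts_position=1.5,
            )


def test_pmf_tsv_round_trip(tmp_path):
    x = np.linspace(0, 1, 20)
    pmf = PMFProfile(x, (x - 0.3) ** 2 - min((x - 0.3) ** 2), temperature=T)
    path = tmp_path / "pmf.tsv"
    write_pmf_tsv(pmf, path)
    back = read_pmf_tsv(path, temperature=T)
    np.testing.assert_allclose(back.bin_centers, pmf.bin_centers, atol=1e-6)
    np.testing.assert_allclose(back.free_energy, pmf.free_energy, atol=1e-6)
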