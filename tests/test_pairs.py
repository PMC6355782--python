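"""RDF normalization, Boltzmann inversion, minima and split detection."""

import numpy as np
import pytest

from memlens.constants import KB
from memlens.core import minimum_image_distance
from memlens.pairs import (FreeEnergyProfile, PairDistribution, com_rdf,
                           detect_second_peak_split, free_energy_profile,
                           locate_minima, pair_axis_density)

from conftest import make_particle_trajectory


def make_pd(r, g, mode="plateau_normalized", bin_width=None):
    r = np.asarray(r, dtype=float)
    return PairDistribution(r_grid=r, g=np.asarray(g, dtype=float),
                            mode=mode, pair_count=1000, n_frames=10,
                            bin_width=bin_width or (float(r[1] - r[0]) if len(r) > 1
                                    else 0.02),
                            counts=np.asarray(g, dtype=float))


def make_fep(r, dG, temperature=298.0):
    dG = np.asarray(dG, dtype=float)
    return FreeEnergyProfile(r_grid=np.asarray(r, dtype=float), dG=dG,
                             defined=np.isfinite(dG),
                             temperature=temperature, reference="test")


class TestComRdf:
    def test_fixed_pair_single_bin(self):
        coords = np.array([[[2.0, 2.0, 2.0], [3.0, 2.0, 2.0]]] * 5)
        traj = make_particle_trajectory(coords, [8.0, 8.0, 8.0])
        pd = com_rdf(traj, bin_width=0.05, r_max=3.0, mode="raw_histogram",
                     window_fraction=1.0)
        nz = np.flatnonzero(pd.counts)
        assert len(nz) == 1
        assert pd.r_grid[nz[0]] == pytest.approx(1.0, abs=0.05)
        assert pd.counts[nz[0]] == 5

    def test_counts_match_brute_force_histogram(self, rng):
        """Accumulated bin counts equal the all-pairs per-frame oracle."""
        box = np.array([7.0, 7.0, 7.0])
        coords = rng.uniform(0, 7, (50, 9, 3))
        traj = make_particle_trajectory(coords, box)
        bw, rmax = 0.1, 3.0
        pd = com_rdf(traj, bin_width=bw, r_max=rmax, mode="raw_histogram",
                     window_fraction=1.0)
        edges = np.arange(0, rmax + bw / 2, bw)
        expected = np.zeros(len(edges) - 1)
        for f in range(50):
            for i in range(9):
                for j in range(i + 1, 9):
                    r = minimum_image_distance(coords[f, i], coords[f, j],
                                               box)
                    if r < edges[-1]:
                        expected[min(int(r // bw), len(expected) - 1)] += 1
        np.testing.assert_array_equal(pd.counts, expected)

    def test_plateau_mode_mean_is_one(self, rng):
        coords = rng.uniform(0, 7, (40, 12, 3))
        traj = make_particle_trajectory(coords, [7.0, 7.0, 7.0])
        pd = com_rdf(traj, bin_width=0.05, r_max=3.4, mode="plateau_normalized",
                     plateau_window=(2.5, 3.2), window_fraction=1.0)
        sel = (pd.r_grid >= 2.5) & (pd.r_grid <= 3.2)
        assert pd.g[sel].mean() == pytest.approx(1.0, abs=1e-6)

    def test_r_max_beyond_half_box_rejected(self, rng):
        traj = make_particle_trajectory(rng.uniform(0, 7, (2, 4, 3)),
                                        [7.0, 7.0, 7.0])
        with pytest.raises(ValueError, match="half the smallest box"):
            com_rdf(traj, r_max=3.6, window_fraction=1.0)


class TestFreeEnergyProfile:
    def test_uniform_g_gives_zero(self):
        fep = free_energy_profile(make_pd([0.5, 1.0, 1.5], [1.0, 1.0, 1.0]),
                                  298.0)
        np.testing.assert_allclose(fep.dG, 0.0, atol=1e-14)

    def test_g_of_e_gives_minus_kbt(self):
        fep = free_energy_profile(make_pd([1.0], [np.e]), 298.0)
        assert fep.dG[0] == pytest.approx(-KB * 298.0)  # about -2.478

    def test_zero_g_masked_not_infinite(self):
        fep = free_energy_profile(make_pd([0.5, 1.0], [0.0, 2.0]), 298.0)
        assert not fep.defined[0]
        assert np.isnan(fep.dG[0])
        assert np.isfinite(fep.dG[1])

    def test_raw_mode_rejected(self):
        with pytest.raises(ValueError, match="additive constant"):
            free_energy_profile(make_pd([1.0], [3.0], mode="raw_histogram"),
                                298.0)

    def test_boltzmann_round_trip_recovers_potential(self):
        """g = exp(-u / kB T) inverts back to u exactly."""
        r = np.linspace(0.9, 2.0, 100)
        u = 4 * 2.0 * ((0.9 / r) ** 12 - (0.9 / r) ** 6)
        temp = 313.0
        g = np.exp(-u / (KB * temp))
        fep = free_energy_profile(make_pd(r, g), temp)
        np.testing.assert_allclose(fep.dG, u, rtol=1e-12, atol=1e-12)


class TestLocateMinima:
    def test_parabola_vertex(self):
        r = np.arange(0.80, 2.0, 0.02)
        fep = make_fep(r, (r - 1.0) ** 2 - 2.0)
        m = locate_minima(fep)
        assert m.r_min1 == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_double_well_zero_ddg(self):
        r = np.arange(0.80, 2.0, 0.01)
        dG = -6.0 * np.exp(-((r - 1.0) / 0.08) ** 2) \
             - 6.0 * np.exp(-((r - 1.5) / 0.08) ** 2)
        m = locate_minima(make_fep(r, dG))
        assert m.ddG == pytest.approx(0.0, abs=1e-6)
        assert m.r_min1 == pytest.approx(1.0, abs=0.01)
        assert m.r_min2 == pytest.approx(1.5, abs=0.01)

    def test_asymmetric_depths_give_ddg(self):
        r = np.arange(0.80, 2.0, 0.01)
        dG = -6.76 * np.exp(-((r - 1.0) / 0.08) ** 2) \
             - 5.0 * np.exp(-((r - 1.5) / 0.08) ** 2)
        m = locate_minima(make_fep(r, dG))
        assert m.ddG == pytest.approx(-1.76, abs=0.01)

    def test_additive_constant_invariance(self):
        r = np.arange(0.80, 2.0, 0.01)
        dG = -3.0 * np.exp(-((r - 1.05) / 0.1) ** 2) \
             - 1.0 * np.exp(-((r - 1.55) / 0.1) ** 2)
        m0 = locate_minima(make_fep(r, dG))
        m1 = locate_minima(make_fep(r, dG + 7.3))
        assert m1.r_min1 == pytest.approx(m0.r_min1, abs=1e-12)
        assert m1.ddG == pytest.approx(m0.ddG, abs=1e-9)

    def test_undefined_window_raises(self):
        r = np.arange(0.80, 2.0, 0.01)
        dG = np.where(r > 1.3, -1.0, np.nan)
        with pytest.raises(ValueError, match="no defined"):
            locate_minima(make_fep(r, dG))

    def test_overlapping_windows_rejected(self):
        fep = make_fep([1.0, 1.5], [0.0, 0.0])
        with pytest.raises(ValueError, match="disjoint"):
            locate_minima(fep, window1=(0.9, 1.4), window2=(1.3, 1.8))


class TestSecondPeakSplit:
    R = np.arange(1.0, 2.5, 0.01)

    def test_single_bump_not_split(self):
        g = 1.0 + 0.5 * np.exp(-((self.R - 1.7) / 0.15) ** 2)
        res = detect_second_peak_split(make_pd(self.R, g))
        assert res["split"] is False

    def test_two_gaussians_split_with_positions(self):
        g = np.exp(-((self.R - 1.55) / 0.08) ** 2) \
            + np.exp(-((self.R - 1.85) / 0.08) ** 2)
        res = detect_second_peak_split(make_pd(self.R, g))
        assert res["split"] is True
        pos = sorted(res["subpeak_positions"])
        assert pos[0] == pytest.approx(1.55, abs=0.02)
        assert pos[-1] == pytest.approx(1.85, abs=0.02)

    def test_merge_at_twice_sigma_separation(self):
        """Equal Gaussians merge into one maximum exactly when their
        separation drops to 2 sigma; the detector flips there."""
        sigma = 0.1
        center, bw = 1.75, 0.002
        r = np.arange(1.3, 2.2, bw)
        flips = []
        for d in np.arange(0.16, 0.24, bw):
            g = (np.exp(-((r - center + d / 2) ** 2) / (2 * sigma ** 2))
                 + np.exp(-((r - center - d / 2) ** 2) / (2 * sigma ** 2)))
            res = detect_second_peak_split(make_pd(r, g),
                                           prominence_frac=1e-12)
            flips.append((d, res["split"]))
        assert flips[0][1] is False and flips[-1][1] is True
        d_flip = next(d for d, s in flips if s)
        assert d_flip == pytest.approx(2 * sigma, abs=2 * bw)

    def test_window_outside_grid_raises(self):
        pd = make_pd([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="window"):
            detect_second_peak_split(pd, window=(1.3, 2.2))


class TestPairAxisDensity:
    def test_isolated_pair_peaks_at_half_separation(self):
        coords = np.array([[[3.0, 4.0, 4.0], [4.5, 4.0, 4.0]]] * 3)
        traj = make_particle_trajectory(coords, [8.0, 8.0, 8.0])
        res = pair_axis_density(traj, separation=1.5, tolerance=0.05,
                                bin_width=0.1, window_fraction=1.0)
        rho = res.density["fullerene"]
        nz = res.axial_grid[rho > 0]
        assert len(nz) == 2
        assert all(abs(abs(v) - 0.75) <= 0.051 for v in nz)  # +-s/2
        mid = np.argmin(np.abs(res.axial_grid))
        assert rho[mid] == 0.0

    def test_bead_at_midpoint_registers_between_pair(self):
        """A lipid bead inserted midway between a 1.5 nm pair shows up at
        axial coordinate zero."""
        from memlens.core import BeadTopology, Trajectory
        names = np.array(["CF", "CF", "T1"], dtype=object)
        topo = BeadTopology(
            names=names, molecule_id=np.array([0, 1, 2]),
            group=np.array(["fullerene", "fullerene", "lipid_tail"],
                           dtype=object),
            species=np.array(["NP", "NP", "DPPC"], dtype=object),
            mass=np.array([720.0, 720.0, 72.0]))
        coords = np.array([[[3.0, 4.0, 4.0], [4.5, 4.0, 4.0],
                            [3.75, 4.0, 4.0]]])
        traj = Trajectory(topo, coords, np.array([[8.0, 8.0, 8.0]]),
                          np.array([0.0]))
        res = pair_axis_density(traj, separation=1.5, bin_width=0.1,
                                window_fraction=1.0)
        central = np.abs(res.axial_grid) < 0.1
        assert res.density["lipid"][central].sum() > 0

    def test_no_qualifying_pairs_raises(self):
        coords = np.array([[[1.0, 1, 1], [6.0, 6, 6]]])
        traj = make_particle_trajectory(coords, [14.0, 14.0, 14.0])
        with pytest.raises(ValueError, match="no fullerene pairs"):
            pair_axis_density(traj, separation=1.0, window_fraction=1.0)

    def test_accumulation_matches_per_pair_recomputation(self, rng):
        """Histogram equals explicit per-pair brute force on random frames."""
        box = np.array([9.0, 9.0, 9.0])
        coords = rng.uniform(0, 9, (20, 14, 3))
        traj = make_particle_trajectory(coords, box)
        sep, tol, rad, bw, ext = 1.5, 0.3, 0.5, 0.1, 1.5
        res = pair_axis_density(traj, sep, tol, rad, bw, ext,
                                window_fraction=1.0)
        edges = np.linspace(-ext, ext, int(2 * ext / bw) + 1)
        expected = np.zeros(len(edges) - 1)
        n_pairs = 0
        for f in range(20):
            for i in range(14):
                for j in range(i + 1, 14):
                    d = coords[f, j] - coords[f, i]
                    d -= box * np.round(d / box)
                    r = np.linalg.norm(d)
                    if abs(r - sep) > tol:
                        continue
                    n_pairs += 1
                    mid = coords[f, i] + d / 2
                    e = d / r
                    for k in range(14):
                        rel = coords[f, k] - mid
                        rel -= box * np.round(rel / box)
                        ax = rel @ e
                        if np.linalg.norm(rel - ax * e) < rad \
                                and -ext <= ax < ext:
                            expected[min(int((ax + ext) // bw),
                                         len(expected) - 1)] += 1
        assert n_pairs == res.n_pairs
        np.testing.assert_allclose(res.density["fullerene"],
                                   expected / (n_pairs * bw), atol=1e-9)
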