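"""Generator ground truths: determinism, detailed balance, closed forms."""

import numpy as np
import pytest

from memlens.constants import KB
from memlens.core import read_trajectory
from memlens.membrane import density_profile
from memlens.synthetic import (LayeringField, PairPotential, SamplerConfig,
                               SyntheticSpec, generate_slab_membrane,
                               metropolis_transition_matrix,
                               sample_particles_mc, simulate_brownian,
                               write_system)


def particle_spec(**kw):
    defaults = dict(n_lipids=0, n_particles=8, box=(6.0, 6.0, 6.0),
                    target_apl=0.64, head_separation=4.0, seed=0)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


class TestSpecValidation:
    def test_apl_box_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lattice cannot host"):
            SyntheticSpec(n_lipids=512, box=(10.0, 10.0, 10.0),
                          target_apl=0.64)

    def test_odd_lipid_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SyntheticSpec(n_lipids=11, box=(2, 2, 10), target_apl=0.64)

    def test_head_separation_must_fit_box(self):
        with pytest.raises(ValueError, match="head_separation"):
            SyntheticSpec(n_lipids=0, box=(5, 5, 3), head_separation=4.0)


class TestSlabMembrane:
    def test_geometry_forced_by_construction(self):
        spec = SyntheticSpec(n_lipids=512, box=(12.8, 12.8, 10.0),
                             target_apl=0.64, head_separation=4.0, seed=3)
        traj = generate_slab_membrane(spec)
        assert traj.n_beads == 512 * 4
        assert traj.topology.n_lipids == 512
        # head beads sit exactly on the +-2.0 nm planes
        heads = traj.topology.select(group="lipid_head")
        z = traj.coords[0, heads, 2]
        assert set(np.round(z, 6)) == {2.0, -2.0}

    def test_head_density_peaks_at_half_separation(self):
        spec = SyntheticSpec(n_lipids=128, box=(6.4, 6.4, 10.0),
                             target_apl=0.64, head_separation=4.0, seed=0)
        prof = density_profile(generate_slab_membrane(spec), ["lipid_head"],
                               bin_width=0.1)
        rho = prof.density["lipid_head"]
        peaks = prof.z_grid[rho > 0.5 * rho.max()]
        assert np.isclose(peaks.min(), -2.0, atol=0.1)
        assert np.isclose(peaks.max(), 2.0, atol=0.1)

    def test_double_bond_labeling(self):
        spec = SyntheticSpec(n_lipids=32, box=(3.2, 3.2, 10.0),
                             target_apl=0.64, with_double_bond=True,
                             lipid_species="DOPC", seed=0)
        topo = generate_slab_membrane(spec).topology
        assert len(topo.select(group="double_bond")) == 32

    def test_fixed_seed_byte_identical_output(self, tmp_path):
        spec = SyntheticSpec(n_lipids=32, box=(3.2, 3.2, 10.0),
                             target_apl=0.64, n_frames=2, area_sd=0.5,
                             n_waters=50, seed=42)
        paths = []
        for tag in ("a", "b"):
            gro = tmp_path / f"{tag}.gro"
            write_system(generate_slab_membrane(spec), gro,
                         tmp_path / f"{tag}.yaml")
            paths.append(gro.read_bytes())
        assert paths[0] == paths[1]

    def test_generated_file_reads_back_with_spec_counts(self, tmp_path):
        spec = SyntheticSpec(n_lipids=32, box=(3.2, 3.2, 10.0),
                             target_apl=0.64, n_waters=20, seed=1)
        gro, ymap = tmp_path / "m.gro", tmp_path / "m.yaml"
        write_system(generate_slab_membrane(spec), gro, ymap)
        back = read_trajectory(gro, ymap)
        assert back.topology.n_lipids == spec.n_lipids
        assert len(back.topology.select(group="water")) == spec.n_waters


class TestMetropolis:
    def test_detailed_balance_on_three_state_toy(self):
        """Transition matrix satisfies pi_i P_ij = pi_j P_ji with Boltzmann
        weights on an arbitrary 3-level system."""
        e = np.array([0.0, 1.7, 4.1])
        temp = 298.0
        p = metropolis_transition_matrix(e, temp)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-14)
        pi = np.exp(-e / (KB * temp))
        pi /= pi.sum()
        flux = pi[:, None] * p
        np.testing.assert_allclose(flux, flux.T, atol=1e-14)
        # stationarity
        np.testing.assert_allclose(pi @ p, pi, atol=1e-14)

    def test_fixed_seed_reproducible(self):
        spec = particle_spec(sampler=SamplerConfig(n_steps=2000,
                                                   frame_stride=10))
        a = sample_particles_mc(spec)
        b = sample_particles_mc(spec)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_harmonic_field_gives_boltzmann_z_distribution(self):
        """w(z) = k z^2 / 2 at 298 K yields Var(z) = kB T / k = 1.0 nm^2."""
        k = 2.478
        spec = particle_spec(
            n_particles=32, box=(8.0, 8.0, 8.0),
            pair_potential=PairPotential(epsilon=0.0),
            layering_field=LayeringField(kind="harmonic", k=k),
            temperature=298.0,
            sampler=SamplerConfig(n_steps=20000, frame_stride=5,
                                  step_size=0.5),
            seed=9)
        traj = sample_particles_mc(spec)
        z = traj.coords[:, :, 2].ravel()
        expected = KB * 298.0 / k
        assert np.var(z) == pytest.approx(expected, rel=0.1)
        assert np.mean(z) == pytest.approx(0.0, abs=0.05)

    def test_cosine3_field_has_three_wells(self):
        f = LayeringField(kind="cosine3", amplitude=2.0, width=4.2)
        z = np.linspace(-2.0, 2.0, 2001)
        w = f(z)
        minima = z[np.r_[False, (w[1:-1] < w[:-2]) & (w[1:-1] < w[2:]),
                         False]]
        np.testing.assert_allclose(minima, [-4.2 / 3, 0.0, 4.2 / 3],
                                   atol=0.01)

    def test_acceptance_rate_warning(self):
        spec = particle_spec(
            pair_potential=PairPotential(epsilon=0.0),
            sampler=SamplerConfig(n_steps=500, frame_stride=5))
        with pytest.warns(UserWarning, match="acceptance rate"):
            sample_particles_mc(spec)  # ideal gas accepts ~every move


class TestPairPotential:
    def test_truncated_shifted_form(self):
        pot = PairPotential(epsilon=2.0, sigma=0.9, cutoff=1.2)
        assert pot(1.2) == 0.0
        assert pot(2.0) == 0.0
        # continuous at the cutoff
        assert pot(1.2 - 1e-9) == pytest.approx(0.0, abs=1e-6)
        # analytic minimum at 2^(1/6) sigma, depth epsilon before the shift
        rmin = 2 ** (1 / 6) * 0.9
        shift = 4 * 2.0 * ((0.9 / 1.2) ** 12 - (0.9 / 1.2) ** 6)
        assert pot(rmin) == pytest.approx(-2.0 - shift)


class TestBrownian:
    def brownian_spec(self, **kw):
        defaults = dict(n_lipids=0, n_particles=16, box=(10.0, 10.0, 10.0),
                        diffusion_constant=0.01, seed=0,
                        sampler=SamplerConfig(mode="brownian", n_frames=100,
                                              dt=0.5))
        defaults.update(kw)
        return SyntheticSpec(**defaults)

    def test_zero_diffusion_is_static(self):
        traj = simulate_brownian(self.brownian_spec(diffusion_constant=0.0))
        assert np.all(traj.coords == traj.coords[0])

    def test_lateral_mask_freezes_z(self):
        spec = self.brownian_spec(
            sampler=SamplerConfig(mode="brownian", n_frames=50, dt=0.5,
                                  axes=(0, 1)))
        traj = simulate_brownian(spec)
        assert np.all(traj.coords[:, :, 2] == traj.coords[0, :, 2])
        assert not np.all(traj.coords[:, :, 0] == traj.coords[0, :, 0])

    def test_unwrapped_bookkeeping_consistent(self):
        wrapped, unwrapped = simulate_brownian(
            self.brownian_spec(diffusion_constant=0.05),
            return_unwrapped=True)
        box = np.array([10.0, 10.0, 10.0])
        rewrap = (unwrapped.coords + box / 2) % box - box / 2
        np.testing.assert_allclose(rewrap, wrapped.coords, atol=1e-12)

    def test_oversized_step_rejected(self):
        spec = self.brownian_spec(diffusion_constant=50.0)
        with pytest.raises(ValueError, match="box/4"):
            simulate_brownian(spec)

    def test_fixed_seed_reproducible(self):
        a = simulate_brownian(self.brownian_spec())
        b = simulate_brownian(self.brownian_spec())
        np.testing.assert_array_equal(a.coords, b.coords)
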