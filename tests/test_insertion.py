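"""Residue heights, reference planes, and the DCLE FWHM estimator."""

import numpy as np
import pytest

from exthmmm.core import Frame, MolecularSystem, TrajectoryEnsemble
from exthmmm.fixtures import (
    FixtureSpec,
    MembraneBedSpec,
    ProbeSchedule,
    make_membrane_bed,
    make_trajectory,
)
from exthmmm.insertion import (
    dcle_density_fwhm,
    fwhm_from_samples,
    mean_plane,
    residue_height,
    spike_profiles,
)

from conftest import ca_chain


def single_frame_traj(system, time=0.0):
    return TrajectoryEnsemble(system, system.coordinates[None],
                              np.array([time]), system.box)


class TestResidueHeight:
    def test_flat_residue(self):
        system = ca_chain(3)
        coords = system.coordinates.copy()
        coords[:, 2] = 5.0
        fr = Frame(coords, None, 0.0)
        assert residue_height(fr, system, 2) == pytest.approx(5.0)

    def test_symmetric_atoms_average_to_zero(self):
        system = MolecularSystem(
            atom_name=np.array(["CB", "CG"], dtype=object),
            residue_number=np.array([7, 7]),
            residue_name=np.array(["LEU", "LEU"], dtype=object),
            segment_id=np.array(["PROT", "PROT"], dtype=object),
            element=np.array(["C", "C"], dtype=object),
            coordinates=np.array([[0, 0, 3.0], [0, 0, -3.0]]),
        )
        fr = Frame(system.coordinates, None, 0.0)
        assert residue_height(fr, system, 7) == pytest.approx(0.0)

    def test_antisymmetric_under_z_reflection(self, toy_protein):
        fr = Frame(toy_protein.coordinates, None, 0.0)
        h = residue_height(fr, toy_protein, 2063)
        flipped = Frame(toy_protein.coordinates * np.array([1, 1, -1]),
                        None, 0.0)
        assert residue_height(flipped, toy_protein, 2063) == \
            pytest.approx(-h)

    def test_missing_residue_raises(self, toy_protein):
        fr = Frame(toy_protein.coordinates, None, 0.0)
        with pytest.raises(ValueError, match="9999"):
            residue_height(fr, toy_protein, 9999)

    def test_planted_depth_recovered(self):
        depth = tuple(np.linspace(25.0, -2.0, 20))
        probe = ProbeSchedule(2063, mode="depth", z=depth)
        spec = FixtureSpec(seed=4, n_frames=20, include_protein=False,
                           include_membrane=True, probes=(probe,))
        traj, truth = make_trajectory(spec)
        got = [residue_height(fr, traj.topology, 2063) for fr in traj]
        assert np.allclose(got, depth, atol=1e-9)
        assert np.allclose(truth["probe2063_z"], depth)


class TestMeanPlane:
    def test_planted_plane(self):
        bed = make_membrane_bed(MembraneBedSpec(p_plane_z=19.0), seed=1)
        traj = single_frame_traj(bed)
        assert mean_plane(traj, "P", "upper") == pytest.approx(19.0)
        assert mean_plane(traj, "N", "upper") == pytest.approx(20.5)

    def test_leaflets_signed(self):
        bed = make_membrane_bed(seed=2)
        traj = single_frame_traj(bed)
        assert mean_plane(traj, "P", "upper") > 0
        assert mean_plane(traj, "P", "lower") == \
            pytest.approx(-mean_plane(traj, "P", "upper"))

    def test_noisy_plane_within_standard_error(self):
        spec = FixtureSpec(seed=6, n_frames=30, include_protein=False,
                           include_membrane=True, noise_sigma=0.2)
        traj, _ = make_trajectory(spec)
        n_samples = 30 * spec.membrane.n_lipids_per_leaflet
        se = 0.2 / np.sqrt(n_samples)
        assert mean_plane(traj, "P", "upper") == \
            pytest.approx(19.0, abs=5 * se)


class TestFWHM:
    def test_uniform_slab(self, rng):
        z = rng.uniform(-10.5, 10.5, size=20_000)
        assert fwhm_from_samples(z) == pytest.approx(21.0, abs=0.5)

    def test_gaussian_closed_form(self, rng):
        sigma = 5.0
        z = rng.normal(scale=sigma, size=100_000)
        assert fwhm_from_samples(z) == \
            pytest.approx(2.355 * sigma, abs=0.5)

    def test_sample_count_stability(self, rng):
        z1 = rng.normal(scale=4.0, size=30_000)
        z2 = np.concatenate([z1, rng.normal(scale=4.0, size=30_000)])
        assert abs(fwhm_from_samples(z1) - fwhm_from_samples(z2)) <= 0.5

    def test_from_trajectory_dcle(self):
        spec = FixtureSpec(seed=3, n_frames=5, include_protein=False,
                           include_membrane=True)
        traj, _ = make_trajectory(spec)
        assert dcle_density_fwhm(traj) == pytest.approx(21.0, abs=0.5)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            fwhm_from_samples(rng.normal(size=50))


class TestSpikeProfiles:
    def make_traj(self):
        # "W2063" planted below the P plane (19 A), "K2060" above it
        deep = ProbeSchedule(2063, mode="depth", z=(16.0,) * 10)
        shallow = ProbeSchedule(2060, mode="depth", z=(23.0,) * 10)
        spec = FixtureSpec(seed=5, n_frames=10, include_protein=False,
                           include_membrane=True, probes=(deep, shallow))
        traj, _ = make_trajectory(spec)
        return traj

    def test_planted_ordering(self):
        profile = spike_profiles(self.make_traj(),
                                 {"C2 spike 1": [2063, 2060]})
        med = profile.summary.set_index("residue_number")["median"]
        assert med[2063] < profile.p_plane < med[2060]

    def test_reference_planes_and_fwhm(self):
        profile = spike_profiles(self.make_traj(), {"s": [2063]})
        assert profile.p_plane == pytest.approx(19.0)
        assert profile.n_plane == pytest.approx(20.5)
        assert profile.dcle_fwhm == pytest.approx(21.0, abs=0.5)

    def test_summary_consistent_with_samples(self):
        profile = spike_profiles(self.make_traj(),
                                 {"s": [2063, 2060]})
        for _, row in profile.summary.iterrows():
            h = profile.samples.query(
                "residue_number == @row.residue_number")["height"]
            assert row["median"] == pytest.approx(np.median(h))
            assert row["n"] == len(h)

    def test_empty_window_is_error(self):
        with pytest.raises(ValueError, match="no frames"):
            spike_profiles(self.make_traj(), {"s": [2063]},
                           bound_window=(100.0, 500.0))

    def test_no_spikes_is_error(self):
        with pytest.raises(ValueError, match="spike"):
            spike_profiles(self.make_traj(), {})

    def test_bound_window_pooling_inclusive(self):
        probe = ProbeSchedule(2063, mode="depth",
                              z=tuple(np.linspace(10, 20, 6)))
        spec = FixtureSpec(seed=9, n_frames=6, dt=0.25, t0=99.25,
                           include_protein=False, include_membrane=True,
                           probes=(probe,))
        traj, _ = make_trajectory(spec)
        # times: 99.25 99.50 99.75 100.00 100.25 100.50 (exact binary)
        profile = spike_profiles(traj, {"s": [2063]},
                                 bound_window=(100.0, 500.0))
        assert profile.summary["n"].iloc[0] == 3
        assert profile.samples["time"].min() == pytest.approx(100.0)
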