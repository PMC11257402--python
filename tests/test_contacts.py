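"""Contact kernels, frequency tables, PS/PC preference, A1-C2 metrics."""

import itertools
import math

import numpy as np
import pytest

from exthmmm.contacts import (
    contact_frequency_table,
    interdomain_contacts,
    interdomain_distance,
    map_scores_to_structure,
    min_distance,
    preference_scores,
    residue_lipid_contact,
)
from exthmmm.core import Frame, MolecularSystem, SelectionSpec
from exthmmm.fixtures import (
    FixtureSpec,
    ProbeSchedule,
    make_trajectory,
)
from conftest import ca_chain


def two_atom_frame(d):
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    return Frame(coords, np.array([100.0, 100.0, 100.0]), 0.0)


def brute_min_distance(a, b, box, periodic_xy=True):
    """Independent oracle: pure-python double loop with minimum image."""
    best = math.inf
    for p in a:
        for q in b:
            dx, dy, dz = p[0] - q[0], p[1] - q[1], p[2] - q[2]
            if periodic_xy:
                dx -= box[0] * round(dx / box[0])
                dy -= box[1] * round(dy / box[1])
            best = min(best, math.sqrt(dx * dx + dy * dy + dz * dz))
    return best


class TestContactKernel:
    def test_contact_at_4p9(self):
        assert residue_lipid_contact(two_atom_frame(4.9), [0], [1])

    def test_no_contact_at_5p1(self):
        assert not residue_lipid_contact(two_atom_frame(5.1), [0], [1])

    def test_cutoff_inclusive(self):
        assert residue_lipid_contact(two_atom_frame(5.0), [0], [1])

    def test_symmetric_in_arguments(self, rng):
        coords = rng.uniform(0, 30, size=(40, 3))
        fr = Frame(coords, np.array([30.0, 30.0, 60.0]), 0.0)
        a, b = np.arange(20), np.arange(20, 40)
        assert residue_lipid_contact(fr, a, b) == \
            residue_lipid_contact(fr, b, a)

    def test_periodic_wrap_in_xy(self):
        box = np.array([50.0, 50.0, 50.0])
        coords = np.array([[1.0, 25.0, 0.0], [49.0, 25.0, 0.0]])
        fr = Frame(coords, box, 0.0)
        assert residue_lipid_contact(fr, [0], [1])  # 2 A through the wall
        assert not residue_lipid_contact(fr, [0], [1], periodic="")

    def test_missing_box_rejected_in_periodic_mode(self):
        fr = Frame(np.zeros((2, 3)), None, 0.0)
        with pytest.raises(ValueError, match="box"):
            residue_lipid_contact(fr, [0], [1])

    @pytest.mark.parametrize("cutoff", [5.0, 10.0])
    def test_matches_bruteforce_oracle(self, cutoff, rng):
        box = np.array([40.0, 40.0, 80.0])
        for _ in range(20):
            a = rng.uniform(0, 40, size=(15, 3))
            b = rng.uniform(0, 40, size=(25, 3))
            fr = Frame(np.vstack([a, b]), box, 0.0)
            mine = residue_lipid_contact(fr, np.arange(15),
                                         np.arange(15, 40), cutoff)
            oracle = brute_min_distance(a, b, box) <= cutoff
            assert mine == oracle
            assert min_distance(a, b, box) == \
                pytest.approx(brute_min_distance(a, b, box), abs=1e-9)


class TestFrequencyTable:
    def make_traj(self, frames_in_contact, n_frames=50):
        probe = ProbeSchedule(2301, mode="contacts", contact_frames=(
            ("PS", tuple(range(frames_in_contact))),
        ))
        spec = FixtureSpec(seed=21, n_frames=n_frames,
                           include_protein=False, include_membrane=True,
                           probes=(probe,))
        return make_trajectory(spec)

    def probe_indices(self, traj):
        return np.flatnonzero(
            traj.topology.segment_id.astype(str) == "PROB")

    def test_always_in_contact(self):
        traj, _ = self.make_traj(50)
        tab = contact_frequency_table(traj, self.probe_indices(traj))
        assert tab.loc[0, "freq_PS"] == 1.0
        assert tab.loc[0, "freq_PC"] == 0.0

    def test_half_the_frames(self):
        traj, _ = self.make_traj(25)
        tab = contact_frequency_table(traj, self.probe_indices(traj))
        assert tab.loc[0, "freq_PS"] == 0.5

    def test_matches_planted_ground_truth(self):
        traj, truth = self.make_traj(37)
        tab = contact_frequency_table(traj, self.probe_indices(traj))
        expected = (truth["probe2301_class"] == "PS").mean()
        assert tab.loc[0, "freq_PS"] == pytest.approx(expected)

    def test_nonselective_residue_follows_stoichiometry(self):
        probe = ProbeSchedule(2301, mode="random_lipid")
        spec = FixtureSpec(seed=8, n_frames=200, include_protein=False,
                           include_membrane=True, probes=(probe,))
        traj, truth = make_trajectory(spec)
        tab = contact_frequency_table(traj, self.probe_indices(traj))
        # 4:1 bed: PC contacts about four times as frequent as PS
        ratio = tab.loc[0, "freq_PC"] / tab.loc[0, "freq_PS"]
        assert 2.5 < ratio < 6.5
        # and the measured split matches the planted one exactly
        assert tab.loc[0, "freq_PC"] == \
            pytest.approx((truth["probe2301_class"] == "PC").mean())

    def test_unmapped_lipid_name_rejected(self):
        traj, _ = self.make_traj(5, n_frames=5)
        with pytest.raises(ValueError, match="unmapped"):
            contact_frequency_table(traj, self.probe_indices(traj),
                                    lipid_classes={"PC": ("POPC",),
                                                   "PS": ("POPS",)})

    def test_frame_order_invariance(self):
        traj, _ = self.make_traj(20)
        idx = self.probe_indices(traj)
        tab = contact_frequency_table(traj, idx)
        reversed_traj = type(traj)(
            traj.topology, traj.coordinates[::-1].copy(), traj.time,
            traj.box,
        )
        tab_rev = contact_frequency_table(reversed_traj, idx)
        assert tab.loc[0, "freq_PS"] == tab_rev.loc[0, "freq_PS"]


class TestPreference:
    def test_planted_selectivity_recovered(self):
        n = 200
        sel = {2301: 0.2, 2302: 0.5, 2303: 0.8}
        base = 0.1
        probes = []
        for res, s in sel.items():
            n_ps = int(round((s + base) * n))
            n_pc = int(round(base * n))
            probes.append(ProbeSchedule(res, mode="contacts", contact_frames=(
                ("PS", tuple(range(n_ps))),
                ("PC", tuple(range(n_ps, n_ps + n_pc))),
            )))
        spec = FixtureSpec(seed=31, n_frames=n, include_protein=False,
                           include_membrane=True, probes=tuple(probes))
        traj, _ = make_trajectory(spec)
        idx = np.flatnonzero(traj.topology.segment_id.astype(str) == "PROB")
        prefs = preference_scores(contact_frequency_table(traj, idx))
        got = dict(zip(prefs["residue_number"], prefs["preference"]))
        for res, s in sel.items():
            assert got[res] == pytest.approx(s, abs=0.05)
        # ranked descending: strongest PS binder first
        assert list(prefs["residue_number"]) == [2303, 2302, 2301]

    def test_diagonal_is_neutral(self):
        import pandas as pd
        tab = pd.DataFrame([{"residue_number": 1, "domain": "",
                             "freq_PC": 0.3, "freq_PS": 0.3,
                             "n_frames": 10}])
        out = preference_scores(tab)
        assert out.loc[0, "preference"] == 0.0
        assert out.loc[0, "classification"] == "neutral"

    def test_pure_ps_binder_tops_ranking(self):
        import pandas as pd
        tab = pd.DataFrame([
            {"residue_number": 1, "domain": "", "freq_PC": 0.0,
             "freq_PS": 1.0, "n_frames": 10},
            {"residue_number": 2, "domain": "", "freq_PC": 0.5,
             "freq_PS": 0.5, "n_frames": 10},
        ])
        out = preference_scores(tab)
        assert out.loc[0, "residue_number"] == 1
        assert out.loc[0, "preference"] == 1.0
        assert out.loc[0, "classification"] == "PS-preferring"


class TestInterdomain:
    def test_single_pair_at_9p9(self):
        a = ca_chain(1, start=1)
        b = ca_chain(1, start=100)
        system = MolecularSystem.concatenate([a, b])
        coords = system.coordinates.copy()
        coords[1] = [9.9, 0, 0]
        fr = Frame(coords, None, 0.0)
        n = interdomain_contacts(fr, system,
                                 SelectionSpec("A", [(1, 1)], ["CA"]),
                                 SelectionSpec("B", [(100, 100)], ["CA"]))
        assert n == 1

    def test_all_pairs_beyond_cutoff(self):
        a = ca_chain(3, start=1)
        b = ca_chain(3, start=100)
        bc = b.coordinates + np.array([0, 0, 50.0])
        system = MolecularSystem.concatenate([a, b.with_coordinates(bc)])
        fr = Frame(system.coordinates, None, 0.0)
        assert interdomain_contacts(
            fr, system, SelectionSpec("A", [(1, 3)], ["CA"]),
            SelectionSpec("B", [(100, 102)], ["CA"])) == 0

    def test_matches_double_loop(self, rng):
        a = ca_chain(12, start=1)
        b = ca_chain(15, start=100)
        system = MolecularSystem.concatenate([a, b])
        coords = rng.uniform(0, 25, size=(27, 3))
        fr = Frame(coords, None, 0.0)
        count = interdomain_contacts(
            fr, system, SelectionSpec("A", [(1, 12)], ["CA"]),
            SelectionSpec("B", [(100, 114)], ["CA"]))
        oracle = sum(
            1 for i, j in itertools.product(range(12), range(12, 27))
            if math.dist(coords[i], coords[j]) <= 10.0
        )
        assert count == oracle

    def test_centroid_distance(self):
        a = ca_chain(1, start=1)
        b = ca_chain(1, start=2)
        system = MolecularSystem.concatenate([a, b])
        coords = np.array([[0.0, 0, 0], [0.0, 0, 40.0]])
        fr = Frame(coords, None, 0.0)
        d = interdomain_distance(fr, system,
                                 SelectionSpec("A", [(1, 1)], ["CA"]),
                                 SelectionSpec("B", [(2, 2)], ["CA"]))
        assert d == pytest.approx(40.0)
        moved = Frame(coords + np.array([5, 6, 7.0]), None, 0.0)
        assert interdomain_distance(
            moved, system, SelectionSpec("A", [(1, 1)], ["CA"]),
            SelectionSpec("B", [(2, 2)], ["CA"])) == pytest.approx(40.0)

    def test_hinge_opening_recovered(self, full_domain_defs):
        phi = tuple(np.linspace(80.0, 150.0, 12))
        traj, truth = make_trajectory(FixtureSpec(seed=2, n_frames=12,
                                                  phi=phi))
        a1 = full_domain_defs.require("A1")
        c2 = full_domain_defs.require("C2")
        got = [interdomain_distance(fr, traj.topology, a1, c2)
               for fr in traj]
        assert np.allclose(got, truth["dist_A1_C2"], atol=1e-9)


class TestScoreMapping:
    def test_bfactor_scaling_and_sentinel(self, tmp_path, toy_protein):
        path = tmp_path / "scored.pdb"
        bfac = map_scores_to_structure({1879: 1.0, 1880: 0.25},
                                       toy_protein, path)
        res = toy_protein.residue_number
        assert bfac[res == 1879][0] == pytest.approx(100.0)
        assert bfac[res == 1880][0] == pytest.approx(25.0)
        assert bfac[res == 1881][0] == -1.0

    def test_roundtrip_two_decimals(self, tmp_path, toy_protein):
        path = tmp_path / "scored.pdb"
        map_scores_to_structure({2038: 0.5}, toy_protein, path)
        import MDAnalysis as mda
        u = mda.Universe(str(path))
        res = u.select_atoms("resid 2038")
        assert res.tempfactors[0] == pytest.approx(50.0, abs=0.01)

    def test_out_of_range_score_rejected(self, tmp_path, toy_protein):
        with pytest.raises(ValueError, match="range"):
            map_scores_to_structure({1879: 1.5}, toy_protein,
                                    tmp_path / "x.pdb")
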