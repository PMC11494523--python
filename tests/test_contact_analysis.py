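"""Contact detection, frame-fraction frequencies, and geometric scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barrelgate.contact_analysis import (
    ContactTable,
    annotate_scores,
    contact_frequencies,
    frame_contacts,
    geometric_score,
    heavy_atom_mask,
    protein_atoms_by_resid,
)
from barrelgate.exceptions import MappingError
from barrelgate.structure_io import read_pdb, write_annotated_pdb
from barrelgate.synthetic_data import SyntheticSpec, generate_trajectory

from conftest import brute_force_contacts, ca_structure, make_structure


class TestFrameContacts:
    def _two_atom_case(self, distance):
        s = make_structure([
            ("CA", "ALA", 1, "A", "C", (0, 0, 0)),
            ("C1", "LIG", 900, "L", "C", (distance, 0, 0)),
        ])
        return s.coords, [1], {1: np.array([0])}

    def test_within_cutoff(self):
        coords, lig, prot = self._two_atom_case(3.9)
        assert frame_contacts(coords, lig, prot, cutoff=4.0) == {1}

    def test_beyond_cutoff(self):
        coords, lig, prot = self._two_atom_case(4.1)
        assert frame_contacts(coords, lig, prot, cutoff=4.0) == set()

    def test_matches_brute_force_on_random_frames(self, rng):
        """KD-tree result equals the O(N²) all-pairs oracle."""
        for _ in range(10):
            coords = rng.uniform(0, 15, size=(50, 3))
            lipid = list(range(40, 50))
            by_resid = {r: np.arange(r * 4, r * 4 + 4) for r in range(10)}
            got = frame_contacts(coords, lipid, by_resid, cutoff=4.0)
            want = brute_force_contacts(coords, lipid, by_resid, 4.0)
            assert got == want

    def test_empty_lipid_rejected(self):
        coords, _, prot = self._two_atom_case(1.0)
        with pytest.raises(ValueError):
            frame_contacts(coords, [], prot, 4.0)


class TestContactFrequencies:
    def test_prescribed_pattern_recovered_exactly(self):
        spec = SyntheticSpec(
            n_frames=40, fluct_sigma=0.2, seed=11,
            contact_pattern={437: (1.0,), 663: (0.5,), 545: (0.25,)},
        )
        traj, truth = generate_trajectory(spec, replica=0)
        template = traj.atom_template
        protein_idx = np.arange(spec.n_residues)
        by_resid = protein_atoms_by_resid(template, protein_idx)
        lipid = [i for i, a in enumerate(template.atoms)
                 if a.resname == "LIG" and a.element != "H"]
        freqs = contact_frequencies(traj, lipid, by_resid)
        for r, f in truth.contact_fractions.items():
            assert freqs[r] == pytest.approx(f, abs=0)
        others = {r: f for r, f in freqs.items()
                  if f > 0 and r not in truth.contact_fractions}
        assert others == {}

    def test_decoy_hydrogen_is_excluded(self):
        """The generator parks a hydrogen 2.5 Å from a mid-barrel residue; it
        must not register once hydrogens are filtered, and would if kept."""
        spec = SyntheticSpec(n_frames=5, fluct_sigma=0.0, seed=1,
                             contact_pattern={437: (0.0,)})
        traj, truth = generate_trajectory(spec)
        template = traj.atom_template
        by_resid = protein_atoms_by_resid(template, np.arange(spec.n_residues))
        lig_all = [i for i, a in enumerate(template.atoms) if a.resname == "LIG"]
        heavy = heavy_atom_mask(template)
        lig_heavy = [i for i in lig_all if heavy[i]]
        with_h = contact_frequencies(traj, lig_all, by_resid)
        without_h = contact_frequencies(traj, lig_heavy, by_resid)
        touched_with_h = {r for r, f in with_h.items() if f > 0}
        assert touched_with_h  # the decoy H does create a contact if kept
        assert all(f == 0.0 for f in without_h.values())


class TestGeometricScore:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.5, 0.5, 0.5), 0.5),
        ((0.9, 0.0, 0.9), 0.0),
        ((0.2, 0.4, 0.8), 0.4),
        ((0.73,), 0.73),  # single replica: identity
    ])
    def test_reference_values(self, freqs, expected):
        assert geometric_score(freqs) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geometric_score((0.5, 1.2))
        with pytest.raises(ValueError):
            geometric_score(())

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_am_gm_inequality(self, freqs):
        g = geometric_score(freqs)
        assert 0.0 <= g <= 1.0
        assert g <= np.mean(freqs) + 1e-12
        if len(set(freqs)) == 1:
            assert g == pytest.approx(freqs[0], abs=1e-12)


class TestContactTableAndAnnotation:
    def test_zero_propagation_in_table(self):
        table = ContactTable.from_replicas([{5: 0.9}, {5: 0.0, 7: 0.4}, {5: 0.9}])
        assert table.score_of(5) == 0.0
        assert table.score_of(7) == 0.0  # missing in two replicas counts as 0

    def test_annotate_and_roundtrip(self, tmp_path):
        s = ca_structure([(0, 0, 0), (1, 0, 0), (2, 0, 0)], resid_start=436)
        table = ContactTable.from_replicas([{437: 0.4}])
        annotated = annotate_scores(s, table)
        assert [a.score for a in annotated.atoms] == [0.0, 0.4, 0.0]
        p = tmp_path / "scores.pdb"
        write_annotated_pdb(annotated, p)
        back = read_pdb(p).atom_template
        np.testing.assert_allclose(back.scores, annotated.scores, atol=5e-3)

    def test_empty_table_scores_all_zero(self):
        s = ca_structure([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        table = ContactTable.from_replicas([{}])
        annotated = annotate_scores(s, table)
        assert np.all(annotated.scores == 0.0)

    def test_unknown_residue_rejected(self):
        s = ca_structure([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        with pytest.raises(MappingError):
            annotate_scores(s, ContactTable.from_replicas([{42: 0.5}]))

    def test_frequency_permutation_invariance(self):
        """Contact frequencies do not depend on frame order."""
        spec = SyntheticSpec(n_frames=20, fluct_sigma=0.0, seed=9,
                             contact_pattern={437: (0.4,)})
        traj, _ = generate_trajectory(spec)
        template = traj.atom_template
        by_resid = protein_atoms_by_resid(template, np.arange(spec.n_residues))
        lipid = [i for i, a in enumerate(template.atoms)
                 if a.resname == "LIG" and a.element != "H"]
        base = contact_frequencies(traj, lipid, by_resid)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = type(traj)(template, traj.frames[perm])
        assert contact_frequencies(shuffled, lipid, by_resid) == base
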