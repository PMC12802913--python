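"""Tail-DNA contacts, bound-state classification, events and thermodynamics."""

import math

import numpy as np
import pytest

from taildyn.contacts import (
    BoundStateSeries,
    ContactTimeline,
    binding_thermodynamics,
    bound_fraction,
    classify_bound_state,
    default_bp_pairing,
    extract_events,
    per_bp_contact_map,
    residue_dna_contacts,
)
from taildyn.trajectory import select

from conftest import bead_trajectory


def two_bead_traj(distance, n_frames=1):
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 1, 0] = distance
    return bead_trajectory(coords, chain_ids=["A", "D"], residue_ids=[1, 1],
                           names=["CA", "P"], elements=["C", "P"])


class TestResidueDnaContacts:
    def test_strict_inequality_at_cutoff(self):
        for d, expect in ((3.9, 1), (4.0, 0), (4.1, 0)):
            traj = two_bead_traj(d)
            tl = residue_dna_contacts(
                traj, select(traj, "chain A"), select(traj, "chain D"),
                cutoff=4.0, stride=1.0, burn_in=0.0,
            )
            assert tl.counts[0, 0] == expect

    def test_orbiting_bead_matches_geometry(self):
        # tail bead circles a DNA bead at radius 3 + 2*cos(angle): inside
        # the 4 A cutoff exactly when cos(angle) < 1/2
        angles = np.linspace(0, 2 * math.pi, 24, endpoint=False)
        coords = np.zeros((24, 2, 3))
        coords[:, 0, 0] = 3.0 + 2.0 * np.cos(angles)
        traj = bead_trajectory(coords, chain_ids=["A", "D"], residue_ids=[1, 1],
                               names=["CA", "P"], elements=["C", "P"])
        tl = residue_dna_contacts(traj, select(traj, "chain A"),
                                  select(traj, "chain D"),
                                  cutoff=4.0, stride=1.0, burn_in=0.0)
        expected = np.abs(3.0 + 2.0 * np.cos(angles)) < 4.0
        assert np.array_equal(tl.in_contact[:, 0], expected)

    def test_burn_in_and_stride_frame_count(self):
        traj = two_bead_traj(3.0, n_frames=1000)  # 1 ns interval, t = 0..999
        tl = residue_dna_contacts(traj, select(traj, "chain A"),
                                  select(traj, "chain D"),
                                  stride=1.0, burn_in=200.0)
        assert tl.n_frames == 800

    def test_stride_below_frame_interval_rejected(self):
        traj = two_bead_traj(3.0, n_frames=10)
        with pytest.raises(ValueError, match="stride"):
            residue_dna_contacts(traj, select(traj, "chain A"),
                                 select(traj, "chain D"), stride=0.5, burn_in=0.0)

    def test_hydrogens_in_selection_rejected(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 3.0
        traj = bead_trajectory(coords, chain_ids=["A", "D"], residue_ids=[1, 1],
                               names=["H", "P"], elements=["H", "P"])
        with pytest.raises(ValueError, match="hydrogen"):
            residue_dna_contacts(traj, select(traj, "chain A"),
                                 select(traj, "chain D"), stride=1.0, burn_in=0.0)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 15, size=(20, 12, 3))
        traj = bead_trajectory(coords, chain_ids=["A"] * 6 + ["D"] * 6,
                               residue_ids=[1, 2, 3, 4, 5, 6] * 2,
                               names=["CA"] * 6 + ["P"] * 6,
                               elements=["C"] * 6 + ["P"] * 6)
        a = residue_dna_contacts(traj, select(traj, "chain A"), select(traj, "chain D"),
                                 cutoff=4.0, stride=1.0, burn_in=0.0)
        b = residue_dna_contacts(traj, select(traj, "chain A"), select(traj, "chain D"),
                                 cutoff=5.0, stride=1.0, burn_in=0.0)
        assert np.all(b.counts >= a.counts)


def timeline_from_contacts(n_res, contacts_per_frame):
    """ContactTimeline with the given number of contacting residues per frame."""
    n_frames = len(contacts_per_frame)
    counts = np.zeros((n_frames, n_res), dtype=int)
    for f, k in enumerate(contacts_per_frame):
        counts[f, :k] = 1
    return ContactTimeline(list(range(1, n_res + 1)), np.arange(n_frames, dtype=float), counts)


class TestBoundClassification:
    def test_bound_fraction_values(self):
        tl = timeline_from_contacts(36, [36, 0, 9])
        assert np.allclose(bound_fraction(tl), [1.0, 0.0, 0.25])

    def test_floor_rule_for_36_residues(self):
        tl = timeline_from_contacts(36, [3, 4, 0])
        states = classify_bound_state(tl, unbound_threshold=0.10)
        # floor(0.1*36) = 3: 3 contacts -> unbound, 4 -> bound
        assert states.bound.tolist() == [False, True, False]


class TestExtractEvents:
    def test_hand_counted_episode_table(self):
        s = BoundStateSeries(np.arange(7.0), np.array([1, 1, 1, 0, 0, 1, 1], bool))
        events, kin = extract_events(s, min_residence=0.0)
        assert kin.n_unbinding_events == 1
        bound = [e for e in events.episodes if e.state == "bound"]
        assert [(e.duration, e.truncated) for e in bound] == [(3.0, False), (2.0, True)]
        # censored final episode is excluded from residence statistics
        assert kin.residence_times.tolist() == [3.0]

    def test_all_bound_single_truncated_episode(self):
        s = BoundStateSeries(np.arange(5.0), np.ones(5, bool))
        events, kin = extract_events(s, min_residence=0.0)
        assert kin.n_unbinding_events == 0
        assert len(events.episodes) == 1
        assert events.episodes[0].truncated

    def test_alternating_all_filtered_with_warning(self):
        s = BoundStateSeries(np.arange(20.0), np.arange(20) % 2 == 0)
        with pytest.warns(UserWarning, match="residence"):
            events, kin = extract_events(s, min_residence=50.0)
        assert kin.residence_times.size == 0
        # short bound episodes merge into unbound time for event counting
        assert kin.n_unbinding_events == 0

    def test_short_episodes_can_be_retained(self):
        s = BoundStateSeries(np.arange(20.0), np.arange(20) % 2 == 0)
        with pytest.warns(UserWarning, match="residence"):
            _, kin = extract_events(s, min_residence=50.0, count_short_events=True)
        assert kin.n_unbinding_events == 10

    def test_episodes_tile_timeline(self):
        rng = np.random.default_rng(4)
        s = BoundStateSeries(np.arange(200.0), rng.random(200) < 0.6)
        events, _ = extract_events(s, min_residence=0.0)
        total = sum(e.duration for e in events.episodes)
        assert total == pytest.approx(200.0)
        for a, b in zip(events.episodes, events.episodes[1:]):
            assert a.end == pytest.approx(b.start)


class TestThermodynamics:
    def test_equal_counts(self):
        s = BoundStateSeries(np.arange(10.0), np.arange(10) < 5)
        summ = binding_thermodynamics(s)
        assert summ.Kd == pytest.approx(1.0)
        assert summ.deltaG0 == pytest.approx(0.0)

    def test_hand_arithmetic_910_split(self):
        s = BoundStateSeries(np.arange(1000.0), np.arange(1000) < 900)
        summ = binding_thermodynamics(s, temperature=310.0)
        assert summ.Kd == pytest.approx(1 / 9)
        # RT = 0.61603 kcal/mol at 310 K; ln(1/9) = -2.1972
        assert summ.deltaG0 == pytest.approx(-1.3536, abs=2e-4)

    def test_single_state_undefined(self):
        s = BoundStateSeries(np.arange(10.0), np.ones(10, bool))
        with pytest.warns(UserWarning, match="undefined"):
            summ = binding_thermodynamics(s)
        assert summ.Kd is None and summ.deltaG0 is None

    def test_markov_fixture_kd(self):
        from taildyn.synthetic import TwoStateSpec, gen_two_state_timeline

        tl = gen_two_state_timeline(
            TwoStateSpec(k_on=4e6, k_off=1e6, dt=1e-9, n_frames=1_000_000, seed=17)
        )
        summ = binding_thermodynamics(tl)
        assert summ.Kd == pytest.approx(0.25, rel=0.10)


class TestPerBpContactMap:
    def _duplex_traj(self, tail_xyz, n_bp=6):
        # strand 1: residues 1..n_bp, strand 2: residues n_bp+1..2n_bp
        n = 2 * n_bp
        coords = np.zeros((1, n + 1, 3))
        for i in range(n_bp):
            coords[0, i] = [i * 10.0, 0, 0]
            coords[0, n_bp + i] = [(n_bp - 1 - i) * 10.0, 2.0, 0]
        coords[0, n] = tail_xyz
        traj = bead_trajectory(
            coords,
            chain_ids=["D"] * n + ["A"],
            residue_ids=list(range(1, n + 1)) + [1],
            names=["P"] * n + ["CA"],
            elements=["P"] * n + ["C"],
        )
        pairing = default_bp_pairing(n_bp, list(range(1, n_bp + 1)),
                                     list(range(n_bp + 1, 2 * n_bp + 1)))
        return traj, pairing

    def test_single_bp_contact(self):
        traj, pairing = self._duplex_traj([30.0, -3.0, 0.0])  # near bp 4 strand 1 only
        m = per_bp_contact_map(traj, select(traj, "chain A"), select(traj, "chain D"),
                               pairing, cutoff=4.0, stride=1.0, burn_in=0.0)
        expected = np.zeros(6)
        expected[3] = 1.0
        assert np.allclose(m.mean_contacts, expected)

    def test_both_strands_aggregate_to_one_bin(self):
        traj, pairing = self._duplex_traj([30.0, 1.0, 0.0])  # 1 A from strand1, 1 A from strand2
        m = per_bp_contact_map(traj, select(traj, "chain A"), select(traj, "chain D"),
                               pairing, cutoff=4.0, stride=1.0, burn_in=0.0)
        assert m.mean_contacts[3] == pytest.approx(2.0)
        assert m.mean_contacts.sum() == pytest.approx(2.0)

    def test_empty_contacts_all_zero(self):
        traj, pairing = self._duplex_traj([30.0, 100.0, 0.0])
        m = per_bp_contact_map(traj, select(traj, "chain A"), select(traj, "chain D"),
                               pairing, cutoff=4.0, stride=1.0, burn_in=0.0)
        assert np.allclose(m.mean_contacts, 0.0)

    def test_unmapped_nucleotide_is_error(self):
        traj, pairing = self._duplex_traj([0.0, -3.0, 0.0])
        del pairing[3]
        with pytest.raises(ValueError, match="pairing"):
            per_bp_contact_map(traj, select(traj, "chain A"), select(traj, "chain D"),
                               pairing, cutoff=4.0, stride=1.0, burn_in=0.0)

    def test_conservation_against_total_contacts(self):
        rng = np.random.default_rng(8)
        n_bp = 5
        n = 2 * n_bp
        frames = 20
        coords = np.zeros((frames, n + 3, 3))
        for i in range(n_bp):
            coords[:, i] = [i * 8.0, 0, 0]
            coords[:, n_bp + i] = [(n_bp - 1 - i) * 8.0, 3.0, 0]
        coords[:, n:, :] = rng.uniform(-5, 45, size=(frames, 3, 3))
        traj = bead_trajectory(
            coords,
            chain_ids=["D"] * n + ["A"] * 3,
            residue_ids=list(range(1, n + 1)) + [1, 2, 3],
            names=["P"] * n + ["CA"] * 3,
            elements=["P"] * n + ["C"] * 3,
        )
        pairing = default_bp_pairing(n_bp, list(range(1, n_bp + 1)),
                                     list(range(n_bp + 1, n + 1)))
        m = per_bp_contact_map(traj, select(traj, "chain A"), select(traj, "chain D"),
                               pairing, cutoff=6.0, stride=1.0, burn_in=0.0)
        tl = residue_dna_contacts(traj, select(traj, "chain A"), select(traj, "chain D"),
                                  cutoff=6.0, stride=1.0, burn_in=0.0)
        assert m.mean_contacts.sum() == pytest.approx(tl.counts.sum() / frames)
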