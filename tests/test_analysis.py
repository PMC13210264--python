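"""Order parameters, free energy, pathway classification, local measures."""

import numpy as np
import pytest

from gofold import (
    OrderParameterSeries,
    base_com_delta,
    classify_pathway,
    compute_q,
    contact_frequency_map,
    corner_vs_diagonal,
    free_energy_profile,
    hbond_count,
    make_base_pair,
    pathway_fractions,
    q2d_histogram,
    trajectory_order_parameters,
)
from gofold.analysis import PathwayLabel
from gofold.constants import KB
from gofold.contacts import ContactMap, ContactPair

from conftest import toy_structure


def two_contact_map():
    return ContactMap(
        contacts=[ContactPair(1, 2, 3.8, (1, 3)),
                  ContactPair(3, 4, 3.0, (2, 4))],
        exclusions=set(), cutoff=4.0,
    )


class TestComputeQ:
    def test_native_frame_gives_one(self, hairpin):
        structure, _, cmap = hairpin
        assert compute_q(structure.coordinates(), cmap) == 1.0

    def test_threshold_counting(self):
        cmap = two_contact_map()
        # pair distances 4.0 and 5.0; thresholds 4.56 and 3.6
        frame = np.array([[0, 0, 0], [4.0, 0, 0], [10, 0, 0], [10, 5.0, 0]],
                         dtype=float)
        assert compute_q(frame, cmap, lambda_formed=1.2) == 0.5

    def test_expanded_frame_gives_zero(self, hairpin):
        structure, _, cmap = hairpin
        assert compute_q(structure.coordinates() * 10.0, cmap) == 0.0

    def test_domain_restriction_and_empty_domain_error(self, mini_trna):
        structure, partition, cmap = mini_trna
        q = compute_q(structure.coordinates(), cmap,
                      domain=partition["asl"], domain_name="asl")
        assert q == 1.0
        with pytest.raises(ValueError, match="ghost"):
            compute_q(structure.coordinates(), cmap, domain={999},
                      domain_name="ghost")

    def test_monotone_under_compression_toward_native(self, hairpin):
        # interpolating any frame toward native never decreases Q
        structure, _, cmap = hairpin
        native = structure.coordinates()
        rng = np.random.default_rng(0)
        for _ in range(5):
            frame = native + rng.normal(0, 3.0, native.shape)
            qs = [compute_q(native + t * (frame - native), cmap)
                  for t in np.linspace(0, 1, 11)]
            assert all(a >= b for a, b in zip(qs, qs[1:]))


class TestFreeEnergy:
    def test_closed_form_difference(self):
        # occupancies {8, 4, 4}: bin-to-bin dF = kB * 353 * ln 2
        samples = [0.125] * 8 + [0.175] * 4 + [0.225] * 4
        prof = free_energy_profile(samples, T=353.0, n_bins=20)
        occ = prof.occupancy
        f = prof.F[occ > 0]
        expected = KB * 353.0 * np.log(2.0)
        assert f[0] == pytest.approx(0.0, abs=1e-12)
        assert f[1] == pytest.approx(expected, abs=1e-9)
        assert f[2] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.4862, abs=1e-4)

    def test_uniform_occupancy_is_flat(self):
        samples = np.linspace(0.025, 0.975, 20)
        prof = free_energy_profile(samples, T=300.0, n_bins=20)
        assert np.allclose(prof.F, 0.0, atol=1e-12)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        q = rng.uniform(0, 1, 200)
        a = free_energy_profile(q, T=353.0)
        b = free_energy_profile(np.concatenate([q, q]), T=353.0)
        assert np.allclose(a.F, b.F, equal_nan=True)

    def test_temperature_equivariance(self):
        rng = np.random.default_rng(2)
        q = rng.uniform(0, 1, 500)
        a = free_energy_profile(q, T=300.0)
        b = free_energy_profile(q, T=600.0)
        assert np.allclose(2.0 * a.F, b.F, equal_nan=True)

    def test_empty_bins_masked_and_min_zero(self):
        prof = free_energy_profile([0.1] * 5 + [0.9] * 3, T=353.0, n_bins=10)
        assert np.isnan(prof.F[5])
        assert np.nanmin(prof.F) == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            free_energy_profile([], T=300.0)
        with pytest.raises(ValueError):
            free_energy_profile([0.5, 1.4], T=300.0)


def series(**domains):
    n = max(len(v) for v in domains.values())
    return OrderParameterSeries(
        times=np.arange(n, dtype=float),
        q_global=np.zeros(n),
        q_domain={k: np.asarray(v, dtype=float) for k, v in domains.items()},
    )


def step(n, t_fold, n_frames):
    q = np.zeros(n_frames)
    q[t_fold:] = 1.0
    return q


class TestClassifyPathway:
    def test_recovers_crossing_order(self):
        n = 500
        ser = series(asl=step(0, 100, n), tsl=step(0, 200, n),
                     dsl=step(0, 300, n), aas=step(0, 400, n))
        lab = classify_pathway(ser)
        assert lab.label == "asl→tsl→dsl→aas"
        assert [e[0] for e in lab.events] == ["asl", "tsl", "dsl", "aas"]

    def test_transient_spike_ignored_by_persistence(self):
        n = 600
        dsl = step(0, 500, n)
        dsl[100:102] = 1.0  # 2-frame spike, below persistence = 5
        ser = series(dsl=dsl, tsl=step(0, 50, n))
        lab = classify_pathway(ser, persistence=5)
        assert lab.label == "tsl→dsl"
        assert dict(lab.events)["dsl"] == 500.0

    def test_partial_folding(self):
        ser = series(tsl=step(0, 10, 50), dsl=np.zeros(50))
        lab = classify_pathway(ser)
        assert lab.label == "tsl"
        assert len(lab.events) == 1

    def test_none_when_nothing_folds(self):
        ser = series(tsl=np.zeros(30), dsl=np.zeros(30))
        assert classify_pathway(ser).label == "none"

    def test_tie_flagged_and_broken_by_name(self):
        ser = series(tsl=step(0, 10, 50), dsl=step(0, 10, 50))
        lab = classify_pathway(ser)
        assert lab.tie
        assert lab.label == "dsl→tsl"

    def test_requires_enough_frames(self):
        with pytest.raises(ValueError):
            classify_pathway(series(tsl=np.ones(3)), persistence=5)


class TestPathwayFractions:
    def test_simple_fractions(self):
        labels = [PathwayLabel([], "A"), PathwayLabel([], "A"),
                  PathwayLabel([], "B")]
        summary = pathway_fractions(labels)
        assert summary.fractions["A"] == pytest.approx(66.6667, abs=1e-3)
        assert summary.fractions["B"] == pytest.approx(33.3333, abs=1e-3)
        assert summary.counts == {"A": 2, "B": 1}

    def test_paper_scale_arithmetic(self):
        labels = [PathwayLabel([], "tsl_second")] * 31 \
            + [PathwayLabel([], "other")] * 29
        summary = pathway_fractions(labels)
        assert summary.fractions["tsl_second"] == pytest.approx(51.67, abs=0.01)

    def test_sums_to_hundred(self):
        rng = np.random.default_rng(3)
        labels = [PathwayLabel([], f"L{k}") for k in rng.integers(0, 5, 37)]
        summary = pathway_fractions(labels)
        assert sum(summary.fractions.values()) == pytest.approx(100.0,
                                                               abs=0.01)

    def test_single_label(self):
        assert pathway_fractions([PathwayLabel([], "X")]).fractions == \
            {"X": 100.0}


class TestContactFrequency:
    def test_native_frames_give_ones(self, hairpin):
        structure, _, cmap = hairpin
        frames = np.repeat(structure.coordinates()[None], 4, axis=0)
        freq = contact_frequency_map(frames, cmap, structure.n_residues)
        rp = set(map(tuple, cmap.residue_pairs()))
        for a, b in rp:
            assert freq[a - 1, b - 1] == 1.0
        assert np.allclose(freq, freq.T)

    def test_extended_frames_give_zeros(self, hairpin):
        structure, _, cmap = hairpin
        frames = np.repeat(structure.coordinates()[None] * 10, 3, axis=0)
        freq = contact_frequency_map(frames, cmap, structure.n_residues)
        assert np.all(freq == 0.0)

    def test_half_native_half_extended(self, hairpin):
        structure, _, cmap = hairpin
        native = structure.coordinates()
        frames = np.stack([native, native * 10, native, native * 10])
        freq = contact_frequency_map(frames, cmap, structure.n_residues)
        for a, b in cmap.residue_pairs():
            assert freq[a - 1, b - 1] == pytest.approx(0.5)


def test_sequential_folding_populates_corners(mini_trna):
    from gofold import make_scripted_trajectory

    structure, partition, cmap = mini_trna
    series_list = []
    for k, order in enumerate((["tsl", "dsl"], ["dsl", "tsl"])):
        traj = make_scripted_trajectory((structure, partition), order,
                                        [30, 70], 100, seed=k)
        series_list.append(trajectory_order_parameters(
            traj.frames, traj.times, cmap, partition))
    hist, edges = q2d_histogram(series_list, "tsl", "dsl", n_bins=10)
    corner, diagonal = corner_vs_diagonal(hist, edges)
    assert corner > diagonal


class TestBaseComDelta:
    def com_structure(self, shift=0.0):
        # two residues with two equal-mass base atoms each
        return toy_structure(
            [[0, 0, 0], [2, 0, 0], [4 + shift, 0, 0], [6 + shift, 0, 0]],
            [1, 1, 2, 2],
            names={1: "N9", 2: "N1", 3: "N9", 4: "N1"},
        )

    def test_symmetric_centers_distance(self):
        s = self.com_structure()
        res = base_com_delta(([s.coordinates()], [s.coordinates()]),
                             (s, s), 1, 2)
        assert res["modified"] == pytest.approx(4.0)
        assert res["delta"] == pytest.approx(0.0)

    def test_sign_convention_negative_means_closer(self):
        s_mod = self.com_structure(shift=-0.4)   # d = 4.6... adjust below
        s_unmod = self.com_structure()
        res = base_com_delta(
            ([s_mod.coordinates()], [s_unmod.coordinates()]),
            (s_mod, s_unmod), 1, 2,
        )
        assert res["delta"] == pytest.approx(-0.4)

    def test_gate_with_no_frames_errors(self, mini_trna):
        structure, partition, cmap = mini_trna
        frames = structure.coordinates()[None] * 10  # fully unfolded
        with pytest.raises(ValueError, match="gate"):
            base_com_delta(
                ([frames], [frames]), (structure, structure),
                focus_residue=1, neighbor=2, gate={"asl": 0.8},
                cmaps=(cmap, cmap), partitions=(partition, partition),
            )


class TestHbonds:
    def pair(self, d):
        # pseudo G (donor N2) facing pseudo A (acceptor N1)
        return toy_structure(
            [[0, 0, 0], [1.5, 0, 0], [1.5 + d, 0, 0], [3.0 + d, 0, 0]],
            [1, 1, 2, 2],
            names={1: "N9", 2: "N2", 3: "N1", 4: "N9"},
            bases={1: "G", 2: "A"},
        )

    def test_single_bond_counted(self):
        s = self.pair(2.9)
        assert hbond_count(s.coordinates(), s, 1, 2) == 1

    def test_beyond_threshold_not_counted(self):
        s = self.pair(3.6)
        assert hbond_count(s.coordinates(), s, 1, 2) == 0

    def test_symmetric(self):
        s = self.pair(2.9)
        assert hbond_count(s.coordinates(), s, 1, 2) \
            == hbond_count(s.coordinates(), s, 2, 1)

    def test_no_chemistry_returns_zero(self, caplog):
        s = toy_structure([[0, 0, 0], [1.4, 0, 0], [3, 0, 0], [4.4, 0, 0]],
                          [1, 1, 2, 2],
                          names={1: "N1", 2: "C2", 3: "N1", 4: "C2"},
                          bases={1: "U", 2: "U"})
        # pseudo U carries neither its donor (N3) nor its acceptors here
        assert hbond_count(s.coordinates(), s, 1, 2) == 0

    def test_full_geometry_pair_matches_enumeration_oracle(self):
        from gofold.constants import HB_ACCEPTORS, HB_DONORS

        s = make_base_pair("G", "A", distance=2.9)
        frame = s.coordinates()
        expected = set()
        for ra, rb in ((s.residues[0], s.residues[1]),
                       (s.residues[1], s.residues[0])):
            for d in ra.base_atoms:
                if d.name not in HB_DONORS[ra.base]:
                    continue
                for acc in rb.base_atoms:
                    if acc.name not in HB_ACCEPTORS[rb.base]:
                        continue
                    r = np.linalg.norm(frame[d.index - 1]
                                       - frame[acc.index - 1])
                    if r < 3.5:
                        expected.add(tuple(sorted((d.index, acc.index))))
        assert hbond_count(frame, s, 1, 2) == len(expected)
        assert hbond_count(frame, s, 1, 2) >= 1
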