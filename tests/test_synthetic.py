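"""Fixture generators: geometry guarantees, scripted oracles, unfolded starts."""

import itertools

import numpy as np
import pytest

from gofold import (
    build_native_contacts,
    classify_pathway,
    compute_q,
    make_hairpin,
    make_mini_trna,
    make_nucleotide,
    make_scripted_trajectory,
    randomize_unfolded,
    read_structure,
    trajectory_order_parameters,
    write_frame,
)


class TestHairpin:
    def test_counts(self):
        structure, partition = make_hairpin(6, 4, seed=0)
        assert structure.n_residues == 16
        assert structure.n_atoms == 48
        assert partition["stem"] == set(range(1, 7)) | set(range(11, 17))

    def test_cross_strand_contacts(self):
        structure, partition = make_hairpin(6, 4, seed=0)
        cmap = build_native_contacts(structure)
        cross = [c for c in cmap.contacts
                 if c.residue_pair[0] <= 6 and c.residue_pair[1] >= 11]
        assert len(cross) >= 6

    def test_native_q_is_one(self, hairpin):
        structure, _, cmap = hairpin
        assert compute_q(structure.coordinates(), cmap) == 1.0

    def test_seed_determinism(self):
        a, _ = make_hairpin(4, 4, seed=3)
        b, _ = make_hairpin(4, 4, seed=3)
        c, _ = make_hairpin(4, 4, seed=4)
        assert np.array_equal(a.coordinates(), b.coordinates())
        assert not np.array_equal(a.coordinates(), c.coordinates())

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_hairpin(2, 4)
        with pytest.raises(ValueError):
            make_hairpin(4, 2)


class TestMiniTrna:
    def test_domains_cover_all_five_names(self, mini_trna):
        _, partition, _ = mini_trna
        assert set(partition.names()) == {"aas", "asl", "dsl", "tsl", "vl"}

    def test_per_domain_native_q_is_one(self, mini_trna):
        structure, partition, cmap = mini_trna
        for name in partition.names():
            assert compute_q(structure.coordinates(), cmap,
                             domain=partition[name], domain_name=name) == 1.0

    def test_intra_domain_contacts(self):
        structure, partition = make_mini_trna(4, seed=0)
        cmap = build_native_contacts(structure)
        for arm in ("asl", "dsl", "tsl", "aas"):
            intra = [c for c in cmap.contacts
                     if c.residue_pair[0] in partition[arm]
                     and c.residue_pair[1] in partition[arm]]
            assert len(intra) >= 4, arm
        vl = [c for c in cmap.contacts
              if c.residue_pair[0] in partition["vl"]
              and c.residue_pair[1] in partition["vl"]]
        assert len(vl) >= 1

    def test_interdomain_contacts_exist(self, mini_trna):
        structure, partition, cmap = mini_trna
        inter = [
            c for c in cmap.contacts
            for a, b in [c.residue_pair]
            if (a in partition["dsl"]
                and (b in partition["tsl"] or b in partition["vl"]))
            or (b in partition["dsl"]
                and (a in partition["tsl"] or a in partition["vl"]))
        ]
        assert len(inter) >= 1

    def test_seed_determinism(self):
        a, _ = make_mini_trna(3, seed=5)
        b, _ = make_mini_trna(3, seed=5)
        assert np.array_equal(a.coordinates(), b.coordinates())


class TestScriptedTrajectories:
    @pytest.mark.parametrize("order",
                             list(itertools.permutations(["asl", "dsl",
                                                          "tsl"])))
    def test_all_orderings_recovered(self, mini_trna, order):
        structure, partition, cmap = mini_trna
        traj = make_scripted_trajectory((structure, partition), list(order),
                                        [20, 45, 70], 100, seed=1)
        ser = trajectory_order_parameters(traj.frames, traj.times, cmap,
                                          partition)
        lab = classify_pathway(ser)
        assert lab.label.startswith("→".join(order))

    def test_zero_jitter_is_piecewise_monotone(self, mini_trna):
        structure, partition, cmap = mini_trna
        traj = make_scripted_trajectory((structure, partition),
                                        ["tsl", "dsl"], [20, 50], 80,
                                        seed=0, jitter=0.0)
        ser = trajectory_order_parameters(traj.frames, traj.times, cmap,
                                          partition)
        for name in ("tsl", "dsl"):
            q = ser.q_domain[name]
            assert np.all(np.diff(q) >= -1e-12)

    def test_fold_times_validated(self, mini_trna):
        structure, partition, _ = mini_trna
        with pytest.raises(ValueError, match="exceed"):
            make_scripted_trajectory((structure, partition), ["tsl"], [100],
                                     50, seed=0)
        with pytest.raises(ValueError, match="increasing"):
            make_scripted_trajectory((structure, partition),
                                     ["tsl", "dsl"], [50, 30], 100, seed=0)


class TestRandomizeUnfolded:
    def test_zero_formed_contacts(self, hairpin):
        structure, _, cmap = hairpin
        x = randomize_unfolded(structure, seed=0, cmap=cmap)
        assert compute_q(x, cmap) == 0.0

    def test_bonded_distances_preserved(self, hairpin):
        structure, _, cmap = hairpin
        x = randomize_unfolded(structure, seed=1, cmap=cmap)
        native = structure.coordinates()
        for i, j in structure.bonds:
            d0 = np.linalg.norm(native[i - 1] - native[j - 1])
            d1 = np.linalg.norm(x[i - 1] - x[j - 1])
            assert abs(d1 - d0) / d0 < 0.10

    def test_self_avoiding(self, hairpin):
        structure, _, cmap = hairpin
        x = randomize_unfolded(structure, seed=2, cmap=cmap)
        from gofold.contacts import build_exclusions

        excl = build_exclusions(structure)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        n = len(x)
        d[np.tril_indices(n, 0)] = np.inf
        for i, j in excl:
            d[i - 1, j - 1] = np.inf
        assert d.min() >= 2.0 - 1e-9

    def test_seeds_differ(self, hairpin):
        structure, _, cmap = hairpin
        a = randomize_unfolded(structure, seed=3, cmap=cmap)
        b = randomize_unfolded(structure, seed=4, cmap=cmap)
        assert np.abs(a - b).max() > 1.0

    def test_satisfies_folding_precondition(self, mini_trna):
        structure, _, cmap = mini_trna
        x = randomize_unfolded(structure, seed=5, cmap=cmap)
        assert compute_q(x, cmap) < 0.2


class TestRoundTrips:
    @pytest.mark.parametrize("builder,args", [
        (make_hairpin, (4, 4)), (make_mini_trna, (3,)),
    ])
    def test_fixture_pdb_round_trip_and_contacts(self, builder, args,
                                                 tmp_path):
        structure, _ = builder(*args, seed=2)
        path = tmp_path / "fixture.pdb"
        write_frame(structure, structure.coordinates(), path)
        back = read_structure(path)
        cmap = build_native_contacts(back)
        assert cmap.n_contacts >= 1
        assert back.n_atoms == structure.n_atoms
        assert [a.name for a in back.atoms] \
            == [a.name for a in structure.atoms]

    def test_full_geometry_nucleotides(self):
        for base in ("G", "A"):
            s = make_nucleotide(base)
            s.validate()
            # planar ring
            assert np.abs(s.coordinates()[:, 2]).max() < 1e-9
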