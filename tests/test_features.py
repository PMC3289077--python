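import numpy as np
import pytest

from spasite.annotations import AnnotationRecord
from spasite.errors import InvalidWindowError, MissingAnnotationError, MissingProfileError, ShortChainError
from spasite.features import (
    FeatureTable,
    build_seqasa,
    build_seqprofile,
    build_spapf,
    build_spasecond,
    build_spawasa,
    concat_tables,
    encoding_dim,
    featurize_complex,
    read_feature_tsv,
    spatial_neighbor_order,
    spatial_neighbors_with_distances,
    write_feature_tsv,
)
from spasite.profiles import ProfileMatrix
from spasite.structure_io import ComplexStructure, label_interface_residues, residue_distance
from spasite.synthetic import FixtureSpec, make_bundle, make_complex

from conftest import line_structure, single_atom_residue


def make_ann(asa_values, ss_codes=None, chain="A"):
    ss_codes = ss_codes or ["C"] * len(asa_values)
    return {
        (chain, i): AnnotationRecord(chain, i, float(a), ss)
        for i, (a, ss) in enumerate(zip(asa_values, ss_codes))
    }


class TestSpatialNeighborOrder:
    def test_line_positions(self):
        s = line_structure([0.0, 3.0, 7.0, 12.0])
        assert spatial_neighbor_order(s, 0, 4).tolist() == [0, 1, 2, 3]

    def test_w1_is_target_only(self):
        s = line_structure([0.0, 3.0, 7.0])
        assert spatial_neighbor_order(s, 1, 1).tolist() == [1]

    def test_tie_break_lower_seq_index_first(self):
        # residues 1 and 2 both 3 A from the target
        s = line_structure([0.0, 3.0, -3.0])
        assert spatial_neighbor_order(s, 0, 3).tolist() == [0, 1, 2]

    def test_target_first_no_duplicates(self):
        rng = np.random.default_rng(4)
        s = line_structure(sorted(rng.uniform(0, 50, size=12)))
        for target in range(12):
            order = spatial_neighbor_order(s, target, 7)
            assert order[0] == target
            assert len(set(order.tolist())) == len(order) == 7

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(8)
        s = line_structure(rng.uniform(0, 40, size=10))
        for target in range(10):
            dists = [residue_distance(s, target, j, "ca") for j in range(10)]
            expected = sorted((j for j in range(10) if j != target),
                              key=lambda j: (dists[j], j))
            order = spatial_neighbor_order(s, target, 10)
            assert order.tolist() == [target] + expected

    def test_short_chain_errors(self):
        s = line_structure([0.0, 3.0])
        with pytest.raises(ShortChainError):
            spatial_neighbor_order(s, 0, 5)

    def test_distances_ascending(self):
        rng = np.random.default_rng(6)
        s = line_structure(rng.uniform(0, 40, size=9))
        _, dists = spatial_neighbors_with_distances(s, 4, 9)
        assert dists[0] == 0.0
        assert np.all(np.diff(dists) >= 0)


class TestBuildSpapf:
    def test_w15_gives_300(self, small_bundle):
        order = spatial_neighbor_order(small_bundle.structure, 7, 15)
        assert len(build_spapf(small_bundle.profile, order, 15)) == 300

    def test_w1_is_target_row(self, small_bundle):
        vec = build_spapf(small_bundle.profile, np.array([7]), 1)
        np.testing.assert_array_equal(vec, small_bundle.profile.rows[7])

    def test_slice_equality_every_position(self):
        rng = np.random.default_rng(12)
        p = ProfileMatrix("A", rng.normal(size=(20, 20)))
        order = rng.permutation(20)[:9]
        vec = build_spapf(p, order, 9)
        for j, idx in enumerate(order):
            np.testing.assert_array_equal(vec[20 * j : 20 * j + 20], p.rows[idx])

    def test_short_order_zero_padded(self):
        p = ProfileMatrix("A", np.ones((3, 20)))
        vec = build_spapf(p, np.array([0, 1, 2]), 5)
        assert len(vec) == 100
        assert np.all(vec[:60] == 1) and np.all(vec[60:] == 0)

    def test_out_of_range_index_errors(self):
        p = ProfileMatrix("A", np.ones((3, 20)))
        with pytest.raises(MissingProfileError):
            build_spapf(p, np.array([0, 5]), 2)


class TestBuildSpawasa:
    def test_w15_gives_15(self):
        ann = make_ann(range(1, 21))
        order = np.arange(15)
        dists = np.linspace(0, 10, 15)
        assert len(build_spawasa(ann, order, dists, 15)) == 15

    def test_target_entry_is_raw_asa(self):
        ann = make_ann([42.0, 7.0])
        vec = build_spawasa(ann, np.array([0, 1]), np.array([0.0, 3.0]), 2)
        assert vec[0] == 42.0

    def test_monotone_decay_in_distance(self):
        ann = make_ann([50.0] * 6)
        order = np.arange(6)
        base = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 16.0])
        vec = build_spawasa(ann, order, base, 6, d0=8.0)
        assert np.all(np.diff(vec) < 0)

    def test_exact_weighting_formula(self):
        ann = make_ann([10.0, 20.0, 30.0])
        dists = np.array([0.0, 2.0, 5.0])
        vec = build_spawasa(ann, np.arange(3), dists, 3, d0=8.0)
        expected = np.array([10.0, 20.0 * np.exp(-2 / 8), 30.0 * np.exp(-5 / 8)])
        np.testing.assert_allclose(vec, expected)

    def test_infinite_d0_reduces_to_raw_window(self):
        asa = [11.0, 22.0, 33.0, 44.0]
        ann = make_ann(asa)
        vec = build_spawasa(ann, np.arange(4), np.array([0.0, 3.0, 6.0, 9.0]), 4, d0=np.inf)
        np.testing.assert_allclose(vec, asa)

    def test_missing_annotation_errors(self):
        ann = make_ann([1.0])
        with pytest.raises(MissingAnnotationError):
            build_spawasa(ann, np.array([0, 3]), np.array([0.0, 1.0]), 2)


class TestBuildSpasecond:
    def test_all_helix(self):
        ann = make_ann([1.0] * 5, ["H"] * 5)
        np.testing.assert_array_equal(build_spasecond(ann, np.arange(5), 5), [1, 0, 0])

    def test_mixed_window(self):
        ann = make_ann([1.0] * 4, ["H", "H", "E", "C"])
        np.testing.assert_allclose(build_spasecond(ann, np.arange(4), 4), [0.5, 0.25, 0.25])

    @pytest.mark.parametrize("seed", range(4))
    def test_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.choice(["H", "E", "C"], size=8).tolist()
        ann = make_ann([1.0] * 8, codes)
        assert build_spasecond(ann, np.arange(8), 8).sum() == pytest.approx(1.0)


class TestSequenceBaselines:
    def test_seqprofile_length(self):
        p = ProfileMatrix("A", np.arange(40 * 20, dtype=float).reshape(40, 20))
        assert len(build_seqprofile(p, 20, 15)) == 300

    def test_seqprofile_left_padding(self):
        p = ProfileMatrix("A", np.ones((5, 20)))
        vec = build_seqprofile(p, 0, 3)
        assert np.all(vec[:20] == 0)
        assert np.all(vec[20:] == 1)

    def test_seqprofile_interior_matches_index_arithmetic(self):
        rng = np.random.default_rng(21)
        p = ProfileMatrix("A", rng.normal(size=(30, 20)))
        w, target = 7, 12
        vec = build_seqprofile(p, target, w)
        expected = np.concatenate([p.rows[target - 3 + j] for j in range(w)])
        np.testing.assert_array_equal(vec, expected)

    def test_seqprofile_even_w_errors(self):
        p = ProfileMatrix("A", np.ones((5, 20)))
        with pytest.raises(InvalidWindowError):
            build_seqprofile(p, 2, 4)

    def test_seqasa_w1(self):
        ann = make_ann([5.5, 9.0])
        np.testing.assert_array_equal(build_seqasa(ann, 1, 1), [9.0])

    def test_seqasa_terminal_padding(self):
        ann = make_ann([1.0, 2.0, 3.0])
        vec = build_seqasa(ann, 0, 5)
        np.testing.assert_array_equal(vec, [0.0, 0.0, 1.0, 2.0, 3.0])

    def test_seqasa_matches_direct_indexing(self):
        rng = np.random.default_rng(30)
        asa = rng.uniform(0, 200, size=12)
        ann = make_ann(asa)
        vec = build_seqasa(ann, 6, 5)
        np.testing.assert_allclose(vec, asa[4:9])


class TestFeaturizeComplex:
    def test_spapf_shape(self, small_bundle):
        b = small_bundle
        t = featurize_complex(b.structure, b.profile, b.annotations, b.labels, "SpaPF", 15)
        assert t.X.shape == (30, 300)
        assert t.encoding == "SpaPF" and t.window_w == 15

    def test_labels_pass_through(self, small_bundle):
        b = small_bundle
        t = featurize_complex(b.structure, b.profile, b.annotations, b.labels, "SpaPF", 15)
        np.testing.assert_array_equal(t.labels, b.labels)
        np.testing.assert_array_equal(t.labels, label_interface_residues(b.structure))

    def test_rows_match_per_residue_builder(self, small_bundle):
        b = small_bundle
        t = featurize_complex(b.structure, b.profile, b.annotations, b.labels, "SpaPF", 15)
        for i in range(30):
            order = spatial_neighbor_order(b.structure, i, 15)
            np.testing.assert_array_equal(t.X[i], build_spapf(b.profile, order, 15))

    @pytest.mark.parametrize("encoding,dim", [
        ("SpaPF", 300), ("SpawASA", 15), ("SpaSecond", 3), ("SeqProfile", 300), ("SeqASA", 15),
    ])
    def test_all_encoding_dims(self, small_bundle, encoding, dim):
        b = small_bundle
        t = featurize_complex(b.structure, b.profile, b.annotations, b.labels, encoding, 15)
        assert t.X.shape == (30, dim)
        assert encoding_dim(encoding, 15) == dim

    def test_rna_permutation_invariance(self, small_bundle):
        b = small_bundle
        t1 = featurize_complex(b.structure, b.profile, b.annotations, b.labels, "SpaPF", 15)
        reordered = ComplexStructure(
            b.structure.protein_residues() + b.structure.rna_residues()[::-1],
            source_id=b.structure.source_id,
        )
        t2 = featurize_complex(reordered, b.profile, b.annotations, b.labels, "SpaPF", 15)
        np.testing.assert_array_equal(t1.X, t2.X)

    def test_short_chain_padded_not_dropped(self):
        bundle = make_bundle(FixtureSpec(n_residues=8, rna_patch=(2, 3), seed=5))
        t = featurize_complex(
            bundle.structure, bundle.profile, bundle.annotations, bundle.labels, "SpaPF", 15
        )
        assert t.X.shape == (8, 300)
        assert np.all(t.X[:, 8 * 20 :] == 0)


class TestFeatureTableIo:
    def test_tsv_round_trip(self, tmp_path, small_bundle):
        b = small_bundle
        t = featurize_complex(b.structure, b.profile, b.annotations, b.labels, "SpawASA", 15)
        path = tmp_path / "f.tsv"
        write_feature_tsv(t, path)
        back = read_feature_tsv(path)
        assert back.encoding == t.encoding and back.window_w == t.window_w
        assert back.metric == t.metric and back.d0 == t.d0
        np.testing.assert_array_equal(back.X, t.X)
        np.testing.assert_array_equal(back.labels, t.labels)
        assert back.provenance == t.provenance

    def test_concat_tables(self, small_bundle):
        b = small_bundle
        t = featurize_complex(b.structure, b.profile, b.annotations, b.labels, "SpaPF", 15)
        both = concat_tables([t, t])
        assert both.X.shape == (60, 300)
        chains = {cid for cid, _ in both.provenance}
        assert chains == {"0:A", "1:A"}
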