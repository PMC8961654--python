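"""Superposition, peptide RMSD, benchmark filters and rank metrics."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepspot import evaluation as ev
from pepspot.structio import ResidueRecord, TemplateComplex

from conftest import random_residue


def ca_residue(chain, num, xyz, letter="A"):
    from pepspot.modeling import AA3

    return ResidueRecord(chain, num, "", AA3[letter], letter,
                         (("CA", float(xyz[0]), float(xyz[1]), float(xyz[2])),))


def points_complex(receptor_pts, peptide_pts):
    receptor = tuple(ca_residue("A", i + 1, p) for i, p in enumerate(receptor_pts))
    peptide = tuple(ca_residue("B", j + 1, p) for j, p in enumerate(peptide_pts))
    return TemplateComplex(receptor, peptide, (0,) * len(peptide))


class TestKabsch:
    def test_self_superposition_is_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 3))
        tr = ev.kabsch(pts, pts)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(tr.translation, 0, atol=1e-10)

    def test_recovers_exact_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3)) * 5
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([3.0, -2.0, 7.0])
        tr = ev.kabsch(moved, pts)
        assert np.abs(tr.apply(moved) - pts).max() < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(15, 3)) * 8
        mov = rng.normal(size=(15, 3)) * 8
        tr = ev.kabsch(mov, ref)
        oracle, _ = Rotation.align_vectors(ref - ref.mean(0), mov - mov.mean(0))
        assert np.allclose(tr.rotation, oracle.as_matrix(), atol=1e-9)
        ours = float(np.sqrt(np.mean(np.sum((tr.apply(mov) - ref) ** 2, axis=1))))
        theirs = float(np.sqrt(np.mean(np.sum(
            ((mov - mov.mean(0)) @ oracle.as_matrix().T + ref.mean(0) - ref) ** 2,
            axis=1))))
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_reflection_excluded(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        mirrored = pts * np.array([1, 1, -1])
        tr = ev.kabsch(mirrored, pts)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)


class TestSuperposeReceptors:
    def test_identity_pair(self):
        rng = np.random.default_rng(4)
        cplx = points_complex(rng.normal(size=(6, 3)) * 9, rng.normal(size=(4, 3)))
        tr, moved, rmsd = ev.superpose_receptors(cplx, cplx)
        assert rmsd < 1e-9
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_rotated_copy_recovered(self):
        rng = np.random.default_rng(5)
        rec = rng.normal(size=(6, 3)) * 9
        pep = rng.normal(size=(4, 3)) * 3
        R = Rotation.from_euler("xyz", [30, -60, 90], degrees=True).as_matrix()
        t = np.array([4.0, 5.0, -6.0])
        ref = points_complex(rec, pep)
        mov = points_complex(rec @ R.T + t, pep @ R.T + t)
        _, moved, rmsd = ev.superpose_receptors(ref, mov)
        assert rmsd < 1e-6
        # peptide is carried along by the same transform
        for a, b in zip(moved.peptide, ref.peptide):
            assert np.allclose(a.coords, b.coords, atol=1e-6)

    def test_too_few_shared_atoms_raises(self):
        a = points_complex(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match=">= 3"):
            ev.superpose_receptors(a, a)

    def test_numbering_mismatch_falls_back_to_alignment(self):
        rng = np.random.default_rng(6)
        rec = rng.normal(size=(8, 3)) * 9
        pep = rng.normal(size=(3, 3))
        seq = "ACDEFGHK"
        ref = TemplateComplex(
            tuple(ca_residue("A", i + 1, rec[i], seq[i]) for i in range(8)),
            tuple(ca_residue("B", j + 1, pep[j]) for j in range(3)),
            (0, 0, 0))
        mov = TemplateComplex(
            tuple(ca_residue("A", i + 101, rec[i], seq[i]) for i in range(8)),
            tuple(ca_residue("B", j + 1, pep[j]) for j in range(3)),
            (0, 0, 0))
        _, _, rmsd = ev.superpose_receptors(ref, mov)
        assert rmsd < 1e-9


class TestPeptideRmsd:
    def test_identical_coordinates_zero(self):
        rng = np.random.default_rng(7)
        pep = [ca_residue("B", j + 1, p) for j, p in
               enumerate(rng.normal(size=(5, 3)))]
        assert ev.peptide_rmsd(pep, pep, [(j, j) for j in range(5)]) == 0.0

    def test_two_pairs_three_and_four_angstrom(self):
        a = [ca_residue("B", 1, (0, 0, 0)), ca_residue("B", 2, (10, 0, 0))]
        b = [ca_residue("B", 1, (3, 0, 0)), ca_residue("B", 2, (10, 4, 0))]
        got = ev.peptide_rmsd(a, b, [(0, 0), (1, 1)])
        assert got == pytest.approx(math.sqrt((9 + 16) / 2), abs=1e-4)
        assert got == pytest.approx(3.5355, abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        xa, xb = rng.normal(size=(n, 3)) * 5, rng.normal(size=(n, 3)) * 5
        pa = [ca_residue("B", j + 1, p) for j, p in enumerate(xa)]
        pb = [ca_residue("B", j + 1, p) for j, p in enumerate(xb)]
        expected = math.sqrt(
            sum(np.sum((xa[i] - xb[i]) ** 2) for i in range(n)) / n)
        assert ev.peptide_rmsd(pa, pb, [(j, j) for j in range(n)]) == \
            pytest.approx(expected, abs=1e-9)

    def test_common_rigid_transform_invariance(self):
        rng = np.random.default_rng(11)
        xa, xb = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 10
        pa = [ca_residue("B", j + 1, p) for j, p in enumerate(xa)]
        pb = [ca_residue("B", j + 1, p) for j, p in enumerate(xb)]
        pa2 = [ca_residue("B", j + 1, p) for j, p in enumerate(xa @ R.T + t)]
        pb2 = [ca_residue("B", j + 1, p) for j, p in enumerate(xb @ R.T + t)]
        eq = [(j, j) for j in range(6)]
        assert ev.peptide_rmsd(pa, pb, eq) == pytest.approx(
            ev.peptide_rmsd(pa2, pb2, eq), abs=1e-9)

    def test_missing_ca_pairs_dropped_then_error(self):
        from pepspot.modeling import AA3

        no_ca = ResidueRecord("B", 1, "", "ALA", "A", (("CB", 0.0, 0.0, 0.0),))
        ok = ca_residue("B", 2, (1, 0, 0))
        got = ev.peptide_rmsd([no_ca, ok], [no_ca, ok], [(0, 0), (1, 1)])
        assert got == 0.0
        with pytest.raises(ValueError, match="C-alpha"):
            ev.peptide_rmsd([no_ca], [no_ca], [(0, 0)])


class TestClassifyRmsd:
    @pytest.mark.parametrize("value,cls", [
        (0.0, "L"), (0.4, "L"), (1.4999, "L"),
        (1.5, "M"), (1.82, "M"), (2.9999, "M"),
        (3.0, "H"), (6.79, "H"), (100.0, "H"),
    ])
    def test_class_bounds(self, value, cls):
        assert ev.classify_rmsd(value) == cls

    def test_partition_of_half_line(self):
        rng = np.random.default_rng(13)
        for v in rng.uniform(0, 10, 200):
            assert ev.classify_rmsd(v) in {"L", "M", "H"}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ev.classify_rmsd(-0.1)


def nw_identity_oracle(seq_a, seq_b):
    """Positional-match identity for equal-length peptides.

    With gap open -10 the optimal global BLOSUM62 alignment of two
    equal-length peptides is the ungapped one (opening a gap in each
    sequence costs at least 20, more than any mismatch saves), so identity
    reduces to a Hamming match count.
    """
    assert len(seq_a) == len(seq_b)
    matches = sum(1 for a, b in zip(seq_a, seq_b) if a == b)
    return matches / len(seq_a)


class TestPeptideIdentity:
    def test_identical_peptides(self):
        assert ev.peptide_identity("PEATAPPEE", "PEATAPPEE") == 1.0

    def test_disjoint_alphabets(self):
        assert ev.peptide_identity("AAAA", "GGGG") == 0.0

    def test_known_pair_matches_independent_oracle(self):
        got = ev.peptide_identity("PTPSAPVPL", "PEATAPPEE")
        assert got == pytest.approx(nw_identity_oracle("PTPSAPVPL", "PEATAPPEE"))
        assert got == pytest.approx(3 / 9)  # P, A, P match positionally

    @pytest.mark.parametrize("seed", range(6))
    def test_random_equal_length_pairs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        from pepspot.constants import STANDARD_AA

        a = "".join(rng.choice(list(STANDARD_AA), 9))
        b = "".join(rng.choice(list(STANDARD_AA), 9))
        assert ev.peptide_identity(a, b) == pytest.approx(nw_identity_oracle(a, b))

    def test_shorter_length_denominator(self):
        # identical prefix: all 5 short letters match, identity 1.0
        assert ev.peptide_identity("AWCDE", "AWCDEFGH") == 1.0


def make_pair(receptor_id, pep_a, pep_b, identity, site_a=None, site_b=None,
              tag=""):
    site_a = frozenset(site_a if site_a is not None else {1, 2, 3})
    site_b = frozenset(site_b if site_b is not None else {1, 2, 3})
    return ev.BenchmarkPair(
        template_entry=ev.ComplexEntry(f"T{tag}", ("A",), "B", pep_a, site_a),
        target_entry=ev.ComplexEntry(f"G{tag}", ("A",), "B", pep_b, site_b),
        receptor_id=receptor_id,
        seq_identity=identity,
    )


class TestPairFilters:
    def test_length_bounds_inclusive(self):
        assert not ev.pair_passes_filters(make_pair("r", "AAA", "AAAA", 0.5))
        assert ev.pair_passes_filters(make_pair("r", "AAAA", "AAAA", 0.5))
        assert ev.pair_passes_filters(make_pair("r", "A" * 14, "A" * 14, 0.5))
        assert not ev.pair_passes_filters(make_pair("r", "A" * 15, "A" * 14, 0.5))

    def test_identity_boundary(self):
        assert ev.pair_passes_filters(make_pair("r", "A" * 9, "C" * 9, 0.80))
        assert not ev.pair_passes_filters(make_pair("r", "A" * 9, "C" * 9, 0.81))

    def test_length_ratio_strictly_greater(self):
        # 6/10 = 0.6 exactly -> excluded; 7/10 = 0.7 -> kept
        assert not ev.pair_passes_filters(make_pair("r", "A" * 6, "C" * 10, 0.1))
        assert ev.pair_passes_filters(make_pair("r", "A" * 7, "C" * 10, 0.1))

    def test_binding_site_overlap(self):
        same = make_pair("r", "A" * 9, "C" * 9, 0.1, {1, 2, 3, 4}, {1, 2, 3, 4})
        half = make_pair("r", "A" * 9, "C" * 9, 0.1, {1, 2, 3, 4}, {3, 4, 5, 6})
        low = make_pair("r", "A" * 9, "C" * 9, 0.1, {1, 2, 3, 4}, {4, 5, 6, 7})
        assert ev.pair_passes_filters(same)
        # Jaccard({1..4},{3..6}) = 2/6 < 0.5
        assert not ev.pair_passes_filters(half)
        assert not ev.pair_passes_filters(low)

    def test_per_receptor_cap_seeded_and_order_independent(self):
        pairs = [make_pair("recA", "A" * 9, "C" * 9, 0.1, tag=str(i))
                 for i in range(12)]
        pairs += [make_pair("recB", "A" * 9, "C" * 9, 0.1, tag=f"b{i}")
                  for i in range(3)]
        kept1 = ev.apply_pair_filters(pairs, max_per_receptor=5, seed=7)
        kept2 = ev.apply_pair_filters(list(reversed(pairs)), max_per_receptor=5,
                                      seed=7)
        assert kept1 == kept2
        by_rec = {}
        for p in kept1:
            by_rec.setdefault(p.receptor_id, []).append(p)
        assert len(by_rec["recA"]) == 5
        assert len(by_rec["recB"]) == 3
        kept3 = ev.apply_pair_filters(pairs, max_per_receptor=5, seed=8)
        assert kept3 != kept1  # different seed, different subsample


class TestRankMetrics:
    def test_topn_accuracy_counts(self):
        frac, count = ev.topn_accuracy([1, 3, 30], 10)
        assert frac == pytest.approx(2 / 3)
        assert count == "2/3"
        frac1, _ = ev.topn_accuracy([1, 3, 30], 1)
        assert frac1 == pytest.approx(1 / 3)

    def test_topn_monotone_in_n(self):
        ranks = [1, 4, 9, 26, 51, 74, 200, None]
        fracs = [ev.topn_accuracy(ranks, n)[0] for n in (1, 10, 25, 50, 75)]
        assert fracs == sorted(fracs)

    def test_absent_binder_counts_as_failure(self):
        frac, count = ev.topn_accuracy([1, None], 10)
        assert frac == 0.5 and count == "1/2"

    def test_rank_change_hand_example(self):
        s = ev.rank_change_summary([30, 40], [20, 45])
        assert s.n_total == 2
        assert s.n_improved == 1
        assert s.avg_rank_change == pytest.approx(2.5)
        assert s.avg_positive_change == pytest.approx(10.0)
        assert s.top10_after == 0 and s.top25_after == 1

    def test_identical_ranks_no_improvement(self):
        s = ev.rank_change_summary([30, 40, 50], [30, 40, 50])
        assert s.n_improved == 0 and s.avg_rank_change == 0.0

    def test_cases_already_top25_excluded(self):
        s = ev.rank_change_summary([5, 25], [100, 200])
        assert s.n_total == 0
        s2 = ev.rank_change_summary([5, 26], [100, 10])
        assert s2.n_total == 1 and s2.top10_after == 1


class TestHydrophobicityCorrelation:
    def test_perfect_positive_and_negative(self):
        seqs = ["III", "AAA", "GGG", "DDD"]  # KD means 4.5, 1.8, -0.4, -3.5
        idx = [ev.hydrophobicity_index(s) for s in seqs]
        assert ev.hydrophobicity_rank_correlation(seqs, idx) == pytest.approx(1.0)
        assert ev.hydrophobicity_rank_correlation(
            seqs, [-v for v in idx]) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(17)
        from pepspot.constants import STANDARD_AA

        seqs = ["".join(rng.choice(list(STANDARD_AA), 9)) for _ in range(20)]
        ranks = list(rng.permutation(20) + 1)
        x = np.array([ev.hydrophobicity_index(s) for s in seqs])
        y = np.array(ranks, dtype=float)
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert ev.hydrophobicity_rank_correlation(seqs, ranks) == \
            pytest.approx(expected, abs=1e-9)

    def test_zero_variance_undefined(self):
        assert math.isnan(
            ev.hydrophobicity_rank_correlation(["AAA", "AAA", "AAA"], [1, 2, 3]))
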