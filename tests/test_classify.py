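import itertools
import random
import re

import pytest

from prolamap.classify import (
    AlignmentParams,
    RepeatPattern,
    classify_records,
    count_cysteines,
    find_repeats,
    group_homology,
    identity_matrix,
    pairwise_identity,
)
from prolamap.seqio import SequenceRecord
from prolamap.synthetic import generate, toy_glupro_spec


def _needleman_wunsch_identity(a, b, params=None):
    """Brute-force reference: enumerate every global alignment, score it
    with BLOSUM62 + affine gaps, and return the (min, max) identity band
    over the optimal-score alignments.  Only feasible for tiny sequences."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    params = params or AlignmentParams()
    open_, ext = params.gap_open, params.gap_extend

    idents_by_score = {}

    def score(align_a, align_b):
        s = 0.0
        in_gap = None
        for x, y in zip(align_a, align_b):
            if x == "-" or y == "-":
                which = "a" if x == "-" else "b"
                s -= ext if in_gap == which else open_
                in_gap = which
            else:
                s += mat[x, y]
                in_gap = None
        return s

    def extend(align_a, align_b, i, j):
        if i == len(a) and j == len(b):
            s = score(align_a, align_b)
            ident = sum(x == y for x, y in zip(align_a, align_b))
            cols = len(align_a)
            idents_by_score.setdefault(round(s, 6), []).append(100.0 * ident / cols)
            return
        if i < len(a):
            extend(align_a + a[i], align_b + "-", i + 1, j)
        if j < len(b):
            extend(align_a + "-", align_b + b[j], i, j + 1)
        if i < len(a) and j < len(b):
            extend(align_a + a[i], align_b + b[j], i + 1, j + 1)

    extend("", "", 0, 0)
    optimal = idents_by_score[max(idents_by_score)]
    return round(min(optimal), 2), round(max(optimal), 2)


class TestCysteines:
    def test_examples(self):
        assert count_cysteines("ACCA") == 2
        assert count_cysteines("PQPQ") == 0

    def test_synthetic_skeletons(self, toy_dataset):
        # omega-type prolamins carry no cysteines; A-avenins nine, B-avenins eight
        expected = {t.group_name: t.expected_cys for t in toy_dataset.templates}
        assert expected["omega"] == 0
        assert expected["avenin_A"] == 9
        assert expected["avenin_B"] == 8
        groups = toy_dataset.groups_of()
        for rec in toy_dataset.clean_records:
            assert count_cysteines(rec.sequence) == expected[groups[rec.accession]]


class TestFindRepeats:
    def test_greedy_q_run(self):
        assert find_repeats("PFMQQQ", RepeatPattern("PFM", 1, 5)) == [(1, 6)]

    def test_q_run_capped(self):
        assert find_repeats("PFM" + "Q" * 8, RepeatPattern("PFM", 1, 5)) == [(1, 8)]

    def test_min_run_enforced(self):
        assert find_repeats("PFMA", RepeatPattern("PFM", 1, 5)) == []

    def test_no_match(self):
        assert find_repeats("AAAA", RepeatPattern("PFM", 1, 5)) == []

    def test_literal_pattern(self):
        assert find_repeats("AVTQGVTQG", RepeatPattern("VTQG")) == [(2, 5), (6, 9)]

    def test_overlapping_hits_reported(self):
        hits = find_repeats("MLLMLLQQQ", RepeatPattern("MLL", 3, 6))
        assert hits == [(4, 9)]
        hits = find_repeats("PFPFP", RepeatPattern("PFP"))
        assert hits == [(1, 3), (3, 5)]

    def test_regex_oracle_equivalence(self):
        rng = random.Random(3)
        pattern = RepeatPattern("PFM", 1, 5)
        rx = re.compile(r"(?=(PFMQ{1,5}))")
        for _ in range(200):
            seq = "".join(rng.choices("PFMQA", k=60))
            ours = find_repeats(seq, pattern)
            # the regex lookahead enumerates greedy matches at each position
            theirs = [(m.start() + 1, m.start() + len(m.group(1))) for m in rx.finditer(seq)]
            assert ours == theirs
            for start, end in ours:
                assert 1 <= start <= end <= len(seq)
                assert rx.match(seq[start - 1 :])


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("PQPQPFPQ", "PQPQPFPQ") == 100.0

    def test_worked_example(self):
        assert pairwise_identity("PQPQ", "PQPA") == 75.0

    def test_brute_force_oracle(self):
        # the aligner reports one optimal alignment; its identity must fall
        # inside the [min, max] identity band over all optimal alignments
        rng = random.Random(5)
        for _ in range(8):
            a = "".join(rng.choices("PQAG", k=rng.randint(2, 4)))
            b = "".join(rng.choices("PQAG", k=rng.randint(2, 4)))
            lo, hi = _needleman_wunsch_identity(a, b)
            assert lo <= pairwise_identity(a, b) <= hi

    def test_symmetry(self):
        rng = random.Random(9)
        for _ in range(20):
            a = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=rng.randint(5, 40)))
            b = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=rng.randint(5, 40)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "PQPQ")

    def test_identity_matrix_properties(self, toy_dataset):
        recs = toy_dataset.clean_records[:6]
        labels, mat = identity_matrix(recs)
        n = len(labels)
        for i in range(n):
            assert mat[i][i] == 100.0
            for j in range(n):
                assert mat[i][j] == mat[j][i]

    def test_adding_record_leaves_existing_identities(self, toy_dataset):
        recs = toy_dataset.clean_records[:4]
        _, small = identity_matrix(recs)
        _, big = identity_matrix(recs + [SequenceRecord("Z", sequence="MKTVVAAGAW" * 8)])
        for i, j in itertools.combinations(range(4), 2):
            assert small[i][j] == big[i][j]


class TestGroupHomology:
    def test_identical_pair(self):
        recs = [SequenceRecord("a", sequence="PQPQPF"), SequenceRecord("b", sequence="PQPQPF")]
        assert group_homology(recs, {"a": "g", "b": "g"}) == {"g": 100.0}

    def test_mean_over_pairs(self):
        recs = [
            SequenceRecord("a", sequence="PQPQ"),
            SequenceRecord("b", sequence="PQPA"),
            SequenceRecord("c", sequence="PQPQ"),
        ]
        # pairwise identities 75, 100, 75
        assert group_homology(recs, {"a": "g", "b": "g", "c": "g"}) == {"g": 83.33}

    def test_group_of_one_errors(self):
        recs = [SequenceRecord("a", sequence="PQPQ")]
        with pytest.raises(ValueError):
            group_homology(recs, {"a": "g"})


class TestClassification:
    def test_masters_classify_to_own_group(self, toy_dataset):
        results = classify_records(
            list(toy_dataset.masters.values()), toy_dataset.templates, toy_dataset.masters
        )
        group_of = {
            acc: t.group_name
            for t in toy_dataset.templates
            for acc in t.master_accessions
        }
        for r in results:
            assert r.assigned_group == group_of[r.accession]
            assert r.best_master == (r.accession, 100.0)

    def test_random_sequence_unclassified(self, toy_dataset):
        rng = random.Random(21)
        seq = "".join(rng.choices("ACDEFGHIKMNRSTVWY", k=200))  # uniform, Q/P-poor
        rec = SequenceRecord("RND", sequence=seq)
        (result,) = classify_records([rec], toy_dataset.templates, toy_dataset.masters)
        assert result.assigned_group == "unclassified"

    def test_accuracy_degrades_with_mutation_rate(self):
        accuracies = []
        for rate in (0.0, 0.05, 0.2):
            ds = generate(toy_glupro_spec(seed=1, mutation_rate=rate))
            truth = ds.groups_of()
            results = classify_records(ds.clean_records, ds.templates, ds.masters)
            acc = sum(r.assigned_group == truth[r.accession] for r in results) / len(results)
            accuracies.append(acc)
        assert accuracies[0] == 1.0
        assert accuracies[0] >= accuracies[1] >= accuracies[2]
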