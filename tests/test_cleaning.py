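import numpy as np
import pytest

from msaclean.cleaning import (
    CleaningParams,
    CleaningPipeline,
    CropEnds,
    MinimumSequencesError,
    RemoveDivergent,
    RemoveInsertions,
    crop_end,
    crop_ends,
    find_insertions,
    remove_divergent,
    remove_gap_only,
    remove_insertions,
    remove_short,
    run_pipeline,
    temporary_consensus,
)
from msaclean.synthetic import example1_like, generate
from .conftest import make_alignment, random_alignment, random_plan
from . import oracles


class TestTemporaryConsensus:
    def test_strict_majority(self):
        aln = make_alignment(["A", "A", "C"])
        assert temporary_consensus(aln) == "A"

    def test_all_gap_column(self):
        aln = make_alignment(["A-", "C-", "A-"])
        assert temporary_consensus(aln) == "A-"

    def test_tie_breaks_alphabetically(self):
        aln = make_alignment(["A", "C", "-"])
        assert temporary_consensus(aln) == oracles.consensus(["A", "C", "-"]) == "A"

    def test_requires_three_rows(self):
        with pytest.raises(MinimumSequencesError):
            temporary_consensus(make_alignment(["A", "C"]))


class TestRemoveDivergent:
    def test_identical_rows_kept(self):
        aln = make_alignment(["ACGTACGT"] * 3)
        out, rec = remove_divergent(aln)
        assert rec.removed_rows == [] and out.n_rows == 3

    def test_row_at_60_percent_removed_at_default(self):
        # 4 backbone rows; one row matching the consensus at 12/20 = 60%
        backbone = "ACGTACGTACGTACGTACGT"
        divergent = backbone[:12] + "TACGTACG"  # shifted tail: 0 matches there
        matches = sum(a == b for a, b in zip(backbone, divergent))
        assert matches / 20 == 0.6
        aln = make_alignment([backbone] * 4 + [divergent])
        out, rec = remove_divergent(aln)
        assert rec.removed_rows == ["s4"]
        assert out.names == ["s0", "s1", "s2", "s3"]

    def test_identity_uses_own_nongap_denominator(self):
        # 10 of the row's 12 residues match: 0.83 >= 0.65, kept despite padding
        backbone = "ACGTACGTACGTACGTACGT"
        partial = "--------ACGTTCGAACGT"
        aln = make_alignment([backbone] * 4 + [partial])
        _, rec = remove_divergent(aln)
        assert rec.removed_rows == []

    def test_all_gap_row_removed(self):
        aln = make_alignment(["ACGT"] * 3 + ["----"])
        _, rec = remove_divergent(aln)
        assert rec.removed_rows == ["s3"]

    def test_matches_oracle_on_random_input(self, rng):
        for _ in range(50):
            aln = random_alignment(rng)
            thr = float(rng.choice([0.3, 0.5, 0.65, 0.8]))
            _, rec = remove_divergent(aln, CleaningParams(divergent_min_identity=thr))
            rows = [aln.sequence(i) for i in range(aln.n_rows)]
            assert rec.removed_rows == oracles.divergent_removed(aln.names, rows, thr)


def insertion_fixture(width, n_cols=None, carriers=(4,), n_rows=5, start=20):
    """Rows share an internal gap block; carrier rows keep residues there."""
    n_cols = n_cols or (start + width + 20)
    rows = []
    for i in range(n_rows):
        row = list("ACGTA" * (n_cols // 5 + 1))[:n_cols]
        if i not in carriers:
            row[start:start + width] = "-" * width
        rows.append("".join(row))
    return make_alignment(rows)


class TestFindInsertions:
    def test_minority_carried_block_detected(self):
        aln = insertion_fixture(width=4)
        assert find_insertions(aln) == [(20, 24)]
        rows = [aln.sequence(i) for i in range(aln.n_rows)]
        assert oracles.insertion_runs(rows, 3, 200, 5) == [(20, 24)]

    def test_width_below_minimum_ignored(self):
        assert find_insertions(insertion_fixture(width=2)) == []

    def test_width_above_maximum_ignored(self):
        aln = insertion_fixture(width=250, n_cols=300)
        assert find_insertions(aln) == []
        # same geometry within bounds is found
        aln2 = insertion_fixture(width=200, n_cols=300)
        assert find_insertions(aln2) == [(20, 220)]

    def test_terminal_gaps_are_not_insertions(self):
        # most rows gapped at the start, but outside their spans
        rows = ["-----ACGTACGTACGT"] * 4 + ["ACGTAACGTACGTACGT"]
        assert find_insertions(make_alignment(rows)) == []

    def test_insufficient_flank_rejected(self):
        # block starts 2 columns from the edge: no room for a 5-residue flank
        aln = insertion_fixture(width=4, start=2)
        assert find_insertions(aln) == []

    def test_requires_three_rows(self):
        with pytest.raises(MinimumSequencesError):
            find_insertions(make_alignment(["ACGT", "AC-T"]))


class TestRemoveInsertions:
    def test_qualifying_block_removed_for_all_rows(self):
        aln = insertion_fixture(width=4)
        out, rec = remove_insertions(aln)
        assert out.n_cols == aln.n_cols - 4
        assert rec.removed_cols == [20, 21, 22, 23]

    def test_no_majority_gap_unchanged(self, toy):
        out, rec = remove_insertions(toy)
        assert out == toy and rec.removed_cols == []

    def test_two_disjoint_blocks_sorted_indices(self):
        n_cols = 60
        rows = []
        for i in range(5):
            row = list("ACGTA" * 12)
            if i != 4:
                row[15:19] = "----"
                row[35:38] = "---"
            rows.append("".join(row))
        aln = make_alignment(rows)
        out, rec = remove_insertions(aln)
        assert rec.removed_cols == [15, 16, 17, 18, 35, 36, 37]
        assert rec.removed_cols == sorted(rec.removed_cols)
        assert out.n_cols == n_cols - 7
        oracle = oracles.insertion_runs(
            [aln.sequence(i) for i in range(5)], 3, 200, 5
        )
        assert oracle == [(15, 19), (35, 38)]


class TestCropEnd:
    def test_worked_example_window_and_threshold(self):
        # 80 non-gap positions under defaults: examine 8 per end, 4-gap change
        op = CropEnds()
        assert op.window_size(80) == 8
        assert op.change_threshold(80) == 4

    def test_no_gaps_means_no_crop(self):
        row = "A" * 80
        assert crop_end(row, side="start") == 0
        assert crop_end(row, side="end") == 79

    def test_scattered_leading_residues_cropped(self):
        # two residues separated by wide gaps before a solid 58-residue body
        row = "-" * 6 + "A" + "-" * 8 + "C" + "-" * 8 + "A" * 58
        new_start = crop_end(row, side="start")
        assert new_start == 24  # first body residue
        assert new_start == oracles.crop_start(row)

    def test_end_side_mirrors_start(self):
        row = "A" * 58 + "-" * 8 + "C" + "-" * 8 + "A" + "-" * 6
        assert crop_end(row, side="end") == 57
        assert crop_end(row, side="end") == oracles.crop_end(row)

    def test_short_sequence_no_window(self):
        # L = 8 -> window floor(0.8) = 0: never cropped
        row = "-A-C-G-T-A-C-G-T" + "-" * 10
        assert crop_end(row, side="start") == 1

    def test_matches_oracle_on_random_rows(self, rng):
        chars = np.array(list("ACGT-"))
        for _ in range(200):
            n = int(rng.integers(10, 120))
            row = "".join(rng.choice(chars, size=n, p=[0.15] * 4 + [0.4]))
            if all(c == "-" for c in row):
                continue
            assert crop_end(row, side="start") == oracles.crop_start(row)
            assert crop_end(row, side="end") == oracles.crop_end(row)


class TestCropEnds:
    def test_masked_cells_counted_and_shape_kept(self):
        body = "A" * 58
        ragged = "-" * 6 + "A" + "-" * 8 + "C" + "-" * 8 + body
        clean = "G" * len(ragged)
        aln = make_alignment([ragged, clean, clean])
        out, rec = crop_ends(aln)
        assert out.n_cols == aln.n_cols and out.n_rows == aln.n_rows
        assert rec.cropped == {"s0": (2, 0)}
        assert out.sequence(0) == "-" * 24 + body

    def test_ungapped_alignment_untouched(self, toy):
        out, rec = crop_ends(toy)
        assert out == toy and rec.cropped == {}

    def test_masked_count_bounded_by_window(self, rng):
        for _ in range(30):
            aln = random_alignment(rng, n_rows=5, n_cols=60, gap_prob=0.35)
            out, rec = crop_ends(aln)
            for i, name in enumerate(aln.names):
                n_start, n_end = rec.cropped.get(name, (0, 0))
                L = int((aln.matrix[i] != "-").sum())
                window = CropEnds().window_size(L)
                assert n_start <= window and n_end <= window


class TestRemoveShort:
    def test_strict_less_than_boundary(self):
        row49 = "A" * 49 + "-" * 51
        row50 = "A" * 50 + "-" * 50
        full = "G" * 100
        aln = make_alignment([row49, row50, full])
        out, rec = remove_short(aln)
        assert rec.removed_rows == ["s0"]
        assert out.names == ["s1", "s2"]

    def test_ungapped_rows_kept(self):
        aln = make_alignment(["A" * 100] * 4)
        out, rec = remove_short(aln)
        assert rec.removed_rows == [] and out.n_rows == 4

    def test_removing_all_rows_warns(self):
        aln = make_alignment(["A---", "-C--", "--G-"])
        with pytest.warns(UserWarning, match="every sequence"):
            out, _ = remove_short(aln)
        assert out.n_rows == 0


class TestRemoveGapOnly:
    def test_no_gap_only_columns_unchanged(self, toy):
        out, rec = remove_gap_only(toy)
        assert out == toy and rec.removed_cols == []

    def test_exact_column_removed(self):
        aln = make_alignment(["A-C", "A-C", "G-T"])
        out, rec = remove_gap_only(aln)
        assert rec.removed_cols == [1]
        assert out.sequence(0) == "AC"

    def test_matches_column_scan_oracle(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, gap_prob=0.5)
            _, rec = remove_gap_only(aln)
            rows = [aln.sequence(i) for i in range(aln.n_rows)]
            assert rec.removed_cols == oracles.gaponly_cols(rows)


class TestPipeline:
    def test_gaponly_runs_with_nothing_enabled(self):
        aln = make_alignment(["A-C", "A-C", "G-T"])
        cleaned, records, markup = run_pipeline(aln, enabled=set())
        assert cleaned.n_cols == 2
        assert [r.function for r in records] == ["remove_gap_only"]
        assert markup.cells_of("remove_gap_only") == 3

    def test_all_defect_classes_removed(self):
        aln, truth = example1_like()
        cleaned, records, markup = run_pipeline(aln)
        by_fn = {r.function: r for r in records if not r.is_empty}
        assert by_fn["remove_divergent"].removed_rows == list(truth.divergent_rows)
        assert by_fn["remove_short"].removed_rows == truth.short_rows
        assert by_fn["crop_ends"].cropped == truth.cropped
        planted_cols = {
            c for s, e, q in truth.insertion_runs if q for c in range(s, e)
        }
        assert set(by_fn["remove_insertions"].removed_cols) == planted_cols

    def test_partial_idempotence(self):
        aln, _ = example1_like()
        cleaned, _, _ = run_pipeline(aln)
        again, records, _ = run_pipeline(
            cleaned, enabled={"remove_short", "remove_gap_only"}
        )
        assert again == cleaned
        assert all(r.is_empty for r in records)

    def test_gaponly_postcondition(self, rng):
        for seed in range(10):
            aln, _ = generate(random_plan(rng, seed))
            cleaned, _, _ = run_pipeline(aln)
            if cleaned.n_rows:
                assert not (cleaned.matrix == "-").all(axis=0).any()

    def test_two_row_alignment_skips_with_warning(self):
        aln = make_alignment(["ACGT" * 20, "ACGT" * 20])
        with pytest.warns(UserWarning, match="requires at least 3"):
            cleaned, records, _ = run_pipeline(aln)
        assert cleaned.n_rows == 2  # both rows long enough for remove_short

    def test_determinism(self):
        aln, _ = example1_like()
        a = run_pipeline(aln)
        b = run_pipeline(aln)
        assert a[0] == b[0]
        assert [r.__dict__ for r in a[1]] == [r.__dict__ for r in b[1]]
        assert (a[2].codes == b[2].codes).all()

    def test_unknown_function_rejected(self, toy):
        with pytest.raises(ValueError, match="unknown cleaning function"):
            run_pipeline(toy, enabled={"remove_everything"})


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        op = RemoveDivergent(min_identity=0.5)
        assert op.get_params() == {"min_identity": 0.5}
        op.set_params(min_identity=0.8)
        assert op.min_identity == 0.8

    def test_fitted_attributes(self):
        aln = insertion_fixture(width=4)
        op = RemoveInsertions().fit(aln)
        assert op.runs_ == [(20, 24)]
        assert op.record_.removed_cols == list(range(20, 24))

    def test_composes_with_sklearn_pipeline(self):
        from sklearn.pipeline import Pipeline

        aln = insertion_fixture(width=4)
        pipe = Pipeline([
            ("insertions", RemoveInsertions()),
            ("divergent", RemoveDivergent()),
        ])
        out = pipe.fit_transform(aln)
        assert out.n_cols == aln.n_cols - 4

    def test_transform_shape_guard(self, toy):
        op = RemoveDivergent().fit(toy)
        other = make_alignment(["ACGT", "ACGA", "ACGC"])
        with pytest.raises(ValueError, match="shape"):
            op.transform(other)


class TestCleaningParams:
    def test_size_ordering_enforced(self):
        with pytest.raises(ValueError, match="insertion_min_size"):
            CleaningParams(insertion_min_size=10, insertion_max_size=5)

    def test_proportions_validated(self):
        with pytest.raises(ValueError):
            CleaningParams(divergent_min_identity=0.0)

    def test_large_redefine_prop_warns(self):
        with pytest.warns(UserWarning, match="recommended"):
            CleaningParams(crop_redefine_prop=0.3)
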