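"""Residue-level profiling: scores, alanine effects, alignment projection."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptarray import (
    BinderSet,
    ToxinRecord,
    alanine_effects,
    alanine_variants,
    binding_profile,
    build_library,
    build_unique_set,
    compute_residue_profile,
    coverage_counts,
    project_onto_alignment,
    residue_scores,
)
from tests.conftest import median_table_from, random_toxins


def brute_force_residue_scores(toxin, occurrences, medians, k=12):
    """Window-membership oracle: plain loops, no slicing arithmetic shared
    with the implementation."""
    scores = []
    for i in range(1, len(toxin.sequence) + 1):
        covering = []
        for seq, occs in occurrences.items():
            for acc, start in occs:
                if acc == toxin.accession and start <= i <= start + k - 1:
                    covering.append(medians[seq])
        scores.append(sum(covering) / len(covering) if covering else math.nan)
    return scores


@pytest.fixture
def two_tile_setup(two_tile_toxin):
    """Length-14 toxin, tiles at starts 1 and 3, hand-set medians."""
    tiles, _ = build_unique_set([two_tile_toxin])
    occurrences = {t.sequence: t.occurrences for t in tiles}
    m1, m2 = 100.0, 300.0
    medians = {tiles[0].sequence: m1, tiles[1].sequence: m2}
    return two_tile_toxin, occurrences, medians, (m1, m2)


class TestBindingProfile:
    def test_two_points_at_tile_starts(self, two_tile_setup):
        toxin, occurrences, medians, (m1, m2) = two_tile_setup
        table = median_table_from(medians)
        profile = binding_profile(toxin, occurrences, table)
        assert list(profile.points["start"]) == [1, 3]
        assert list(profile.points["median"]) == [m1, m2]

    def test_shared_tile_appears_in_both_homolog_profiles(self):
        seq = "CDEFGHIKLMNP"
        toxins = [
            ToxinRecord(accession="H1", sequence=seq),
            ToxinRecord(accession="H2", sequence=seq),
        ]
        tiles, _ = build_unique_set(toxins)
        occurrences = {t.sequence: t.occurrences for t in tiles}
        table = median_table_from({seq: 250.0})
        for toxin in toxins:
            profile = binding_profile(toxin, occurrences, table)
            assert list(profile.points["median"]) == [250.0]

    def test_unknown_toxin_rejected(self, two_tile_setup):
        _, occurrences, medians, _ = two_tile_setup
        table = median_table_from(medians)
        ghost = ToxinRecord(accession="GHOST", sequence="C" * 14)
        with pytest.raises(KeyError, match="GHOST"):
            binding_profile(ghost, occurrences, table)


class TestResidueScores:
    def test_piecewise_means_for_two_tiles(self, two_tile_setup):
        toxin, occurrences, medians, (m1, m2) = two_tile_setup
        table = median_table_from(medians)
        scores = residue_scores(toxin, occurrences, table)
        assert np.allclose(scores[0:2], m1)  # residues 1-2: first tile only
        assert np.allclose(scores[2:12], (m1 + m2) / 2)  # residues 3-12: both
        assert np.allclose(scores[12:14], m2)  # residues 13-14: second only

    def test_constant_medians_give_flat_profile(self, two_tile_setup):
        toxin, occurrences, _, _ = two_tile_setup
        table = median_table_from({s: 42.0 for s in occurrences})
        assert np.allclose(residue_scores(toxin, occurrences, table), 42.0)

    def test_oracle_equivalence_on_random_instances(self, rng):
        toxins = random_toxins(rng, 6, lo=12, hi=40)
        tiles, _ = build_unique_set(toxins)
        occurrences = {t.sequence: t.occurrences for t in tiles}
        medians = {t.sequence: float(rng.uniform(1, 500)) for t in tiles}
        table = median_table_from(medians)
        for toxin in toxins:
            got = residue_scores(toxin, occurrences, table)
            want = brute_force_residue_scores(toxin, occurrences, medians)
            assert np.allclose(got, want, equal_nan=True)

    def test_scores_bounded_by_covering_medians(self, rng):
        toxins = random_toxins(rng, 4, lo=15, hi=40)
        tiles, _ = build_unique_set(toxins)
        occurrences = {t.sequence: t.occurrences for t in tiles}
        medians = {t.sequence: float(rng.uniform(1, 500)) for t in tiles}
        table = median_table_from(medians)
        lo, hi = min(medians.values()), max(medians.values())
        for toxin in toxins:
            scores = residue_scores(toxin, occurrences, table)
            assert np.all(scores >= lo - 1e-9)
            assert np.all(scores <= hi + 1e-9)

    def test_coverage_matches_brute_force(self, rng):
        toxins = random_toxins(rng, 5, lo=12, hi=40)
        tiles, _ = build_unique_set(toxins)
        occurrences = {t.sequence: t.occurrences for t in tiles}
        for toxin in toxins:
            counts = coverage_counts(toxin, occurrences)
            for i in range(1, len(toxin.sequence) + 1):
                brute = sum(
                    1
                    for seq, occs in occurrences.items()
                    for acc, start in occs
                    if acc == toxin.accession and start <= i <= start + 11
                )
                assert counts[i - 1] == brute


class TestAlanineEffects:
    def _library_with_medians(self, toxin, wt_value, knocked=None):
        """Full median table for one toxin: wt tiles at wt_value, variants
        at wt_value except entries of `knocked` ((residue, value) pairs)."""
        tiles, _ = build_unique_set([toxin])
        variants = alanine_variants(tiles)
        occurrences = {t.sequence: t.occurrences for t in tiles}
        medians = {t.sequence: wt_value for t in tiles}
        classes = {}
        knocked = knocked or {}
        for v in variants:
            classes[v.sequence] = "ala"
            value = wt_value
            for parent, pos in v.provenance:
                for acc, start in occurrences[parent]:
                    residue = start + pos - 1
                    if residue in knocked:
                        value = knocked[residue]
            medians.setdefault(v.sequence, value)
        return occurrences, median_table_from(medians, classes), tiles

    def test_single_binder_knockdown_effect_minus_three(self):
        toxin = ToxinRecord(accession="T0", sequence="CDEFGHIKLMNP")
        occurrences, table, tiles = self._library_with_medians(
            toxin, 400.0, knocked={5: 50.0}
        )
        binders = BinderSet("e", frozenset(t.sequence for t in tiles))
        effects = alanine_effects(toxin, occurrences, table, binders)
        assert effects[4] == pytest.approx(math.log2(50 / 400))  # -3
        assert effects[0] == pytest.approx(0.0)  # untouched residue

    def test_mean_over_covering_binders(self, two_tile_toxin):
        # residue 5 is covered by both tiles; knock its variant to -3 in
        # tile 1's context and -1 in tile 2's context
        tiles, _ = build_unique_set([two_tile_toxin])
        occurrences = {t.sequence: t.occurrences for t in tiles}
        wt = 400.0
        medians = {t.sequence: wt for t in tiles}
        classes = {}
        for tile in tiles:
            start = tile.occurrences[0][1]
            pos = 5 - start + 1  # in-peptide offset of toxin residue 5
            variant = tile.sequence[: pos - 1] + "A" + tile.sequence[pos:]
            value = wt / 8 if start == 1 else wt / 2  # effects -3 and -1
            medians[variant] = value
            classes[variant] = "ala"
        variants = alanine_variants(tiles)
        for v in variants:
            medians.setdefault(v.sequence, wt)
            classes.setdefault(v.sequence, "ala")
        table = median_table_from(medians, classes)
        binders = BinderSet("e", frozenset(t.sequence for t in tiles))
        effects = alanine_effects(two_tile_toxin, occurrences, table, binders)
        assert effects[4] == pytest.approx(-2.0)

    def test_no_covering_binder_is_null(self, two_tile_toxin):
        tiles, _ = build_unique_set([two_tile_toxin])
        occurrences = {t.sequence: t.occurrences for t in tiles}
        _, table, _ = self._library_with_medians(two_tile_toxin, 100.0)
        binders = BinderSet("e", frozenset())  # nothing passed the threshold
        effects = alanine_effects(two_tile_toxin, occurrences, table, binders)
        assert np.isnan(effects).all()

    def test_null_pattern_matches_binder_coverage(self, rng):
        """ala_effect is null exactly where no binder tile covers."""
        toxins = random_toxins(rng, 3, lo=20, hi=40)
        library = build_library(toxins, seed=0)
        occurrences = library.occurrence_map()
        medians = {t.sequence: float(rng.uniform(50, 100)) for t in library.unique_wt}
        classes = {}
        for v in library.variants:
            medians.setdefault(v.sequence, 60.0)
            classes.setdefault(v.sequence, "ala")
        table = median_table_from(medians, classes)
        some = rng.choice(
            [t.sequence for t in library.unique_wt], size=5, replace=False
        )
        binders = BinderSet("e", frozenset(some))
        for toxin in toxins:
            effects = alanine_effects(toxin, occurrences, table, binders)
            cov = coverage_counts(toxin, occurrences, binders)
            assert np.array_equal(np.isnan(effects), cov == 0)

    def test_alanine_residues_score_zero_when_covered(self):
        toxin = ToxinRecord(accession="T0", sequence="CDEAGHIKLMNP")
        occurrences, table, tiles = self._library_with_medians(toxin, 400.0)
        binders = BinderSet("e", frozenset(t.sequence for t in tiles))
        effects = alanine_effects(toxin, occurrences, table, binders)
        assert effects[3] == 0.0  # the alanine at residue 4

    def test_nonpositive_median_floored_to_epsilon(self):
        toxin = ToxinRecord(accession="T0", sequence="CDEFGHIKLMNP")
        occurrences, table, tiles = self._library_with_medians(
            toxin, 400.0, knocked={5: 0.0}
        )
        binders = BinderSet("e", frozenset(t.sequence for t in tiles))
        effects = alanine_effects(
            toxin, occurrences, table, binders, epsilon=1.0
        )
        assert effects[4] == pytest.approx(math.log2(1.0 / 400.0))

    def test_orientation_flip(self):
        toxin = ToxinRecord(accession="T0", sequence="CDEFGHIKLMNP")
        occurrences, table, tiles = self._library_with_medians(
            toxin, 400.0, knocked={5: 50.0}
        )
        binders = BinderSet("e", frozenset(t.sequence for t in tiles))
        down = alanine_effects(toxin, occurrences, table, binders)
        up = alanine_effects(
            toxin, occurrences, table, binders, orientation="wt_over_variant"
        )
        assert up[4] == pytest.approx(-down[4])


class TestResidueProfileContainer:
    def test_profile_frame_schema_and_null_encoding(self, rng):
        toxins = random_toxins(rng, 2, lo=20, hi=30)
        library = build_library(toxins, seed=0)
        medians = {t.sequence: 50.0 for t in library.unique_wt}
        classes = {}
        for v in library.variants:
            medians.setdefault(v.sequence, 50.0)
            classes.setdefault(v.sequence, "ala")
        table = median_table_from(medians, classes)
        binders = BinderSet("e1", frozenset())
        rp = compute_residue_profile(toxins[0], library.occurrence_map(), table, binders)
        frame = rp.to_frame()
        assert list(frame["residue_index"]) == list(range(1, len(toxins[0]) + 1))
        assert frame["ala_effect"].isna().all()
        assert (frame["coverage_binder"] == 0).all()
        assert (frame["coverage_wt"] > 0).all()


class TestAlignmentProjection:
    def test_ungapped_alignment_is_identity(self):
        seqs = {"A1": "CDEFGHIKLMNP"}
        values = {"A1": np.arange(12, dtype=float)}
        projection = project_onto_alignment(values, {"A1": seqs["A1"]}, seqs)
        assert np.array_equal(projection.values["A1"], values["A1"])

    def test_gap_cells_carry_no_value(self):
        seqs = {"A1": "CDEFGHIKLMNP"}
        row = "CD-EFGHIKLMNP"
        values = {"A1": np.arange(12, dtype=float)}
        projection = project_onto_alignment(values, {"A1": row}, seqs)
        assert np.isnan(projection.values["A1"][2])
        assert np.array_equal(projection.ungap("A1"), values["A1"])

    def test_row_sequence_mismatch_names_accession(self):
        seqs = {"A1": "CDEFGHIKLMNP"}
        with pytest.raises(ValueError, match="A1"):
            project_onto_alignment(
                {"A1": np.zeros(12)}, {"A1": "CC-EFGHIKLMNP"}, seqs
            )

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_round_trip_random_alignments(self, data):
        """Projecting then ungapping recovers the profile exactly."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        length = data.draw(st.integers(5, 30))
        seq = "".join(rng.choice(list("ACDEFG"), size=length))
        values = rng.uniform(-5, 5, size=length)
        gaps = data.draw(st.lists(st.integers(0, length), max_size=10))
        row = list(seq)
        for g in sorted(gaps, reverse=True):
            row.insert(g, "-")
        projection = project_onto_alignment(
            {"X": values}, {"X": "".join(row)}, {"X": seq}
        )
        assert np.allclose(projection.ungap("X"), values)
        gap_cols = [c for c, ch in enumerate("".join(row)) if ch == "-"]
        assert np.isnan(projection.values["X"][gap_cols]).all()
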