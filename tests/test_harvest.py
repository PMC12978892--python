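"""N-gram candidate generation, filtering, ranking, selection, review."""

import dataclasses
import random

import pytest

from uit.harvest import (
    CandidateTerm,
    HarvestError,
    SelectionConfig,
    export_review_sheet,
    filter_candidates,
    generate_ngrams,
    harvest_and_select,
    import_review_decisions,
    interface_terms,
    rank_candidates,
    select_terms,
)


def freqs(cands):
    return {c.token_surfaces: c.frequency for c in cands}


class TestGenerateNgrams:
    def test_overlapping_windows_counted(self):
        cands = freqs(generate_ngrams([["a", "b", "a", "b"]], n_max=2))
        assert cands[("a", "b")] == 2
        assert cands[("b", "a")] == 1
        assert cands[("a",)] == 2

    def test_windows_never_cross_sequences(self):
        cands = freqs(generate_ngrams([["a"], ["b"]], n_max=2))
        assert ("a", "b") not in cands

    def test_all_lengths_up_to_five_representable(self):
        seq = ["t1", "t2", "t3", "t4", "t5"]
        cands = freqs(generate_ngrams([seq], n_max=5))
        for n in range(1, 6):
            assert tuple(seq[:n]) in cands

    def test_invalid_n_max(self):
        with pytest.raises(HarvestError):
            generate_ngrams([["a"]], n_max=0)

    def test_frequencies_match_planted_counts(self, noise_free_run):
        study, result, expected = noise_free_run
        got = freqs(result.candidates)
        for term in study.planted_terms:
            assert got[term.tokens] >= term.designed_frequency
            assert got[term.tokens] == expected.candidate_freqs[term.tokens]


CFG = SelectionConfig(
    stopwords=frozenset({"of", "the"}),
    prepositions=frozenset({"in"}),
    frequency_cut=300,
)


class TestFilterCandidates:
    def c(self, *toks, freq=10):
        return CandidateTerm(tuple(toks), freq)

    def test_majority_stopwords_filtered(self):
        [out] = filter_candidates([self.c("of", "the")], CFG)
        assert out.filtered_reason == "stopword_fraction"

    def test_interior_preposition_kept(self):
        [out] = filter_candidates([self.c("pain", "in", "chest")], CFG)
        assert out.filtered_reason is None

    def test_boundary_preposition_filtered(self):
        [out] = filter_candidates([self.c("in", "pain")], CFG)
        assert out.filtered_reason == "boundary_preposition"

    def test_boundary_stopword_filtered(self):
        [out] = filter_candidates([self.c("pain", "the")], CFG)
        assert out.filtered_reason == "boundary_stopword"

    def test_majority_numbers_filtered(self):
        [out] = filter_candidates([self.c("3", "days", "10")], CFG)
        assert out.filtered_reason == "punctuation_numbers"

    def test_enlarging_stopword_set_never_unfilters(self):
        cands = [self.c("pain", "in", "chest"), self.c("of", "x"), self.c("a", "b")]
        small = filter_candidates(cands, CFG)
        bigger = dataclasses.replace(
            CFG, stopwords=frozenset({"of", "the", "chest", "b"})
        )
        big = filter_candidates(cands, bigger)
        for s, b in zip(small, big):
            if s.filtered_reason is not None:
                assert b.filtered_reason is not None


class TestRankAndSelect:
    def ranked(self, frequencies):
        cands = [
            CandidateTerm((f"w{i}",), f) for i, f in enumerate(frequencies)
        ]
        return rank_candidates(filter_candidates(cands, CFG))

    def test_single_candidate_rank_and_percentile(self):
        [out] = self.ranked([7])
        assert out.rank_within_n == 1 and out.percentile_within_n == 100.0

    def test_tie_broken_lexicographically(self):
        out = self.ranked([10, 5, 5, 1])
        by_surface = {c.token_surfaces[0]: c.rank_within_n for c in out}
        assert by_surface == {"w0": 1, "w1": 2, "w2": 3, "w3": 4}

    def test_percentiles_increase_with_rank(self):
        rng = random.Random(5)
        out = self.ranked([rng.randint(1, 50) for _ in range(40)])
        out.sort(key=lambda c: c.rank_within_n)
        pcts = [c.percentile_within_n for c in out]
        assert pcts == sorted(pcts) and len(set(pcts)) == len(pcts)

    def test_absolute_frequency_cut_is_inclusive(self):
        c = CandidateTerm(("x",), 300, rank_within_n=99, percentile_within_n=99.0)
        [out] = select_terms([c], CFG)
        assert out.selected

    def test_failing_both_criteria_not_selected(self):
        c = CandidateTerm(("x",), 299, rank_within_n=71, percentile_within_n=71.0)
        [out] = select_terms([c], CFG)
        assert not out.selected

    def test_filtered_candidates_never_selected(self, study_run):
        _, result, _ = study_run
        assert not any(
            c.selected for c in result.candidates if c.filtered_reason is not None
        )

    def test_selection_predicate_holds_for_every_candidate(self, study_run):
        study, result, _ = study_run
        cfg = study.design.selection_config
        for c in result.candidates:
            should = c.filtered_reason is None and (
                c.percentile_within_n <= cfg.percentile_cut
                or c.frequency >= cfg.frequency_cut
            )
            assert c.selected == should

    def test_high_frequency_planted_terms_all_selected(self, noise_free_run):
        study, result, _ = noise_free_run
        cfg = study.design.selection_config
        selected = result.selected
        for term in study.planted_terms:
            if term.designed_frequency >= cfg.frequency_cut:
                assert term.tokens in selected


class TestReviewRoundTrip:
    def make_candidates(self):
        cands = generate_ngrams([["fever", "rash", "fever"]], n_max=2)
        cands = filter_candidates(cands, CFG)
        cands = rank_candidates(cands)
        return select_terms(cands, CFG)

    def test_round_trip_preserves_fields(self, tmp_path):
        cands = self.make_candidates()
        path = tmp_path / "sheet.csv"
        export_review_sheet(cands, path)
        back = import_review_decisions(cands, path)
        assert back == cands

    def test_all_accepted_gives_selected_set(self, tmp_path):
        cands = [
            dataclasses.replace(c, review_status="accepted")
            for c in self.make_candidates()
        ]
        path = tmp_path / "sheet.csv"
        export_review_sheet(cands, path)
        back = import_review_decisions(cands, path)
        assert {c.token_surfaces for c in interface_terms(back)} == {
            c.token_surfaces for c in cands if c.selected
        }

    def test_single_rejection_shrinks_uit_by_one(self, tmp_path):
        cands = [
            dataclasses.replace(c, review_status="accepted")
            for c in self.make_candidates()
        ]
        before = len(interface_terms(cands))
        victim = next(c for c in cands if c.selected)
        cands[cands.index(victim)] = dataclasses.replace(
            victim, review_status="rejected"
        )
        assert len(interface_terms(cands)) == before - 1

    def test_unknown_candidate_decision_is_error(self, tmp_path):
        cands = self.make_candidates()
        path = tmp_path / "sheet.csv"
        export_review_sheet(cands, path)
        with pytest.raises(HarvestError):
            import_review_decisions(cands[:1], path)
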