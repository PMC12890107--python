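"""Mention detection, candidate strategies, counting rules, filters and
reduction to unique ADRs."""

import datetime as dt
import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrmine import miner
from adrmine.miner import (
    MinerConfig,
    apply_counting_rules,
    apply_fp_filters,
    assemble_candidates,
    deduplicate,
    detect_mentions,
    flag_re_adrs,
    mine_corpus,
    reduce_annotations,
    segment,
)


class TestSegment:
    def test_two_sentences(self):
        seg = segment("A. B.")
        assert len(seg.sentences) == 2

    def test_blank_line_splits_paragraphs(self):
        seg = segment("Eerste alinea.\n\nTweede alinea.")
        assert len(seg.paragraphs) == 2

    @given(st.text(max_size=300))
    @settings(max_examples=100, derandomize=True)
    def test_segments_cover_and_reassemble(self, text):
        seg = segment(text)
        for spans in (seg.sentences, seg.paragraphs):
            assert "".join(text[s:e] for s, e in spans) == text
            covered = 0
            for s, e in spans:
                assert s == covered and e > s
                covered = e
            assert covered == len(text)


class TestDetectMentions:
    def test_dutch_diacritics_sentence(self, lex, make_note):
        note = make_note("Hyponatriëmie door hydrochloorthiazide en ondervoeding.")
        mentions = detect_mentions(note, lex)
        kinds = {(m.kind, m.resolved_id) for m in mentions}
        assert ("adr_term", "T_HYPONAT") in kinds
        assert ("drug", "D_HCTZ") in kinds

    def test_no_lexicon_hits_is_empty(self, lex, make_note):
        assert detect_mentions(make_note("De brug over de rivier."), lex) == []

    def test_offsets_are_exact(self, lex, make_note):
        text = "Verder rustig. Misselijkheid door morfine. Einde."
        note = make_note(text)
        for m in detect_mentions(note, lex):
            assert text[m.start : m.end] == m.surface

    def test_longest_surface_wins(self, lex, make_note):
        note = make_note("Lage bloeddruk gemeten.")
        (m,) = [m for m in detect_mentions(note, lex) if m.kind == "adr_term"]
        assert m.resolved_id == "T_HYPOTENS"
        assert note.text[m.start : m.end] == "Lage bloeddruk"

    def test_planted_offsets_recovered(self, small_corpus, lex):
        notes, ledger, _ = small_corpus
        by_id = {n.note_id: n for n in notes}
        checked = 0
        for plant in ledger.plants[:25]:
            note = by_id[plant.note_id]
            mentions = detect_mentions(note, lex)
            spans = {(m.start, m.end) for m in mentions}
            assert tuple(plant.drug_span) in spans
            if plant.term_span is not None:
                assert tuple(plant.term_span) in spans
            checked += 1
        assert checked


class TestAssembleCandidates:
    def _candidates(self, lex, note, config=None):
        return assemble_candidates(detect_mentions(note, lex), note, lex, config)

    def test_causal_trigger_sentence(self, lex, make_note):
        note = make_note("Misselijk door morfine.")
        cands = self._candidates(lex, note)
        assert len(cands) == 1
        c = cands[0]
        assert c.ingredient_ids == ("D_MORF",)
        assert c.term_code == "T_NAUSEA"
        assert c.strategy in ("S1", "S2")

    def test_separate_paragraphs_without_trigger_do_not_fire(self, lex, make_note):
        note = make_note("Patient gebruikt morfine.\n\nVandaag misselijkheid gemeld.")
        assert self._candidates(lex, note) == []

    def test_allergy_label_yields_hypersensitivity_code(self, lex, make_note):
        note = make_note("Allergie: penicilline.")
        (c,) = self._candidates(lex, note)
        assert c.strategy == "S4"
        assert c.term_code == "T_HYPERSENS"
        assert c.ingredient_ids == ("D_PEN",)

    def test_cross_sentence_association_within_window(self, lex, make_note):
        note = make_note("Morfine gestart. Daarna veel duizeligheid, vermoedelijk door opname.")
        cands = self._candidates(lex, note)
        assert {c.term_code for c in cands} == {"T_DIZZ"}

    def test_disabling_all_strategies_yields_nothing(self, lex, make_note):
        note = make_note("Misselijk door morfine.")
        config = MinerConfig(s1=False, s2=False, s3=False, s4=False, s5=False)
        assert self._candidates(lex, note, config) == []

    def test_discontinuation_strategy(self, lex, make_note):
        note = make_note("Haloperidol gestaakt.\n\nSufheid verdwenen daarna.")
        config = MinerConfig(s1=True, s2=True, s3=True, s4=True, s5=True)
        # term and drug in *different* paragraphs: S5 must not fire
        assert self._candidates(lex, note, config) == []
        note2 = make_note("Haloperidol gestaakt wegens sufheid.")
        cands = self._candidates(lex, note2, config)
        assert len(cands) == 1 and cands[0].term_code == "T_SOMNOL"


class TestCountingRules:
    def test_two_symptoms_one_drug_counts_twice(self, lex, make_note):
        note = make_note("Misselijkheid en obstipatie door opiaten.")
        cands = assemble_candidates(detect_mentions(note, lex), note, lex)
        assert len(cands) == 1
        expanded = apply_counting_rules(cands[0], lex.terms)
        assert {(c.ingredient_ids, c.term_code) for c in expanded} == {
            (("G_OPI",), "T_NAUSEA"),
            (("G_OPI",), "T_CONSTIP"),
        }

    def test_combination_drug_counts_once(self, lex, make_note):
        note = make_note("Lage bloeddruk door metoprolol/ hydrochloorthiazide.")
        cands = assemble_candidates(detect_mentions(note, lex), note, lex)
        assert len(cands) == 1
        (c,) = apply_counting_rules(cands[0], lex.terms)
        assert set(c.ingredient_ids) == {"D_METO", "D_HCTZ"}
        assert c.term_code == "T_HYPOTENS"

    def test_single_symptom_is_identity(self, lex, make_note):
        note = make_note("Duizeligheid door metoprolol.")
        (cand,) = assemble_candidates(detect_mentions(note, lex), note, lex)
        assert apply_counting_rules(cand, lex.terms) == [cand]


class TestFpFilters:
    def _mine_one(self, lex, note, **filters):
        cands = assemble_candidates(detect_mentions(note, lex), note, lex)
        expanded = []
        for c in cands:
            expanded.extend(apply_counting_rules(c, lex.terms))
        return apply_fp_filters(
            expanded,
            {"refusal": False, "switch": False, "indication": False, **filters},
            triggers=lex.triggers,
            indications=lex.indications,
            drugs=lex.drugs,
        )

    def test_refusal_filter_drops_refusal_context(self, lex, make_note):
        note = make_note("Patient weigert oxycodon vanwege misselijkheid.")
        kept, rejected = self._mine_one(lex, note, refusal=True)
        assert kept == [] and [r.reason for r in rejected] == ["refusal"]

    def test_refusal_kept_when_filter_off(self, lex, make_note):
        note = make_note("Patient weigert oxycodon vanwege misselijkheid.")
        kept, rejected = self._mine_one(lex, note)
        assert len(kept) == 1 and rejected == []

    def test_switch_filter_drops_substitution_pattern(self, lex, make_note):
        note = make_note("Morfine omgezet naar een alternatief vanwege obstipatie.")
        kept, rejected = self._mine_one(lex, note, switch=True)
        assert kept == [] and rejected[0].reason == "switch"

    def test_indication_filter_drops_treated_indication(self, lex, make_note):
        note = make_note("Haloperidol gegeven voor delier.")
        kept, rejected = self._mine_one(lex, note, indication=True)
        assert kept == [] and rejected[0].reason == "indication"
        kept_off, _ = self._mine_one(lex, note)
        assert len(kept_off) == 1

    def test_unknown_flag_is_hard_error(self, lex):
        with pytest.raises(ValueError, match="unknown filter flags"):
            apply_fp_filters([], {"negation": True})

    def test_conservation(self, lex, make_note):
        notes_text = [
            "Patient weigert oxycodon vanwege misselijkheid.",
            "Haloperidol gegeven voor delier.",
            "Duizeligheid door metoprolol.",
        ]
        cands = []
        for t in notes_text:
            note = make_note(t)
            cands.extend(assemble_candidates(detect_mentions(note, lex), note, lex))
        kept, rejected = apply_fp_filters(
            cands,
            {"refusal": True, "switch": True, "indication": True},
            triggers=lex.triggers,
            indications=lex.indications,
            drugs=lex.drugs,
        )
        assert len(kept) + len(rejected) == len(cands)


class TestDeduplicate:
    def _candidate(self, lex, make_note, text, patient="P1", date=dt.date(2023, 6, 1)):
        note = make_note(text, patient_id=patient, date=date)
        (c,) = assemble_candidates(detect_mentions(note, lex), note, lex)
        return c

    def test_first_date_kept_and_count_reported(self, lex, make_note):
        c1 = self._candidate(lex, make_note, "Misselijk door morfine.", date=dt.date(2023, 6, 5))
        c2 = self._candidate(lex, make_note, "Misselijkheid door morfine.", date=dt.date(2023, 6, 1))
        uniques, n_dup, occ, audit = deduplicate([c1, c2])
        assert len(uniques) == 1 and n_dup == 1
        assert uniques[0].first_date == dt.date(2023, 6, 1)
        assert audit[uniques[0].key] == [0, 1]

    def test_empty_and_idempotent(self, lex, make_note):
        assert deduplicate([])[0] == []
        c = self._candidate(lex, make_note, "Misselijk door morfine.")
        uniques, n_dup, _, _ = deduplicate([c, c, c])
        assert len(uniques) == 1 and n_dup == 2


class TestFlagReAdrs:
    def _setup(self, lex, make_note, second_day, with_represcription):
        notes = [
            make_note("Misselijk door morfine.", date=dt.date(2023, 1, 1)),
            make_note(
                "Morfine herstart." if with_represcription else "Rustige dag.",
                date=dt.date(2023, 2, 1),
            ),
            make_note("Misselijk door morfine.", date=second_day),
        ]
        cands = []
        for n in notes:
            cands.extend(assemble_candidates(detect_mentions(n, lex), n, lex))
        uniques, _, occ, _ = deduplicate(cands)
        events = flag_re_adrs(uniques, occ, notes, lex.drugs, gap_days=30)
        return uniques, events

    def test_two_episodes_with_represcription_flagged(self, lex, make_note):
        uniques, events = self._setup(lex, make_note, dt.date(2023, 4, 1), True)
        assert uniques[0].re_adr is True
        assert len(events) == 1 and events[0].date == dt.date(2023, 4, 1)

    def test_same_day_repeat_is_duplicate_not_re_adr(self, lex, make_note):
        uniques, events = self._setup(lex, make_note, dt.date(2023, 1, 1), True)
        assert uniques[0].re_adr is False and events == []

    def test_no_represcription_signal_not_flagged(self, lex, make_note):
        uniques, events = self._setup(lex, make_note, dt.date(2023, 4, 1), False)
        assert uniques[0].re_adr is False and events == []


class TestReduceAnnotations:
    def test_duplicates_and_recurrences_partition_input(self, lex):
        from adrmine.synthdata import generate_annotation_ledger

        records = generate_annotation_ledger(
            n_unique=50, n_duplicates=20, n_re_adrs=7, seed=5, n_patients=10,
            lexicons=lex,
        )
        red = reduce_annotations(records)
        assert (len(red.unique), len(red.duplicates), len(red.re_adrs)) == (50, 20, 7)
        assert len(red.unique) + len(red.duplicates) + len(red.re_adrs) == len(records)


class TestMineCorpus:
    def test_planted_gold_recovered_exactly(self, lex, small_corpus):
        notes, ledger, _ = small_corpus
        result = mine_corpus(notes, lex)
        mined = {u.key for u in result.unique}
        assert ledger.plant_keys() <= mined
        assert mined <= ledger.plant_keys() | ledger.confounder_keys()

    def test_non_medical_corpus_yields_nothing(self, lex, make_note):
        notes = [make_note("Vandaag rustige controle. Geen bijzonderheden gezien.")]
        assert mine_corpus(notes, lex).unique == []

    def test_doubling_corpus_leaves_unique_set_unchanged(self, lex, make_note):
        notes = [
            make_note("Misselijk door morfine."),
            make_note("Duizeligheid door metoprolol."),
        ]
        doubled = notes + [
            make_note(n.text, patient_id=n.patient_id, date=n.timestamp) for n in notes
        ]
        keys = lambda res: sorted(u.key for u in res.unique)  # noqa: E731
        assert keys(mine_corpus(notes, lex)) == keys(mine_corpus(doubled, lex))

    def test_determinism_byte_identical(self, lex, small_corpus):
        notes, _, _ = small_corpus
        def run():
            res = mine_corpus(notes, lex)
            return json.dumps(
                [[u.patient_id, list(u.ingredient_ids), u.term_code,
                  u.first_date.isoformat(), u.serious, u.re_adr] for u in res.unique]
            )
        assert run() == run()

    def test_audit_links_every_unique_to_candidates(self, lex, small_corpus):
        notes, _, _ = small_corpus
        res = mine_corpus(notes, lex)
        for u in res.unique:
            idxs = res.audit[u.key]
            assert idxs and all(
                res.kept[i].patient_id == u.patient_id for i in idxs
            )

    def test_filter_monotonicity(self, lex, small_corpus):
        notes, _, _ = small_corpus
        base = len(mine_corpus(notes, lex).unique)
        for flag in ("filter_refusal", "filter_switch", "filter_indication"):
            config = MinerConfig(**{flag: True})
            assert len(mine_corpus(notes, lex, config).unique) <= base
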