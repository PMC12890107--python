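"""Matching, confusion metrics, strata, agreement statistics and the
portability comparison."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adrmine import evaluation
from adrmine.evaluation import (
    EvalReport,
    UndefinedMetricError,
    cohen_kappa,
    compare_groups,
    f_score,
    gold_subset_report,
    match,
    missed_by_manual,
    percent,
    portability_check,
    ppv,
    report,
    round2,
    sensitivity,
    stratified_report,
)
from adrmine.lexicons import DrugEntry, DrugLexicon
from adrmine.miner import UniqueADR


def adr(patient="P1", drugs=("D1",), term="T1", day=1, serious=False, score=None):
    return UniqueADR(
        patient_id=patient,
        ingredient_ids=tuple(sorted(drugs)),
        term_code=term,
        first_date=dt.date(2023, 1, day),
        serious=serious,
        naranjo_score=score,
    )


@pytest.fixture(scope="module")
def toy_drugs():
    """Four specific drugs; G1 groups D1 and D2."""
    return DrugLexicon(
        [
            DrugEntry("D1", "alfadrug", group_names=("groupone",)),
            DrugEntry("D2", "betadrug", group_names=("groupone",)),
            DrugEntry("D3", "gammadrug"),
            DrugEntry("D4", "deltadrug"),
            DrugEntry("G1", "groupone", is_group=True),
        ]
    )


class TestMatch:
    def test_identical_sets_fully_matched(self):
        gold = [adr(term="T1"), adr(term="T2")]
        pred = [adr(term="T1"), adr(term="T2")]
        m = match(gold, pred)
        assert len(m.pairs) == 2 and not m.unmatched_gold and not m.unmatched_pred

    def test_synonym_normalized_term_codes_match(self, lex):
        # hives and urticaria resolve to one code at lookup time, so the
        # unique-ADR records compare equal on term_code
        hives = lex.terms.lookup("hives").term_code
        urticaria = lex.terms.lookup("urticaria").term_code
        gold = [adr(drugs=("D_PEN",), term=urticaria)]
        pred = [adr(drugs=("D_PEN",), term=hives)]
        assert len(match(gold, pred, lex.drugs).pairs) == 1

    def test_drug_mismatch_is_unmatched(self):
        m = match([adr(drugs=("D1",))], [adr(drugs=("D4",))])
        assert not m.pairs and len(m.unmatched_gold) == len(m.unmatched_pred) == 1

    def test_group_attribution_is_compatible_with_member(self, toy_drugs):
        m = match([adr(drugs=("G1",))], [adr(drugs=("D2",))], toy_drugs)
        assert len(m.pairs) == 1

    def test_group_record_not_starved_by_exact_competitor(self, toy_drugs):
        # G1 is compatible with both predictions; D2 only with one of them:
        # a maximal matching pairs both
        gold = [adr(drugs=("G1",)), adr(drugs=("D2",))]
        pred = [adr(drugs=("D1",)), adr(drugs=("D2",))]
        m = match(gold, pred, toy_drugs)
        assert len(m.pairs) == 2

    def test_exact_match_preferred_over_group(self, toy_drugs):
        gold = [adr(drugs=("D1",))]
        pred = [adr(drugs=("G1",)), adr(drugs=("D1",))]
        m = match(gold, pred, toy_drugs)
        assert m.pairs[0][1].ingredient_ids == ("D1",)

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate unique-ADR keys"):
            match([adr(), adr()], [])

    def test_agrees_with_exhaustive_search_on_small_instances(self, toy_drugs):
        drug_sets = [("D1",), ("D2",), ("D3",), ("D4",), ("G1",), ("D1", "D2")]
        terms = ["T1", "T2"]
        rng = np.random.default_rng(2024)

        def compatible(g, p):
            return bool(
                evaluation._expand(g.ingredient_ids, toy_drugs)
                & evaluation._expand(p.ingredient_ids, toy_drugs)
            ) and g.term_code == p.term_code and g.patient_id == p.patient_id

        def brute_force(gold, pred):
            best = 0

            def rec(i, used, count):
                nonlocal best
                best = max(best, count)
                if i == len(gold):
                    return
                rec(i + 1, used, count)
                for j, p in enumerate(pred):
                    if j not in used and compatible(gold[i], p):
                        rec(i + 1, used | {j}, count + 1)

            rec(0, frozenset(), 0)
            return best

        for _ in range(60):
            def sample(n):
                keys = set()
                records = []
                while len(records) < n:
                    key = (
                        drug_sets[rng.integers(len(drug_sets))],
                        terms[rng.integers(len(terms))],
                    )
                    if key in keys:
                        continue
                    keys.add(key)
                    records.append(adr(drugs=key[0], term=key[1], day=int(rng.integers(1, 28))))
                return records

            gold = sample(int(rng.integers(0, 9)))
            pred = sample(int(rng.integers(0, 9)))
            assert len(match(gold, pred, toy_drugs).pairs) == brute_force(gold, pred)


class TestMetrics:
    def test_published_style_fractions(self):
        assert percent(sensitivity(286, 73)) == 80
        assert percent(ppv(286, 248)) == 54
        assert round2(f_score(sensitivity(286, 73), ppv(286, 248))) == 0.64

    def test_zero_numerator(self):
        assert sensitivity(0, 5) == 0.0 and percent(sensitivity(0, 5)) == 0

    def test_zero_denominator_is_explicit(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(0, 0)
        with pytest.raises(UndefinedMetricError):
            ppv(0, 0)

    @pytest.mark.parametrize(
        "s,p,expected", [(1.0, 1.0, 1.0), (1.0, 0.5, 2 / 3), (0.0, 0.0, 0.0)]
    )
    def test_f_score_closed_forms(self, s, p, expected):
        assert f_score(s, p) == pytest.approx(expected)

    def test_percent_rounds_half_up(self):
        assert percent(0.535) == 54
        assert percent(0.625) == 63  # bankers' rounding would give 62
        assert round2(0.645) == 0.65

    @pytest.mark.parametrize("f,ok", [(0.64, True), (0.60, False), (1.0, True)])
    def test_portability_threshold_is_strict(self, f, ok):
        assert portability_check(f) is ok

    def test_report_symmetry(self):
        gold = [adr(term=f"T{i}") for i in range(6)]
        pred = [adr(term=f"T{i}") for i in range(3, 11)]
        fwd = report(match(gold, pred))
        rev = report(match(pred, gold))
        assert fwd.sensitivity == rev.ppv and fwd.ppv == rev.sensitivity
        assert fwd.f_score == pytest.approx(rev.f_score)

    def test_f_between_sensitivity_and_ppv(self):
        rep = report(match([adr(term=f"T{i}") for i in range(6)],
                           [adr(term=f"T{i}") for i in range(3, 11)]))
        assert min(rep.sensitivity, rep.ppv) <= rep.f_score <= max(rep.sensitivity, rep.ppv)


class TestStratifiedReport:
    def _sets(self):
        gold, pred = [], []
        for pid, tp, fp, fn in [("P1", 3, 2, 1), ("P2", 2, 0, 2), ("P3", 0, 3, 0)]:
            for i in range(tp):
                gold.append(adr(patient=pid, term=f"T{pid}s{i}"))
                pred.append(adr(patient=pid, term=f"T{pid}s{i}"))
            for i in range(fp):
                pred.append(adr(patient=pid, term=f"T{pid}p{i}"))
            for i in range(fn):
                gold.append(adr(patient=pid, term=f"T{pid}g{i}"))
        return gold, pred

    def test_strata_counts_sum_to_overall(self):
        gold, pred = self._sets()
        rep = stratified_report(gold, pred, {"P1": "A", "P2": "A", "P3": "B"})
        for i in range(3):
            assert sum(r.venn[i] for r in rep.strata.values()) == rep.venn[i]
        assert rep.venn == (5, 5, 3)

    def test_single_stratum_equals_overall(self):
        gold, pred = self._sets()
        rep = stratified_report(gold, pred, lambda pid: "all")
        assert rep.strata["all"].venn == rep.venn

    def test_unlabelled_patient_is_hard_error(self):
        gold, pred = self._sets()
        with pytest.raises(ValueError, match="no stratum label"):
            stratified_report(gold, pred, {"P1": "A"})

    def test_conservation_under_random_partition(self):
        gold, pred = self._sets()
        rng = np.random.default_rng(7)
        for _ in range(10):
            labels = {p: f"S{rng.integers(3)}" for p in ("P1", "P2", "P3")}
            rep = stratified_report(gold, pred, labels)
            assert rep.tp + rep.fn == len(gold)
            assert rep.tp + rep.fp == len(pred)
            for i in range(3):
                assert sum(r.venn[i] for r in rep.strata.values()) == rep.venn[i]


class TestAgreementStatistics:
    def test_perfect_agreement_kappa_is_one(self):
        assert cohen_kappa([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_kappa_matches_direct_formula_and_reference_implementation(self):
        table = np.array([[10, 5], [5, 10]], dtype=float)
        n = table.sum()
        p_o = np.trace(table) / n
        p_e = sum(table.sum(0)[k] * table.sum(1)[k] for k in range(2)) / n**2
        expected = (p_o - p_e) / (1 - p_e)
        assert cohen_kappa(table) == pytest.approx(expected, abs=1e-12)
        sklearn = pytest.importorskip("sklearn.metrics")
        a = [0] * 15 + [1] * 15
        b = [0] * 10 + [1] * 5 + [0] * 5 + [1] * 10
        assert cohen_kappa(table) == pytest.approx(
            sklearn.cohen_kappa_score(a, b), abs=1e-12
        )

    def test_chance_level_agreement_is_zero(self):
        assert cohen_kappa([[4, 6], [4, 6]]) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_marginals_are_explicit(self):
        with pytest.raises(UndefinedMetricError):
            cohen_kappa([[5, 0], [0, 0]])


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([60.0, 70.0, 80.0], [60.0, 70.0, 80.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(70, 15, size=14)
        b = rng.normal(62, 15, size=16)
        res = compare_groups(a, b, tails=2)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_expected = 2 * stats.t.sf(abs(t_expected), na + nb - 2)
        assert res.t == pytest.approx(t_expected, abs=1e-12)
        assert res.p == pytest.approx(p_expected, abs=1e-12)
        tcrit = stats.t.ppf(0.975, na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.ci_low == pytest.approx(a.mean() - b.mean() - tcrit * se, abs=1e-12)

    def test_one_tailed_is_half_two_tailed_in_hypothesized_direction(self):
        a = [75.0, 80.0, 70.0, 85.0]
        b = [60.0, 65.0, 55.0, 62.0]
        two = compare_groups(a, b, tails=2)
        one = compare_groups(a, b, tails=1)
        assert two.t > 0
        assert one.p == pytest.approx(two.p / 2, abs=1e-12)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups([1.0], [2.0, 3.0])


class TestDiscrepancyTriage:
    def test_scores_filter_discrepancies(self):
        gold = [adr(term=f"T{i}") for i in range(3)]
        pred = [adr(term=f"T{i}") for i in range(3)] + [
            adr(term=f"X{i}", score=(2 if i < 4 else 0), serious=(i < 2))
            for i in range(10)
        ]
        m = match(gold, pred)
        triage = missed_by_manual(m)
        assert len(triage.records) == 4 and triage.n_serious == 2

    def test_all_zero_scores_yield_empty(self):
        pred = [adr(term=f"X{i}", score=0) for i in range(5)]
        triage = missed_by_manual(match([], pred))
        assert triage.records == [] and triage.n_serious == 0

    def test_serious_subset_report(self):
        gold = [adr(term=f"T{i}", serious=i < 4) for i in range(10)]
        pred = [adr(term=f"T{i}") for i in range(7)]
        rep = gold_subset_report(match(gold, pred), lambda g: g.serious)
        assert (rep.tp, rep.fn) == (4, 0)
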