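"""Comparison of two unique-ADR sets (reference/"gold" vs predicted):
one-to-one matching, confusion counts, sensitivity / PPV / F-score,
stratified reports and Venn triples, inter-annotator agreement (Cohen's
kappa) and the unpaired t-test used for portability comparisons.

Concordance is defined at the unique-ADR key: a gold and a predicted record
match when they refer to the same patient, the same coded reaction term
(synonyms collapse to one code at lookup time, so "hives" and "urticaria"
compare equal) and a compatible drug attribution (same ingredient, or a
drug group containing the other's ingredient). Matching is one-to-one and
of maximum cardinality; among maximum matchings, exact ingredient
agreement is preferred, then the earliest predicted date, then input order.

All chained computations use unrounded proportions; percent rounding is
half-up and applied only at presentation.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from adrmine.lexicons import DrugLexicon
from adrmine.miner import UniqueADR

__all__ = [
    "UndefinedMetricError",
    "Matching",
    "EvalReport",
    "match",
    "report",
    "stratified_report",
    "gold_subset_report",
    "sensitivity",
    "ppv",
    "f_score",
    "percent",
    "portability_check",
    "cohen_kappa",
    "compare_groups",
    "TTestResult",
    "missed_by_manual",
    "MissedByManual",
    "PORTABILITY_THRESHOLD",
]

PORTABILITY_THRESHOLD = 0.6


class UndefinedMetricError(ZeroDivisionError):
    """A proportion with an empty denominator; never silently zero."""


# ---------------------------------------------------------------------------
# matching


@dataclass
class Matching:
    pairs: list[tuple[UniqueADR, UniqueADR]]
    unmatched_gold: list[UniqueADR]
    unmatched_pred: list[UniqueADR]


def _expand(ids: tuple[str, ...], drugs: DrugLexicon | None) -> frozenset[str]:
    if drugs is None:
        return frozenset(ids)
    out: set[str] = set()
    for iid in ids:
        out |= drugs.expand(iid)
    return frozenset(out)


def _compatible(g: UniqueADR, p: UniqueADR, drugs: DrugLexicon | None) -> bool:
    return bool(_expand(g.ingredient_ids, drugs) & _expand(p.ingredient_ids, drugs))


def match(
    gold: Sequence[UniqueADR],
    predicted: Sequence[UniqueADR],
    drugs: DrugLexicon | None = None,
) -> Matching:
    """One-to-one matching of gold vs predicted unique ADRs.

    Solved as an optimal assignment per (patient, term code) block so the
    number of matched pairs is always maximal (a purely greedy pass can
    strand a group-level attribution on the wrong specific drug). Inputs
    must already be unique: duplicate keys within one input are an error.
    """
    for name, records in (("gold", gold), ("predicted", predicted)):
        keys = [r.key for r in records]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate unique-ADR keys in {name} input: {dupes[:3]}")

    blocks: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
    for i, g in enumerate(gold):
        blocks.setdefault((g.patient_id, g.term_code), ([], []))[0].append(i)
    for j, p in enumerate(predicted):
        blocks.setdefault((p.patient_id, p.term_code), ([], []))[1].append(j)

    matched_gold: set[int] = set()
    matched_pred: set[int] = set()
    pair_idx: list[tuple[int, int]] = []
    for gi, pj in blocks.values():
        if not gi or not pj:
            continue
        # preference ranks for predicted records: earliest date, then input order
        pred_rank = {
            j: r
            for r, j in enumerate(sorted(pj, key=lambda j: (predicted[j].first_date, j)))
        }
        reward = np.zeros((len(gi), len(pj)))
        for a, i in enumerate(gi):
            for b, j in enumerate(pj):
                if not _compatible(gold[i], predicted[j], drugs):
                    continue
                exact = tuple(sorted(set(gold[i].ingredient_ids))) == tuple(
                    sorted(set(predicted[j].ingredient_ids))
                )
                reward[a, b] = 1e6 + (1e4 if exact else 0.0) + (len(pj) - pred_rank[j])
        rows, cols = optimize.linear_sum_assignment(reward, maximize=True)
        for a, b in zip(rows, cols):
            if reward[a, b] > 0:
                pair_idx.append((gi[a], pj[b]))
                matched_gold.add(gi[a])
                matched_pred.add(pj[b])

    pair_idx.sort()
    return Matching(
        pairs=[(gold[i], predicted[j]) for i, j in pair_idx],
        unmatched_gold=[g for i, g in enumerate(gold) if i not in matched_gold],
        unmatched_pred=[p for j, p in enumerate(predicted) if j not in matched_pred],
    )


# ---------------------------------------------------------------------------
# metrics


def sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN); empty gold set is an explicit error."""
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no gold records")
    return tp / (tp + fn)


def ppv(tp: int, fp: int) -> float:
    """TP / (TP + FP); empty prediction set is an explicit error."""
    if tp + fp == 0:
        raise UndefinedMetricError("PPV undefined: no predicted records")
    return tp / (tp + fp)


def f_score(sens: float, prec: float) -> float:
    """Harmonic mean of unrounded sensitivity and PPV.

    The degenerate s = p = 0 case is defined as 0 (flagged by callers that
    build reports)."""
    if sens == 0.0 and prec == 0.0:
        return 0.0
    return 2 * sens * prec / (sens + prec)


def percent(value: float) -> int:
    """Integer percent, rounded half-up (presentation only)."""
    return int(Decimal(str(value * 100)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def round2(value: float) -> float:
    return float(Decimal(str(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def portability_check(f: float) -> bool:
    """Acceptable portability iff the F-score is strictly above 0.6."""
    return f > PORTABILITY_THRESHOLD


@dataclass
class EvalReport:
    """Confusion counts plus derived metrics for one comparison.

    ``venn`` is the (concordant, algorithm-only, manual-only) triple, i.e.
    (tp, fp, fn). Metrics are ``None`` when their denominator is empty.
    """

    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    ppv: float | None
    f_score: float | None
    f_zero_warning: bool = False
    strata: dict[str, "EvalReport"] = field(default_factory=dict)

    @property
    def venn(self) -> tuple[int, int, int]:
        return (self.tp, self.fp, self.fn)

    @property
    def n_gold(self) -> int:
        return self.tp + self.fn

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "f_score": self.f_score,
            "sensitivity_percent": percent(self.sensitivity)
            if self.sensitivity is not None
            else None,
            "ppv_percent": percent(self.ppv) if self.ppv is not None else None,
            "f_score_2dp": round2(self.f_score) if self.f_score is not None else None,
            "venn": list(self.venn),
        }
        if self.strata:
            d["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return d


def _build_report(tp: int, fp: int, fn: int) -> EvalReport:
    try:
        sens = sensitivity(tp, fn)
    except UndefinedMetricError:
        sens = None
    try:
        prec = ppv(tp, fp)
    except UndefinedMetricError:
        prec = None
    if sens is None or prec is None:
        f = None
        warn = False
    else:
        f = f_score(sens, prec)
        warn = sens == 0.0 and prec == 0.0
    return EvalReport(tp=tp, fp=fp, fn=fn, sensitivity=sens, ppv=prec,
                      f_score=f, f_zero_warning=warn)


def report(matching: Matching) -> EvalReport:
    return _build_report(
        tp=len(matching.pairs),
        fp=len(matching.unmatched_pred),
        fn=len(matching.unmatched_gold),
    )


def stratified_report(
    gold: Sequence[UniqueADR],
    predicted: Sequence[UniqueADR],
    strata_of: Callable[[str], str] | Mapping[str, str],
    drugs: DrugLexicon | None = None,
) -> EvalReport:
    """Overall report plus one nested report per patient stratum.

    Every patient must be labelled; stratum confusion counts sum to the
    overall counts because matching never crosses patients.
    """
    lookup = strata_of if callable(strata_of) else dict(strata_of).__getitem__
    labels: dict[str, str] = {}
    for rec in list(gold) + list(predicted):
        if rec.patient_id not in labels:
            try:
                labels[rec.patient_id] = lookup(rec.patient_id)
            except KeyError as exc:
                raise ValueError(f"patient {rec.patient_id!r} has no stratum label") from exc
    overall_match = match(gold, predicted, drugs)
    overall = report(overall_match)
    strata_counts: dict[str, list[int]] = {}
    for g, _ in overall_match.pairs:
        strata_counts.setdefault(labels[g.patient_id], [0, 0, 0])[0] += 1
    for p in overall_match.unmatched_pred:
        strata_counts.setdefault(labels[p.patient_id], [0, 0, 0])[1] += 1
    for g in overall_match.unmatched_gold:
        strata_counts.setdefault(labels[g.patient_id], [0, 0, 0])[2] += 1
    overall.strata = {
        label: _build_report(tp, fp, fn)
        for label, (tp, fp, fn) in sorted(strata_counts.items())
    }
    return overall


def gold_subset_report(
    matching: Matching, predicate: Callable[[UniqueADR], bool]
) -> EvalReport:
    """Report restricted to the gold records satisfying ``predicate`` (e.g.
    the serious stratum): tp counts matched such gold records, fn unmatched
    ones; fp is 0 by construction (predicted-only records have no gold
    attribute to restrict on)."""
    tp = sum(1 for g, _ in matching.pairs if predicate(g))
    fn = sum(1 for g in matching.unmatched_gold if predicate(g))
    return _build_report(tp=tp, fp=0, fn=fn)


# ---------------------------------------------------------------------------
# agreement and group comparison


def cohen_kappa(table: Sequence[Sequence[float]]) -> float:
    """Cohen's kappa from a square agreement table of two assessors.

    kappa = (p_o - p_e) / (1 - p_e); chance agreement of 1 (degenerate
    marginals) is an explicit error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("agreement table must be square")
    n = arr.sum()
    if n == 0:
        raise UndefinedMetricError("kappa undefined: empty table")
    p_o = np.trace(arr) / n
    p_e = float((arr.sum(axis=0) * arr.sum(axis=1)).sum()) / n**2
    if math.isclose(p_e, 1.0):
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1 - p_e)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    ci_low: float
    ci_high: float
    tails: int


def compare_groups(
    a: Sequence[float], b: Sequence[float], tails: int = 2
) -> TTestResult:
    """Unpaired two-sample t-test (equal variances) of per-patient scores.

    ``tails=1`` tests the directional hypothesis mean(a) > mean(b); the
    95% confidence interval of the mean difference is always two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    alternative = "greater" if tails == 1 else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    df = len(a) + len(b) - 2
    sp2 = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / df
    se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    diff = a.mean() - b.mean()
    tcrit = stats.t.ppf(0.975, df)
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=float(df),
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        tails=tails,
    )


# ---------------------------------------------------------------------------
# discrepancy triage


@dataclass
class MissedByManual:
    """Algorithm-only records that score possible or better on causality —
    candidate ADRs the reference review overlooked."""

    records: list[UniqueADR]
    n_serious: int


def missed_by_manual(
    matching: Matching,
    naranjo_scores: Mapping[tuple, int] | None = None,
) -> MissedByManual:
    """Filter the algorithm-only discrepancies to those with a Naranjo
    score >= 1; ``naranjo_scores`` (key -> score) overrides scores carried
    on the records themselves."""
    records = []
    for rec in matching.unmatched_pred:
        s = rec.naranjo_score
        if naranjo_scores is not None and rec.key in naranjo_scores:
            s = naranjo_scores[rec.key]
        if s is not None and s >= 1:
            records.append(rec)
    return MissedByManual(
        records=records, n_serious=sum(1 for r in records if r.serious)
    )
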