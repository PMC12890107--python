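"""The text-mining algorithm: dictionary-based mention detection, proximity
strategies that assemble candidate drug-reaction pairs, counting rules,
optional false-positive filters, and reduction to unique ADRs per patient.

Candidate assembly uses five switchable strategies:

S1  drug and reaction term in the same sentence;
S2  causal trigger with a drug and a reaction term both within the proximity
    window (same sentence, else at most ``proximity_window`` characters away
    inside the paragraph);
S3  reaction term plus causal trigger within the window, drug resolved from
    the nearest preceding drug mention in the same paragraph;
S4  allergy label adjacent to a drug; a nearby reaction term supplies the
    code, otherwise the unspecified-hypersensitivity code is assigned;
S5  discontinuation trigger together with a drug and a reaction term in the
    same paragraph.

No general negation detection is performed: only the three named
false-positive filters exist (drug-indication exclusion, drug-switch rule,
patient-refusal filter), all off by default.

Character offsets are 0-based, half-open throughout.
"""

from __future__ import annotations

import datetime as dt
import re
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from adrmine.corpus_io import AnnotationRecord, Note
from adrmine.lexicons import AdrTermIndex, DrugLexicon, Lexicons, TriggerLexicon, fold

__all__ = [
    "MinerConfig",
    "Mention",
    "CandidateADR",
    "UniqueADR",
    "Segmentation",
    "segment",
    "detect_mentions",
    "assemble_candidates",
    "apply_counting_rules",
    "apply_fp_filters",
    "deduplicate",
    "flag_re_adrs",
    "reduce_annotations",
    "AnnotationReduction",
    "mine_corpus",
    "MiningResult",
    "ReAdrEvent",
    "DEFAULT_SWITCH_PATTERNS",
    "FILTER_NAMES",
]

DEFAULT_SWITCH_PATTERNS = (
    "omgezet naar",
    "vervangen door",
    "gewisseld naar",
    "overgestapt op",
    "switched to",
    "replaced by",
)

FILTER_NAMES = ("refusal", "switch", "indication")


@dataclass
class MinerConfig:
    """Tunables of the mining algorithm; defaults match the validated
    configuration (all strategies on, all false-positive filters off)."""

    s1: bool = True
    s2: bool = True
    s3: bool = True
    s4: bool = True
    s5: bool = True
    proximity_window: int = 250  # chars, within a paragraph
    allergy_adjacency: int = 30  # chars between allergy label and drug
    hypersensitivity_code: str = "T_HYPERSENS"
    re_adr_gap_days: int = 30
    filter_refusal: bool = False
    filter_switch: bool = False
    filter_indication: bool = False
    switch_patterns: tuple[str, ...] = DEFAULT_SWITCH_PATTERNS
    conjunctions: tuple[str, ...] = ("en", "and")

    def filter_flags(self) -> dict[str, bool]:
        return {
            "refusal": self.filter_refusal,
            "switch": self.filter_switch,
            "indication": self.filter_indication,
        }


# ---------------------------------------------------------------------------
# segmentation


@dataclass(frozen=True)
class Segmentation:
    """Sentence and paragraph spans partitioning a text.

    Spans are 0-based half-open; separators are attached to the preceding
    segment, so concatenating segments reconstructs the text exactly and
    every character belongs to exactly one sentence and one paragraph.
    """

    text: str
    sentences: tuple[tuple[int, int], ...]
    paragraphs: tuple[tuple[int, int], ...]

    def sentence_index(self, offset: int) -> int:
        starts = [s for s, _ in self.sentences]
        return max(0, bisect_right(starts, offset) - 1)

    def paragraph_index(self, offset: int) -> int:
        starts = [s for s, _ in self.paragraphs]
        return max(0, bisect_right(starts, offset) - 1)


_PARA_BREAK = re.compile(r"\n[ \t]*(?:\n[ \t]*)+")
_SENT_BOUND = re.compile(r"[.!?]+(?:\s+|$)")


def segment(text: str) -> Segmentation:
    """Split text into paragraph and sentence spans (reassembly-exact)."""
    paragraphs: list[tuple[int, int]] = []
    prev = 0
    for m in _PARA_BREAK.finditer(text):
        paragraphs.append((prev, m.end()))
        prev = m.end()
    if prev < len(text) or not paragraphs:
        if text:
            paragraphs.append((prev, len(text)))
    sentences: list[tuple[int, int]] = []
    for ps, pe in paragraphs:
        start = ps
        for m in _SENT_BOUND.finditer(text, ps, pe):
            if m.end() > start:
                sentences.append((start, m.end()))
                start = m.end()
        if start < pe:
            sentences.append((start, pe))
    return Segmentation(text=text, sentences=tuple(sentences), paragraphs=tuple(paragraphs))


# ---------------------------------------------------------------------------
# mention detection


@dataclass(frozen=True)
class Mention:
    kind: str  # drug | adr_term | trigger
    start: int
    end: int
    resolved_id: str
    sentence_index: int
    surface: str
    trigger_kind: str | None = None


class _Matcher:
    """Compiled longest-match scanner over a set of folded surface forms."""

    def __init__(self, surfaces: Mapping[str, str]) -> None:
        self._surfaces = dict(surfaces)
        if self._surfaces:
            parts = [
                r"\s+".join(re.escape(tok) for tok in s.split())
                for s in sorted(self._surfaces, key=len, reverse=True)
            ]
            self._re: re.Pattern | None = re.compile(
                r"(?<![a-z0-9])(?:" + "|".join(parts) + r")(?![a-z0-9])"
            )
        else:
            self._re = None

    def find(self, folded_text: str) -> list[tuple[int, int, str]]:
        if self._re is None:
            return []
        out = []
        for m in self._re.finditer(folded_text):
            key = re.sub(r"\s+", " ", m.group(0))
            out.append((m.start(), m.end(), self._surfaces[key]))
        return out


def _matchers(lexicons: Lexicons) -> dict[str, _Matcher]:
    cache = getattr(lexicons, "_adrmine_matchers", None)
    if cache is None:
        cache = {
            "drug": _Matcher(lexicons.drugs.surfaces),
            "adr_term": _Matcher(lexicons.terms.surfaces),
            "trigger": _Matcher(lexicons.triggers.surfaces),
        }
        lexicons._adrmine_matchers = cache  # type: ignore[attr-defined]
    return cache


def detect_mentions(
    note: Note, lexicons: Lexicons, seg: Segmentation | None = None
) -> list[Mention]:
    """All lexicon surface forms present in the note text, longest-match,
    non-overlapping per kind, with exact character offsets."""
    if seg is None:
        seg = segment(note.text)
    folded = fold(note.text)
    matchers = _matchers(lexicons)
    mentions: list[Mention] = []
    for kind, matcher in matchers.items():
        for start, end, rid in matcher.find(folded):
            mentions.append(
                Mention(
                    kind=kind,
                    start=start,
                    end=end,
                    resolved_id=rid,
                    sentence_index=seg.sentence_index(start),
                    surface=note.text[start:end],
                    trigger_kind=(
                        lexicons.triggers.kind_of(rid) if kind == "trigger" else None
                    ),
                )
            )
    mentions.sort(key=lambda m: (m.start, m.end))
    return mentions


# ---------------------------------------------------------------------------
# candidate assembly


@dataclass(frozen=True)
class CandidateADR:
    note_id: str
    patient_id: str
    ingredient_ids: tuple[str, ...]
    term_code: str
    symptom_text: str
    trigger_word: str | None
    trigger_kind: str | None
    context: str
    date: dt.date
    professional: str
    strategy: str
    drug_span: tuple[int, int] = (0, 0)
    term_span: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class _Phrase:
    start: int
    end: int
    ids: tuple[str, ...]
    sentence_index: int


_SLASH_GAP = re.compile(r"^\s*[/+]\s*$")


def _drug_phrases(drug_mentions: Sequence[Mention], text: str) -> list[_Phrase]:
    """Merge drug mentions joined by a combination construction ("/", "+")
    into one phrase carrying all ingredient ids."""
    phrases: list[_Phrase] = []
    i = 0
    while i < len(drug_mentions):
        first = drug_mentions[i]
        ids = [first.resolved_id]
        end = first.end
        j = i + 1
        while j < len(drug_mentions) and _SLASH_GAP.match(text[end : drug_mentions[j].start]):
            if drug_mentions[j].resolved_id not in ids:
                ids.append(drug_mentions[j].resolved_id)
            end = drug_mentions[j].end
            j += 1
        phrases.append(
            _Phrase(start=first.start, end=end, ids=tuple(ids),
                    sentence_index=first.sentence_index)
        )
        i = j
    return phrases


def _conjunction_gap_re(conjunctions: tuple[str, ...]) -> re.Pattern:
    alts = "|".join(re.escape(c) for c in conjunctions)
    return re.compile(rf"^[\s,]*(?:(?:{alts})\s+)?[\s,]*$")


def _reaction_phrases(
    term_mentions: Sequence[Mention], folded: str, conjunctions: tuple[str, ...]
) -> list[_Phrase]:
    """Merge reaction-term mentions joined only by commas/conjunctions into
    one phrase (the "reaction phrase" the counting rules later re-split)."""
    gap_re = _conjunction_gap_re(conjunctions)
    phrases: list[_Phrase] = []
    i = 0
    while i < len(term_mentions):
        first = term_mentions[i]
        ids = [first.resolved_id]
        end = first.end
        j = i + 1
        while j < len(term_mentions):
            gap = folded[end : term_mentions[j].start]
            if not (0 < len(gap) <= 16 and gap_re.match(gap)):
                break
            if term_mentions[j].resolved_id not in ids:
                ids.append(term_mentions[j].resolved_id)
            end = term_mentions[j].end
            j += 1
        phrases.append(
            _Phrase(start=first.start, end=end, ids=tuple(ids),
                    sentence_index=first.sentence_index)
        )
        i = j
    return phrases


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, a[0] - b[1], b[0] - a[1])


def assemble_candidates(
    mentions: Sequence[Mention],
    note: Note,
    lexicons: Lexicons,
    config: MinerConfig | None = None,
    seg: Segmentation | None = None,
) -> list[CandidateADR]:
    """Apply the enabled strategies to the detected mentions.

    One candidate is emitted per (drug phrase, reaction phrase) pair; when
    several strategies fire for the same pair the lowest-numbered strategy
    is recorded. The candidate's ``term_code`` is the first code of the
    reaction phrase; :func:`apply_counting_rules` expands multi-symptom
    phrases afterwards.
    """
    config = config or MinerConfig()
    if seg is None:
        seg = segment(note.text)
    folded = fold(note.text)
    out: dict[tuple, CandidateADR] = {}

    for ps, pe in seg.paragraphs:
        in_par = [m for m in mentions if ps <= m.start < pe]
        drugs = [m for m in in_par if m.kind == "drug"]
        terms = [m for m in in_par if m.kind == "adr_term"]
        trigs = [m for m in in_par if m.kind == "trigger"]
        if not drugs:
            continue
        dps = _drug_phrases(drugs, note.text)
        rps = _reaction_phrases(terms, folded, config.conjunctions)
        context = note.text[ps:pe].strip()

        def near(a: _Phrase | Mention, b: _Phrase | Mention) -> bool:
            a_span = (a.start, a.end)
            b_span = (b.start, b.end)
            if a.sentence_index == b.sentence_index:
                return True
            return _gap(a_span, b_span) <= config.proximity_window

        def emit(strategy: str, dp: _Phrase, rp: _Phrase | None,
                 trigger: Mention | None, term_code: str | None = None) -> None:
            if rp is not None:
                code = rp.ids[0]
                symptom = note.text[rp.start : rp.end]
                term_span = (rp.start, rp.end)
            else:
                code = term_code or config.hypersensitivity_code
                symptom = trigger.surface if trigger else ""
                term_span = (trigger.start, trigger.end) if trigger else (0, 0)
            key = (dp.start, dp.end, term_span, code)
            if key in out:
                return  # earlier (lower-numbered) strategy wins
            out[key] = CandidateADR(
                note_id=note.note_id,
                patient_id=note.patient_id,
                ingredient_ids=dp.ids,
                term_code=code,
                symptom_text=symptom,
                trigger_word=trigger.surface if trigger else None,
                trigger_kind=trigger.trigger_kind if trigger else None,
                context=context,
                date=note.timestamp,
                professional=note.author_role,
                strategy=strategy,
                drug_span=(dp.start, dp.end),
                term_span=term_span,
            )

        if config.s1:
            for dp in dps:
                for rp in rps:
                    if dp.sentence_index == rp.sentence_index:
                        emit("S1", dp, rp, None)
        if config.s2:
            for t in (m for m in trigs if m.trigger_kind == "causal_link"):
                for dp in dps:
                    if not near(dp, t):
                        continue
                    for rp in rps:
                        if near(rp, t):
                            emit("S2", dp, rp, t)
        if config.s3:
            for t in (m for m in trigs if m.trigger_kind == "causal_link"):
                for rp in rps:
                    if not near(rp, t):
                        continue
                    preceding = [dp for dp in dps if dp.end <= rp.start]
                    if not preceding:
                        continue
                    dp = min(
                        preceding,
                        key=lambda d: (rp.start - d.end, d.start),
                    )
                    emit("S3", dp, rp, t)
        if config.s4:
            for t in (m for m in trigs if m.trigger_kind == "allergy_label"):
                for dp in dps:
                    if (
                        t.sentence_index == dp.sentence_index
                        and _gap((t.start, t.end), (dp.start, dp.end))
                        <= config.allergy_adjacency
                    ):
                        nearby = [rp for rp in rps if near(rp, t)]
                        if nearby:
                            for rp in nearby:
                                emit("S4", dp, rp, t)
                        else:
                            emit("S4", dp, None, t)
        if config.s5:
            if any(m.trigger_kind == "discontinuation" for m in trigs):
                t = next(m for m in trigs if m.trigger_kind == "discontinuation")
                for dp in dps:
                    for rp in rps:
                        emit("S5", dp, rp, t)

    order = {"S1": 0, "S2": 1, "S3": 2, "S4": 3, "S5": 4}
    return sorted(
        out.values(),
        key=lambda c: (c.drug_span, c.term_span, order.get(c.strategy, 9)),
    )


# ---------------------------------------------------------------------------
# counting rules


def apply_counting_rules(
    candidate: CandidateADR,
    terms: AdrTermIndex,
    conjunctions: tuple[str, ...] = ("en", "and"),
) -> list[CandidateADR]:
    """The manual-review counting rules.

    A reaction phrase resolving to k distinct term codes yields k candidates
    (multiple symptoms count separately); a combination-drug construction
    stays ONE candidate carrying all ingredient ids (already merged at
    assembly).
    """
    alts = "|".join(re.escape(c) for c in conjunctions)
    fragments = re.split(rf",|\s+(?:{alts})\s+", fold(candidate.symptom_text))
    resolved: list[tuple[str, str]] = []
    for frag in fragments:
        frag = frag.strip(" ,")
        if not frag:
            continue
        term = terms.lookup(frag)
        if term is not None and term.term_code not in [c for c, _ in resolved]:
            resolved.append((term.term_code, frag))
    if len(resolved) <= 1:
        return [candidate]
    return [
        replace(candidate, term_code=code, symptom_text=frag)
        for code, frag in resolved
    ]


# ---------------------------------------------------------------------------
# false-positive filters


@dataclass(frozen=True)
class RejectedCandidate:
    candidate: CandidateADR
    reason: str


def apply_fp_filters(
    candidates: Sequence[CandidateADR],
    flags: Mapping[str, bool],
    *,
    triggers: TriggerLexicon | None = None,
    switch_patterns: Sequence[str] = DEFAULT_SWITCH_PATTERNS,
    indications: Mapping[str, frozenset[str]] | None = None,
    drugs: DrugLexicon | None = None,
) -> tuple[list[CandidateADR], list[RejectedCandidate]]:
    """Apply the three optional false-positive filters (all default off).

    ``flags`` maps filter name (``refusal``, ``switch``, ``indication``) to
    on/off; unknown names are a hard error. Filters are applied in that
    order; the first one that fires records the rejection reason.
    """
    unknown = set(flags) - set(FILTER_NAMES)
    if unknown:
        raise ValueError(f"unknown filter flags: {sorted(unknown)}")
    refusal_matcher = None
    if flags.get("refusal") and triggers is not None:
        refusal_surfaces = {
            s: s for s, surf in triggers.surfaces.items()
            if triggers.kind_of(s) == "refusal"
        }
        refusal_matcher = _Matcher(refusal_surfaces)
    folded_patterns = [fold(p) for p in switch_patterns]
    indications = indications or {}

    kept: list[CandidateADR] = []
    rejected: list[RejectedCandidate] = []
    for cand in candidates:
        reason = None
        if flags.get("refusal"):
            if cand.trigger_kind == "refusal":
                reason = "refusal"
            elif refusal_matcher is not None and refusal_matcher.find(fold(cand.context)):
                reason = "refusal"
        if reason is None and flags.get("switch"):
            folded_context = fold(cand.context)
            if any(p in folded_context for p in folded_patterns):
                reason = "switch"
        if reason is None and flags.get("indication"):
            for iid in cand.ingredient_ids:
                ids = drugs.expand(iid) if drugs is not None else {iid}
                if any(cand.term_code in indications.get(i, ()) for i in ids):
                    reason = "indication"
                    break
        if reason is None:
            kept.append(cand)
        else:
            rejected.append(RejectedCandidate(candidate=cand, reason=reason))
    return kept, rejected


# ---------------------------------------------------------------------------
# unique ADRs


@dataclass
class UniqueADR:
    """Deduplicated patient-level ADR — the unit all metrics count."""

    patient_id: str
    ingredient_ids: tuple[str, ...]
    term_code: str
    first_date: dt.date
    serious: bool = False
    source: str = "algorithm"  # manual | algorithm | structured
    naranjo_score: int | None = None
    re_adr: bool = False

    @property
    def key(self) -> tuple[str, tuple[str, ...], str]:
        return (self.patient_id, tuple(sorted(set(self.ingredient_ids))), self.term_code)


def deduplicate(
    candidates: Sequence[CandidateADR], source: str = "algorithm"
) -> tuple[list[UniqueADR], int, dict[tuple, list[dt.date]], dict[tuple, list[int]]]:
    """Reduce candidates to unique ADRs.

    Key is (patient, normalized ingredient set, term code); the earliest
    date is kept. Returns (uniques, number of duplicates removed, key ->
    sorted occurrence dates, key -> contributing candidate indices).
    Idempotent: deduplicating the output again removes nothing.
    """
    uniques: dict[tuple, UniqueADR] = {}
    occurrences: dict[tuple, list[dt.date]] = {}
    audit: dict[tuple, list[int]] = {}
    n_dup = 0
    for idx, cand in enumerate(candidates):
        key = (
            cand.patient_id,
            tuple(sorted(set(cand.ingredient_ids))),
            cand.term_code,
        )
        occurrences.setdefault(key, []).append(cand.date)
        audit.setdefault(key, []).append(idx)
        if key in uniques:
            n_dup += 1
            if cand.date < uniques[key].first_date:
                uniques[key].first_date = cand.date
        else:
            uniques[key] = UniqueADR(
                patient_id=cand.patient_id,
                ingredient_ids=key[1],
                term_code=cand.term_code,
                first_date=cand.date,
                source=source,
            )
    for dates in occurrences.values():
        dates.sort()
    return list(uniques.values()), n_dup, occurrences, audit


def _episodes(dates: Sequence[dt.date], gap_days: int) -> list[list[dt.date]]:
    episodes: list[list[dt.date]] = []
    for d in sorted(dates):
        if episodes and (d - episodes[-1][-1]).days <= gap_days:
            episodes[-1].append(d)
        else:
            episodes.append([d])
    return episodes


@dataclass(frozen=True)
class ReAdrEvent:
    """A recurrence of an already-recorded ADR in a later episode."""

    patient_id: str
    ingredient_ids: tuple[str, ...]
    term_code: str
    date: dt.date


def flag_re_adrs(
    unique_adrs: Sequence[UniqueADR],
    occurrences: Mapping[tuple, Sequence[dt.date]],
    notes: Sequence[Note],
    drugs: DrugLexicon,
    gap_days: int = 30,
) -> list[ReAdrEvent]:
    """Flag recurrent ADRs (reADRs).

    A unique ADR is flagged when its key occurs in two episodes separated by
    more than ``gap_days`` with an intervening re-prescription signal (a
    mention of the drug in a note dated between the episodes). The unique
    ADR keeps its first episode; each later episode is reported separately
    as a :class:`ReAdrEvent` and is not counted again.
    """
    by_patient: dict[str, list[Note]] = {}
    for note in notes:
        by_patient.setdefault(note.patient_id, []).append(note)
    matcher_cache: dict[tuple[str, ...], _Matcher] = {}
    events: list[ReAdrEvent] = []
    for adr in unique_adrs:
        dates = occurrences.get(adr.key, [adr.first_date])
        episodes = _episodes(dates, gap_days)
        if len(episodes) < 2:
            continue
        ids = adr.ingredient_ids
        if ids not in matcher_cache:
            surfaces: dict[str, str] = {}
            expanded: set[str] = set()
            for iid in ids:
                expanded |= drugs.expand(iid)
            for iid in expanded:
                entry = drugs.entries.get(iid)
                if entry:
                    for s in entry.surface_forms:
                        surfaces[fold(s)] = iid
            matcher_cache[ids] = _Matcher(surfaces)
        matcher = matcher_cache[ids]
        flagged = False
        for prev, nxt in zip(episodes, episodes[1:]):
            between = [
                n
                for n in by_patient.get(adr.patient_id, [])
                if prev[-1] < n.timestamp < nxt[0]
            ]
            if any(matcher.find(fold(n.text)) for n in between):
                flagged = True
                events.append(
                    ReAdrEvent(
                        patient_id=adr.patient_id,
                        ingredient_ids=ids,
                        term_code=adr.term_code,
                        date=nxt[0],
                    )
                )
        adr.re_adr = adr.re_adr or flagged
    return events


# ---------------------------------------------------------------------------
# annotation-ledger reduction (manual-review flow arithmetic)


@dataclass
class AnnotationReduction:
    """Outcome of the duplicate/reADR exclusion stage over an annotation
    ledger: ``unique`` + ``duplicates`` + ``re_adrs`` partition the input."""

    unique: list[AnnotationRecord]
    duplicates: list[AnnotationRecord]
    re_adrs: list[AnnotationRecord]


def reduce_annotations(
    records: Sequence[AnnotationRecord], gap_days: int = 30
) -> AnnotationReduction:
    """Deduplicate an annotation ledger and split off recurrences.

    Records sharing (patient, ingredient set, term) are grouped; occurrence
    dates are clustered into episodes (chained gap of ``gap_days``). The
    first record of the first episode is the unique ADR; later records in
    the same episode are duplicates; the first record of each later episode
    is a reADR; remaining records are duplicates.
    """
    groups: dict[tuple, list[AnnotationRecord]] = {}
    for rec in records:
        key = (rec.patient_id, tuple(sorted(set(rec.ingredient_ids))), rec.term_code)
        groups.setdefault(key, []).append(rec)
    unique: list[AnnotationRecord] = []
    duplicates: list[AnnotationRecord] = []
    re_adrs: list[AnnotationRecord] = []
    for recs in groups.values():
        recs = sorted(recs, key=lambda r: r.date)
        episode_last: dt.date | None = None
        for rec in recs:
            if episode_last is None:
                unique.append(rec)
            elif (rec.date - episode_last).days <= gap_days:
                duplicates.append(rec)
            else:
                re_adrs.append(rec)
            episode_last = rec.date
    return AnnotationReduction(unique=unique, duplicates=duplicates, re_adrs=re_adrs)


# ---------------------------------------------------------------------------
# end-to-end composition


@dataclass
class MiningResult:
    unique: list[UniqueADR]
    re_adr_events: list[ReAdrEvent]
    candidates: list[CandidateADR]
    kept: list[CandidateADR]
    rejected: list[RejectedCandidate]
    n_duplicates: int
    audit: dict[tuple, list[int]]
    stage_counts: dict[str, int]


def mine_corpus(
    notes: Sequence[Note], lexicons: Lexicons, config: MinerConfig | None = None
) -> MiningResult:
    """Run the full pipeline: detect, assemble, count, filter, deduplicate,
    flag recurrences. Deterministic for fixed inputs and config; the audit
    trail links every unique ADR to its contributing candidates."""
    config = config or MinerConfig()
    candidates: list[CandidateADR] = []
    n_mentions = 0
    for note in notes:
        seg = segment(note.text)
        mentions = detect_mentions(note, lexicons, seg)
        n_mentions += len(mentions)
        for cand in assemble_candidates(mentions, note, lexicons, config, seg):
            candidates.extend(
                apply_counting_rules(cand, lexicons.terms, config.conjunctions)
            )
    kept, rejected = apply_fp_filters(
        candidates,
        config.filter_flags(),
        triggers=lexicons.triggers,
        switch_patterns=config.switch_patterns,
        indications=lexicons.indications,
        drugs=lexicons.drugs,
    )
    uniques, n_dup, occurrences, audit = deduplicate(kept)
    for adr in uniques:
        term = lexicons.terms.terms.get(adr.term_code)
        adr.serious = bool(term and term.serious)
    events = flag_re_adrs(uniques, occurrences, notes, lexicons.drugs, config.re_adr_gap_days)
    return MiningResult(
        unique=uniques,
        re_adr_events=events,
        candidates=candidates,
        kept=kept,
        rejected=rejected,
        n_duplicates=n_dup,
        audit=audit,
        stage_counts={
            "notes": len(notes),
            "mentions": n_mentions,
            "candidates": len(candidates),
            "kept": len(kept),
            "rejected": len(rejected),
            "unique": len(uniques),
            "re_adr_events": len(events),
        },
    )
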