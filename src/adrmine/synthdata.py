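"""Seeded synthetic EHR corpora with a known gold standard.

No patient data accompany the study this package operationalises, so every
other module is exercised against generated corpora whose ground truth is
recorded exhaustively in a :class:`GoldLedger`. The generator emulates the
published data profile of two hospitals (CZE, JBZ) x two departments
(geriatric, orthopedic): per-patient note counts and word volumes are drawn
from log-normal distributions calibrated to the reported medians and
truncated to the reported ranges (log-normals match the strong right skew
of EHR volume: median 347 notes against a maximum of 1,720).

Notes are filler sentences from a closed vocabulary that is verified at
generation time to contain no lexicon surface form; ADR mentions are
planted as grammatical template instantiations ("[symptom] door [drug]",
"[drug] gestaakt wegens [symptom]", allergy labels), together with
duplicates, recurrences (reADRs) with an intervening re-prescription
signal, and the three documented false-positive confounder patterns
(patient refusal, drug switch, treated indication). Dutch templates are
the default; English templates are provided for readable examples.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from adrmine.corpus_io import AnnotationRecord, Note
from adrmine.lexicons import Lexicons, fold, load_bundled
from adrmine.miner import UniqueADR, segment

__all__ = [
    "SynthConfig",
    "NoiseConfig",
    "PlantedAdr",
    "PlantedConfounder",
    "GoldLedger",
    "generate",
    "degrade",
    "generate_annotation_ledger",
]


# calibration targets: per-department note/word medians and ranges as
# reported for the two-hospital study population
_NOTES_PER_PATIENT = {"geriatric": (480.0, 99, 1720), "orthopedic": (248.0, 70, 670)}
_WORDS_PER_PATIENT_MEDIAN = {"geriatric": 21626.0, "orthopedic": 6861.5}


@dataclass
class SynthConfig:
    """All distributions, rates and the seed governing corpus generation.

    Defaults reproduce the study conditions: 62 patients split over two
    hospitals and two departments, department-specific note volumes, a
    median of roughly four unique ADRs per patient (more at CZE than JBZ),
    a duplicate-to-unique ratio of ~0.51, a reADR rate of ~0.13 and a
    serious fraction of ~0.19.
    """

    seed: int
    patients: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("CZE", "geriatric"): 15,
            ("CZE", "orthopedic"): 15,
            ("JBZ", "geriatric"): 15,
            ("JBZ", "orthopedic"): 17,
        }
    )
    notes_per_patient: Mapping[str, tuple[float, int, int]] = field(
        default_factory=lambda: dict(_NOTES_PER_PATIENT)
    )
    words_per_patient_median: Mapping[str, float] = field(
        default_factory=lambda: dict(_WORDS_PER_PATIENT_MEDIAN)
    )
    note_sigma: float = 0.45  # log-sd of the note-count log-normal
    word_sigma: float = 0.55  # log-sd of the words-per-note log-normal
    adr_median_per_patient: Mapping[str, float] = field(
        default_factory=lambda: {"CZE": 6.0, "JBZ": 3.0}
    )
    adr_sigma: float = 0.8
    max_adrs_per_patient: int = 30
    duplicate_rate: float = 234 / 455
    re_adr_rate: float = 58 / 455
    re_adr_min_gap: int = 45  # days to the recurrence episode
    re_adr_max_gap: int = 300
    confounder_rates: Mapping[str, float] = field(
        default_factory=lambda: {"refusal": 0.6, "switch": 0.6, "indication": 0.6}
    )
    serious_fraction: float = 69 / 359
    allergy_fraction: float = 0.1
    naranjo_scores: tuple[int, ...] = (1, 2, 3, 4, 5)
    naranjo_probs: tuple[float, ...] = (0.22, 0.25, 0.33, 0.18, 0.02)
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "consultation": 0.50,
            "questionnaire": 0.30,
            "microbiology": 0.05,
            "pathology": 0.05,
            "radiology": 0.05,
            "medical_history": 0.05,
        }
    )
    role_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "physician": 0.60,
            "nurse": 0.30,
            "dietician": 0.05,
            "physiotherapist": 0.05,
        }
    )
    language: str = "nl"
    base_date: dt.date = dt.date(2023, 12, 1)
    span_days: int = 365

    def __post_init__(self) -> None:
        for name, rate in [
            ("duplicate_rate", self.duplicate_rate),
            ("re_adr_rate", self.re_adr_rate),
            ("serious_fraction", self.serious_fraction),
            ("allergy_fraction", self.allergy_fraction),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.language not in ("nl", "en"):
            raise ValueError(f"language must be 'nl' or 'en', got {self.language!r}")
        if any(n < 0 for n in self.patients.values()):
            raise ValueError("patient counts must be >= 0")


# template -> (format string, which slot comes first)
_TEMPLATES = {
    "nl": {
        "causal": "{term} door {drug}.",
        "discontinuation": "{drug} gestaakt wegens {term}.",
        "allergy": "Allergie: {drug}.",
        "refusal": "Patient weigert {drug} vanwege {term}.",
        "switch": "{drug} omgezet naar een alternatief vanwege {term}.",
        "indication": "{drug} gegeven voor {term}.",
        "represcription": "{drug} herstart.",
    },
    "en": {
        "causal": "{term} due to {drug}.",
        "discontinuation": "{drug} discontinued because of {term}.",
        "allergy": "Allergy: {drug}.",
        "refusal": "Patient refuses {drug} because of {term}.",
        "switch": "{drug} switched to an alternative because of {term}.",
        "indication": "{drug} given for {term}.",
        "represcription": "{drug} restarted.",
    },
}

_FILLER_VOCAB = (
    "de het een is was wordt bleef vandaag gisteren controle opname ontslag "
    "beleid verder stabiel rustig goede nacht dag eet drinkt mobiliseert "
    "met hulp fysiotherapie afspraak familie besproken lab uitslagen binnen "
    "normale waarden wond genezing vlot geen bijzonderheden vervolg morgen "
    "visite arts verpleging rapportage situatie ongewijzigd conditie "
    "verbetering langzaam herstel na operatie knie heup links rechts "
    "belastbaar loopt zelfstandig"
).split()


@dataclass
class PlantedAdr:
    """One planted ADR mention, locatable as a substring of the corpus."""

    patient_id: str
    note_id: str
    ingredient_ids: tuple[str, ...]
    term_code: str
    date: dt.date
    serious: bool
    naranjo_score: int
    template: str
    fragment: str
    fragment_span: tuple[int, int] = (0, 0)
    drug_span: tuple[int, int] = (0, 0)
    term_span: tuple[int, int] | None = None
    degraded: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, tuple[str, ...], str]:
        return (self.patient_id, tuple(sorted(set(self.ingredient_ids))), self.term_code)


@dataclass
class PlantedConfounder:
    """A planted false-positive pattern (refusal / switch / indication)."""

    kind: str
    patient_id: str
    note_id: str
    ingredient_ids: tuple[str, ...]
    term_code: str
    date: dt.date
    fragment: str
    fragment_span: tuple[int, int] = (0, 0)

    @property
    def key(self) -> tuple[str, tuple[str, ...], str]:
        return (self.patient_id, tuple(sorted(set(self.ingredient_ids))), self.term_code)


@dataclass
class GoldLedger:
    """Exhaustive ground truth for one generated corpus."""

    plants: list[PlantedAdr] = field(default_factory=list)
    duplicates: list[PlantedAdr] = field(default_factory=list)
    re_adrs: list[PlantedAdr] = field(default_factory=list)
    confounders: list[PlantedConfounder] = field(default_factory=list)
    patient_strata: dict[str, tuple[str, str]] = field(default_factory=dict)
    per_patient: dict[str, dict[str, int]] = field(default_factory=dict)

    def gold_unique(self) -> list[UniqueADR]:
        """The planted unique ADRs as the manual-review reference set."""
        return [
            UniqueADR(
                patient_id=p.patient_id,
                ingredient_ids=tuple(sorted(set(p.ingredient_ids))),
                term_code=p.term_code,
                first_date=p.date,
                serious=p.serious,
                source="manual",
                naranjo_score=p.naranjo_score,
            )
            for p in self.plants
        ]

    def plant_keys(self) -> set[tuple]:
        return {p.key for p in self.plants}

    def confounder_keys(self) -> set[tuple]:
        return {c.key for c in self.confounders}


def _check_filler_safe(lexicons: Lexicons) -> None:
    vocab = {fold(w) for w in _FILLER_VOCAB}
    for surfaces in (
        lexicons.drugs.surfaces,
        lexicons.terms.surfaces,
        lexicons.triggers.surfaces,
    ):
        for surface in surfaces:
            if all(tok in vocab for tok in surface.split()):
                raise ValueError(
                    f"filler vocabulary can spell lexicon surface {surface!r}"
                )


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float, lo: float, hi: float
) -> float:
    for _ in range(100):
        value = float(rng.lognormal(np.log(median), sigma))
        if lo <= value <= hi:
            return value
    return float(min(max(median, lo), hi))


class _NoteDraft:
    __slots__ = ("note_id", "date", "category", "role", "paragraphs", "items")

    def __init__(self, note_id: str, date: dt.date, category: str, role: str) -> None:
        self.note_id = note_id
        self.date = date
        self.category = category
        self.role = role
        self.paragraphs: list[str] = []
        # (ledger item, paragraph index, relative drug span, relative term span)
        self.items: list[tuple[object, int, tuple[int, int], tuple[int, int] | None]] = []


def _filler_paragraphs(rng: np.random.Generator, n_words: int) -> list[str]:
    words = list(rng.choice(_FILLER_VOCAB, size=max(n_words, 3)))
    paragraphs = []
    i = 0
    while i < len(words):
        n_sent = int(rng.integers(1, 4))
        sentences = []
        for _ in range(n_sent):
            k = int(rng.integers(4, 13))
            chunk = words[i : i + k]
            i += k
            if not chunk:
                break
            sentences.append(" ".join(chunk).capitalize() + ".")
        if sentences:
            paragraphs.append(" ".join(sentences))
    return paragraphs


def _fragment(
    rng: np.random.Generator,
    template_name: str,
    templates: Mapping[str, str],
    drug_surface: str,
    term_surface: str | None,
) -> tuple[str, tuple[int, int], tuple[int, int] | None]:
    """Instantiate a template; returns (text, drug span, term span), spans
    relative to the fragment."""
    tpl = templates[template_name]
    head, _, tail = tpl.partition("{drug}")
    if "{term}" in head:
        assert term_surface is not None
        pre, _, mid = head.partition("{term}")
        term_text = term_surface.capitalize() if not pre else term_surface
        text = pre + term_text + mid
        term_span = (len(pre), len(pre) + len(term_surface))
        drug_span = (len(text), len(text) + len(drug_surface))
        return text + drug_surface + tail, drug_span, term_span
    drug_text = drug_surface
    text = head + drug_text
    drug_span = (len(head), len(head) + len(drug_surface))
    if "{term}" in tail:
        mid, _, end = tail.partition("{term}")
        assert term_surface is not None
        term_span = (len(text) + len(mid), len(text) + len(mid) + len(term_surface))
        return text + mid + term_surface + end, drug_span, term_span
    return text + tail, drug_span, None


def generate(
    config: SynthConfig, lexicons: Lexicons | None = None
) -> tuple[list[Note], GoldLedger]:
    """Generate a corpus plus its gold ledger; deterministic for a fixed
    seed. Raises if a requested plant cannot be realised from the lexicons
    or if the filler vocabulary could spell a lexicon surface form."""
    lexicons = lexicons or load_bundled(config.language)
    _check_filler_safe(lexicons)
    rng = np.random.default_rng(config.seed)
    templates = _TEMPLATES[config.language]

    ingredients = [e for e in lexicons.drugs if not e.is_group]
    hyp_code = "T_HYPERSENS"
    if hyp_code not in lexicons.terms:
        raise ValueError("lexicons lack the unspecified-hypersensitivity code")
    indication_pairs = [
        (iid, code)
        for iid, codes in lexicons.indications.items()
        for code in sorted(codes)
        if iid in lexicons.drugs.entries and code in lexicons.terms
    ]
    serious_terms = sorted(
        t.term_code
        for t in lexicons.terms
        if t.serious
    )
    plain_terms = sorted(
        t.term_code
        for t in lexicons.terms
        if not t.serious and t.term_code != hyp_code
    )
    if not serious_terms or not plain_terms:
        raise ValueError("term dictionary must contain serious and non-serious terms")

    def pick_pair(used: set, serious: bool) -> tuple[str, str] | None:
        pool = serious_terms if serious else plain_terms
        for _ in range(200):
            drug = ingredients[int(rng.integers(len(ingredients)))]
            code = pool[int(rng.integers(len(pool)))]
            key = (drug.ingredient_id, code)
            if key in used or code in lexicons.indications.get(drug.ingredient_id, ()):
                continue
            used.add(key)
            return key
        return None

    notes: list[Note] = []
    ledger = GoldLedger()
    note_seq = 0
    patient_seq = 0

    for (hospital, department), n_patients in config.patients.items():
        npp_median, npp_lo, npp_hi = config.notes_per_patient[department]
        wpn_median = config.words_per_patient_median[department] / npp_median
        categories = sorted(config.category_mix)
        cat_p = np.array([config.category_mix[c] for c in categories], dtype=float)
        cat_p /= cat_p.sum()
        roles = sorted(config.role_mix)
        role_p = np.array([config.role_mix[r] for r in roles], dtype=float)
        role_p /= role_p.sum()

        for _ in range(n_patients):
            patient_seq += 1
            pid = f"P{patient_seq:03d}"
            ledger.patient_strata[pid] = (hospital, department)
            n_notes = int(
                round(
                    _truncated_lognormal(
                        rng, npp_median, config.note_sigma, npp_lo, npp_hi
                    )
                )
            )
            drafts: list[_NoteDraft] = []
            offsets = rng.integers(0, config.span_days, size=n_notes)
            cats = rng.choice(categories, size=n_notes, p=cat_p)
            rls = rng.choice(roles, size=n_notes, p=role_p)
            for k in range(n_notes):
                note_seq += 1
                date = config.base_date - dt.timedelta(days=int(offsets[k]))
                draft = _NoteDraft(f"N{note_seq:06d}", date, str(cats[k]), str(rls[k]))
                n_words = int(
                    round(
                        _truncated_lognormal(
                            rng, wpn_median, config.word_sigma, 3, wpn_median * 20
                        )
                    )
                )
                draft.paragraphs = _filler_paragraphs(rng, n_words)
                drafts.append(draft)
            drafts.sort(key=lambda d: d.date)

            used_pairs: set[tuple[str, str]] = set()
            used_drugs_allergy: set[str] = set()

            n_adrs = int(
                round(
                    _truncated_lognormal(
                        rng,
                        config.adr_median_per_patient[hospital],
                        config.adr_sigma,
                        0.0,
                        config.max_adrs_per_patient,
                    )
                )
            )
            for _ in range(n_adrs):
                is_allergy = rng.random() < config.allergy_fraction
                if is_allergy:
                    candidates = [
                        e
                        for e in ingredients
                        if e.ingredient_id not in used_drugs_allergy
                        and (e.ingredient_id, hyp_code) not in used_pairs
                    ]
                    if not candidates:
                        continue
                    drug = candidates[int(rng.integers(len(candidates)))]
                    used_drugs_allergy.add(drug.ingredient_id)
                    used_pairs.add((drug.ingredient_id, hyp_code))
                    pair = (drug.ingredient_id, hyp_code)
                    template = "allergy"
                else:
                    serious = rng.random() < config.serious_fraction
                    pair = pick_pair(used_pairs, serious)
                    if pair is None:
                        continue
                    template = (
                        "discontinuation" if rng.random() < 0.3 else "causal"
                    )
                iid, code = pair
                entry = lexicons.drugs.entries[iid]
                drug_surface = entry.surface_forms[
                    int(rng.integers(len(entry.surface_forms)))
                ]
                if template == "allergy":
                    term_surface = None
                else:
                    forms = lexicons.terms[code].surface_forms
                    term_surface = forms[int(rng.integers(len(forms)))]
                text, dspan, tspan = _fragment(
                    rng, template, templates, drug_surface, term_surface
                )
                host = drafts[int(rng.integers(len(drafts)))]
                naranjo = int(
                    rng.choice(config.naranjo_scores, p=config.naranjo_probs)
                )
                plant = PlantedAdr(
                    patient_id=pid,
                    note_id=host.note_id,
                    ingredient_ids=(iid,),
                    term_code=code,
                    date=host.date,
                    serious=lexicons.terms[code].serious,
                    naranjo_score=naranjo,
                    template=template,
                    fragment=text,
                    drug_span=dspan,
                    term_span=tspan,
                )
                host.items.append((plant, len(host.paragraphs), dspan, tspan))
                host.paragraphs.append(text)
                ledger.plants.append(plant)

                if rng.random() < config.duplicate_rate:
                    same_day = [
                        d for d in drafts if abs((d.date - host.date).days) <= 1
                    ] or [host]
                    dup_host = same_day[int(rng.integers(len(same_day)))]
                    dup = replace(
                        plant,
                        note_id=dup_host.note_id,
                        date=dup_host.date,
                        fragment=text,
                    )
                    dup_host.items.append((dup, len(dup_host.paragraphs), dspan, tspan))
                    dup_host.paragraphs.append(text)
                    ledger.duplicates.append(dup)

                if rng.random() < config.re_adr_rate:
                    later = [
                        d
                        for d in drafts
                        if config.re_adr_min_gap
                        <= (d.date - host.date).days
                        <= config.re_adr_max_gap
                    ]
                    if later:
                        re_host = later[int(rng.integers(len(later)))]
                        between = [
                            d
                            for d in drafts
                            if host.date < d.date < re_host.date
                        ]
                        if between:
                            represc_host = between[int(rng.integers(len(between)))]
                            rtext, rdspan, _ = _fragment(
                                rng, "represcription", templates, drug_surface, None
                            )
                            represc_host.paragraphs.append(rtext)
                            re_plant = replace(
                                plant,
                                note_id=re_host.note_id,
                                date=re_host.date,
                                fragment=text,
                            )
                            re_host.items.append(
                                (re_plant, len(re_host.paragraphs), dspan, tspan)
                            )
                            re_host.paragraphs.append(text)
                            ledger.re_adrs.append(re_plant)

            for kind in sorted(config.confounder_rates):
                n_conf = int(rng.poisson(config.confounder_rates[kind]))
                for _ in range(n_conf):
                    if kind == "indication":
                        free = [
                            p for p in indication_pairs if p not in used_pairs
                        ]
                        if not free:
                            continue
                        iid, code = free[int(rng.integers(len(free)))]
                        used_pairs.add((iid, code))
                    else:
                        pair = pick_pair(used_pairs, serious=False)
                        if pair is None:
                            continue
                        iid, code = pair
                    entry = lexicons.drugs.entries[iid]
                    drug_surface = entry.surface_forms[
                        int(rng.integers(len(entry.surface_forms)))
                    ]
                    forms = lexicons.terms[code].surface_forms
                    term_surface = forms[int(rng.integers(len(forms)))]
                    text, dspan, tspan = _fragment(
                        rng, kind, templates, drug_surface, term_surface
                    )
                    host = drafts[int(rng.integers(len(drafts)))]
                    conf = PlantedConfounder(
                        kind=kind,
                        patient_id=pid,
                        note_id=host.note_id,
                        ingredient_ids=(iid,),
                        term_code=code,
                        date=host.date,
                        fragment=text,
                    )
                    host.items.append((conf, len(host.paragraphs), dspan, tspan))
                    host.paragraphs.append(text)
                    ledger.confounders.append(conf)

            # assemble note texts; shuffle paragraph order first so plants
            # are not always note-final
            total_words = 0
            total_chars = 0
            for draft in drafts:
                order = list(rng.permutation(len(draft.paragraphs)))
                new_pos = {old: new for new, old in enumerate(order)}
                bodies = [draft.paragraphs[i] for i in order]
                starts: list[int] = []
                cursor = 0
                for b, body in enumerate(bodies):
                    starts.append(cursor)
                    cursor += len(body) + (2 if b < len(bodies) - 1 else 0)
                text = "\n\n".join(bodies)
                for item, par_idx, dspan, tspan in draft.items:
                    base = starts[new_pos[par_idx]]
                    item.fragment_span = (base, base + len(item.fragment))
                    if isinstance(item, PlantedAdr):
                        item.drug_span = (base + dspan[0], base + dspan[1])
                        item.term_span = (
                            (base + tspan[0], base + tspan[1]) if tspan else None
                        )
                note = Note(
                    patient_id=pid,
                    note_id=draft.note_id,
                    category=draft.category,
                    author_role=draft.role,
                    specialty=department,
                    timestamp=draft.date,
                    text=text,
                )
                notes.append(note)
                total_words += note.word_count()
                total_chars += note.char_count()
            ledger.per_patient[pid] = {
                "notes": len(drafts),
                "words": total_words,
                "chars": total_chars,
            }

    return notes, ledger


# ---------------------------------------------------------------------------
# degradation


@dataclass
class NoiseConfig:
    """Optional realistic obstacles layered on a generated corpus."""

    seed: int = 0
    misspelling_rate: float = 0.0  # per planted reaction surface
    abbreviations: Mapping[str, str] = field(default_factory=dict)
    abbreviation_rate: float = 0.0
    shuffle_paragraphs: bool = False


def degrade(
    notes: Sequence[Note], ledger: GoldLedger, noise: NoiseConfig
) -> tuple[list[Note], GoldLedger]:
    """Apply misspellings (edit distance 1 on planted reaction surfaces),
    abbreviation substitution and paragraph shuffling; the returned ledger
    annotates which plants were degraded. The inputs are not modified."""
    rng = np.random.default_rng(noise.seed)
    texts = {n.note_id: n.text for n in notes}
    items: list[PlantedAdr | PlantedConfounder] = [
        replace(p) for p in ledger.plants
    ]
    new_ledger = GoldLedger(
        plants=items,
        duplicates=[replace(p) for p in ledger.duplicates],
        re_adrs=[replace(p) for p in ledger.re_adrs],
        confounders=[replace(c) for c in ledger.confounders],
        patient_strata=dict(ledger.patient_strata),
        per_patient={k: dict(v) for k, v in ledger.per_patient.items()},
    )
    all_items = (
        new_ledger.plants + new_ledger.duplicates + new_ledger.re_adrs
    )
    by_note: dict[str, list[PlantedAdr]] = {}
    for item in all_items:
        by_note.setdefault(item.note_id, []).append(item)

    letters = "abcdefghijklmnopqrstuvwxyz"
    for note_id, note_items in by_note.items():
        # rightmost-first so earlier spans stay valid under length changes
        for item in sorted(note_items, key=lambda i: -(i.term_span or (0, 0))[0]):
            if item.term_span is None:
                continue
            start, end = item.term_span
            text = texts[note_id]
            surface = text[start:end]
            replacement = None
            tag = None
            folded = fold(surface)
            if noise.abbreviation_rate and folded in noise.abbreviations:
                if rng.random() < noise.abbreviation_rate:
                    replacement = noise.abbreviations[folded]
                    tag = "abbreviation"
            if replacement is None and rng.random() < noise.misspelling_rate:
                pos = int(rng.integers(0, len(surface)))
                for _ in range(20):
                    c = letters[int(rng.integers(len(letters)))]
                    if c != folded[pos]:
                        break
                replacement = surface[:pos] + c + surface[pos + 1 :]
                tag = "misspelling"
            if replacement is None:
                continue
            delta = len(replacement) - len(surface)
            texts[note_id] = text[:start] + replacement + text[end:]
            item.degraded = item.degraded + (tag,)
            item.term_span = (start, start + len(replacement))
            fs, fe = item.fragment_span
            item.fragment_span = (fs, fe + delta)
            item.fragment = texts[note_id][fs : fe + delta]
            if delta:
                for other in note_items:
                    if other is item:
                        continue
                    if other.fragment_span[0] > start:
                        other.fragment_span = (
                            other.fragment_span[0] + delta,
                            other.fragment_span[1] + delta,
                        )
                        other.drug_span = (
                            other.drug_span[0] + delta,
                            other.drug_span[1] + delta,
                        )
                        if other.term_span:
                            other.term_span = (
                                other.term_span[0] + delta,
                                other.term_span[1] + delta,
                            )

    new_notes = []
    conf_by_note: dict[str, list[PlantedConfounder]] = {}
    for conf in new_ledger.confounders:
        conf_by_note.setdefault(conf.note_id, []).append(conf)
    for note in notes:
        text = texts[note.note_id]
        if noise.shuffle_paragraphs:
            seg = segment(text)
            bodies = [text[s:e].rstrip("\n") for s, e in seg.paragraphs]
            trimmed_starts = [s for s, _ in seg.paragraphs]
            order = list(rng.permutation(len(bodies)))
            new_text = "\n\n".join(bodies[i] for i in order)
            new_starts: dict[int, int] = {}
            cursor = 0
            for pos, old_idx in enumerate(order):
                new_starts[old_idx] = cursor
                cursor += len(bodies[old_idx]) + 2
            def par_of(offset: int) -> int:
                idx = 0
                for k, (s, e) in enumerate(seg.paragraphs):
                    if s <= offset < e:
                        idx = k
                return idx
            for item in by_note.get(note.note_id, []) + conf_by_note.get(note.note_id, []):
                old_par = par_of(item.fragment_span[0])
                shift = new_starts[old_par] - trimmed_starts[old_par]
                item.fragment_span = (
                    item.fragment_span[0] + shift,
                    item.fragment_span[1] + shift,
                )
                if isinstance(item, PlantedAdr):
                    item.drug_span = (item.drug_span[0] + shift, item.drug_span[1] + shift)
                    if item.term_span:
                        item.term_span = (
                            item.term_span[0] + shift,
                            item.term_span[1] + shift,
                        )
            text = new_text
        new_notes.append(replace(note, text=text))
    return new_notes, new_ledger


# ---------------------------------------------------------------------------
# annotation-ledger generation (manual-review flow arithmetic)


def generate_annotation_ledger(
    n_unique: int = 455,
    n_duplicates: int = 234,
    n_re_adrs: int = 58,
    seed: int = 0,
    n_patients: int = 62,
    lexicons: Lexicons | None = None,
    gap_days: int = 30,
    base_date: dt.date = dt.date(2023, 6, 1),
) -> list[AnnotationRecord]:
    """A synthetic manual-review ledger with planted duplicates and reADRs.

    Produces ``n_unique + n_duplicates + n_re_adrs`` records: distinct
    (patient, drug, term) keys for the unique ADRs, same-day repeats for
    duplicates, and recurrences more than ``gap_days`` later for reADRs
    (at most one per key). Shuffled record order; deterministic per seed.
    """
    if n_re_adrs > n_unique:
        raise ValueError("cannot plant more reADRs than unique records")
    lexicons = lexicons or load_bundled()
    rng = np.random.default_rng(seed)
    ingredients = sorted(
        e.ingredient_id for e in lexicons.drugs if not e.is_group
    )
    terms = sorted(t.term_code for t in lexicons.terms)
    capacity = n_patients * len(ingredients) * len(terms)
    if n_unique > capacity:
        raise ValueError(f"cannot place {n_unique} unique keys in {capacity} slots")

    used: set[tuple] = set()
    base_records: list[AnnotationRecord] = []
    while len(base_records) < n_unique:
        pid = f"P{int(rng.integers(1, n_patients + 1)):03d}"
        iid = ingredients[int(rng.integers(len(ingredients)))]
        code = terms[int(rng.integers(len(terms)))]
        key = (pid, iid, code)
        if key in used:
            continue
        used.add(key)
        term = lexicons.terms[code]
        date = base_date + dt.timedelta(days=int(rng.integers(0, 180)))
        base_records.append(
            AnnotationRecord(
                patient_id=pid,
                symptom_text=term.preferred_label,
                ingredient_ids=(iid,),
                term_code=code,
                trigger_word=None,
                context="",
                date=date,
                professional="physician",
                assessor_id=f"A{int(rng.integers(1, 3))}",
                naranjo_score=int(rng.integers(1, 6)),
                serious=term.serious,
            )
        )

    records: list[AnnotationRecord] = list(base_records)
    dup_choices = rng.integers(0, n_unique, size=n_duplicates)
    for idx in dup_choices:
        base = base_records[int(idx)]
        records.append(
            replace(base, assessor_id="A2", flags=frozenset({"duplicate"}))
        )
    re_choices = rng.choice(n_unique, size=n_re_adrs, replace=False)
    for idx in re_choices:
        base = base_records[int(idx)]
        gap = int(rng.integers(gap_days + 15, gap_days + 180))
        records.append(
            replace(
                base,
                date=base.date + dt.timedelta(days=gap),
                flags=frozenset({"re_adr"}),
            )
        )
    perm = rng.permutation(len(records))
    return [records[int(i)] for i in perm]
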