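"""Controlled vocabularies: drug lexicon, ADR term dictionary, trigger words
and the serious-event (IME-like) code list.

All four are delimited UTF-8 text files with a header row, one row per
surface form. Matching throughout the package is case-insensitive and
diacritics-insensitive; the folding used for lookup is length-preserving so
character offsets into folded text are valid offsets into the original.

File schemas (tab-separated, header required):

``drugs``
    surface, entity_id, kind, canonical_name, group_names
    kind is one of ``generic``, ``trade``, ``synonym``, ``group``;
    group_names is a ``;``-separated list of group names the ingredient
    belongs to (empty for group entries themselves).

``adr_terms``
    surface, term_code, preferred_label, organ_class

``triggers``
    surface, kind — kind one of ``causal_link``, ``allergy_label``,
    ``discontinuation``, ``refusal``.

``ime_codes``
    term_code — one code per row; terms with these codes are serious.

``indications``
    ingredient_id, term_code — reaction terms that are a known indication
    of the drug (used by the optional indication false-positive filter).
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "LexiconError",
    "DrugEntry",
    "AdrTerm",
    "TriggerWord",
    "DrugLexicon",
    "AdrTermIndex",
    "TriggerLexicon",
    "Lexicons",
    "fold",
    "load_drug_lexicon",
    "load_adr_terms",
    "load_ime_codes",
    "load_triggers",
    "load_indications",
    "load_bundled",
    "lookup_term",
    "bundled_path",
    "TRIGGER_KINDS",
]

TRIGGER_KINDS = frozenset({"causal_link", "allergy_label", "discontinuation", "refusal"})


class LexiconError(ValueError):
    """Raised when a vocabulary file is malformed or internally inconsistent."""


_FOLD_CACHE: dict[str, str] = {}


def _fold_char(c: str) -> str:
    try:
        return _FOLD_CACHE[c]
    except KeyError:
        decomposed = unicodedata.normalize("NFKD", c)
        base = "".join(ch for ch in decomposed if not unicodedata.combining(ch)) or c
        folded = base[0].lower()
        if len(folded) != 1:  # e.g. casefold expansions; keep length invariant
            folded = folded[0]
        _FOLD_CACHE[c] = folded
        return folded


def fold(text: str) -> str:
    """Length-preserving normalization: lowercase + diacritics stripped.

    ``len(fold(t)) == len(t)`` always holds, so offsets found in folded text
    address the same characters in the original.
    """
    table = {ord(c): _fold_char(c) for c in set(text) if not c.isascii() or c.isupper()}
    return text.translate(table).lower() if table else text.lower()


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DrugEntry:
    """One drug concept: a specific ingredient, or a drug group ("opiates")."""

    ingredient_id: str
    canonical_name: str
    trade_names: tuple[str, ...] = ()
    group_names: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()
    is_group: bool = False

    @property
    def surface_forms(self) -> tuple[str, ...]:
        return (self.canonical_name, *self.trade_names, *self.synonyms)


@dataclass(frozen=True)
class AdrTerm:
    """A coded reaction term (preferred-term level) with its synonyms."""

    term_code: str
    preferred_label: str
    surface_forms: tuple[str, ...]
    organ_class: str
    serious: bool = False


@dataclass(frozen=True)
class TriggerWord:
    surface: str
    kind: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise LexiconError("trigger surface must be non-empty")
        if self.kind not in TRIGGER_KINDS:
            raise LexiconError(f"unknown trigger kind {self.kind!r}")


# ---------------------------------------------------------------------------
# indexes


class _SurfaceIndex:
    """Shared machinery: folded surface form -> entity id, rejects ambiguity."""

    def __init__(self, what: str) -> None:
        self._what = what
        self._by_surface: dict[str, str] = {}
        self._raw_surface: dict[str, str] = {}

    def add(self, surface: str, entity_id: str, line: int | None = None) -> None:
        key = fold(surface)
        if not key.strip():
            raise LexiconError(f"{self._what}: empty surface form (line {line})")
        if key in self._by_surface:
            other = self._by_surface[key]
            if other != entity_id:
                raise LexiconError(
                    f"{self._what}: surface {surface!r} maps to both "
                    f"{other!r} and {entity_id!r}"
                )
            raise LexiconError(
                f"{self._what}: duplicate surface {surface!r} for {entity_id!r}"
            )
        self._by_surface[key] = entity_id
        self._raw_surface[key] = surface

    def get(self, surface: str) -> str | None:
        return self._by_surface.get(fold(surface))

    @property
    def surfaces(self) -> Mapping[str, str]:
        """Folded surface -> entity id."""
        return self._by_surface


class DrugLexicon:
    """Index over drug entries supporting case/diacritics-insensitive lookup.

    Group entries (e.g. "opiaten") are first-class: ``expand`` maps a group
    id to the ingredient ids that declare membership in that group, which is
    how group-level ADR attributions stay comparable with specific drugs.
    """

    def __init__(self, entries: Iterable[DrugEntry]) -> None:
        self.entries: dict[str, DrugEntry] = {}
        self._index = _SurfaceIndex("drug lexicon")
        for entry in entries:
            if not entry.canonical_name:
                raise LexiconError(f"{entry.ingredient_id}: empty canonical name")
            if entry.ingredient_id in self.entries:
                raise LexiconError(f"duplicate entity id {entry.ingredient_id!r}")
            self.entries[entry.ingredient_id] = entry
            for surface in entry.surface_forms:
                self._index.add(surface, entry.ingredient_id)
        # group membership: ingredient declares group names; match them to
        # the surface forms of group entries
        self._members: dict[str, set[str]] = {
            gid: set() for gid, e in self.entries.items() if e.is_group
        }
        group_by_name: dict[str, str] = {}
        for gid, entry in self.entries.items():
            if entry.is_group:
                for surface in entry.surface_forms:
                    group_by_name[fold(surface)] = gid
        for iid, entry in self.entries.items():
            if entry.is_group:
                continue
            for name in entry.group_names:
                gid = group_by_name.get(fold(name))
                if gid is not None:
                    self._members[gid].add(iid)

    def lookup(self, surface: str) -> DrugEntry | None:
        iid = self._index.get(surface)
        return self.entries[iid] if iid is not None else None

    @property
    def surfaces(self) -> Mapping[str, str]:
        return self._index.surfaces

    def is_group(self, entity_id: str) -> bool:
        return self.entries[entity_id].is_group

    def members(self, group_id: str) -> frozenset[str]:
        return frozenset(self._members.get(group_id, ()))

    def expand(self, entity_id: str) -> frozenset[str]:
        """Entity id -> itself plus, for groups, the member ingredient ids."""
        if entity_id in self._members:
            return frozenset({entity_id}) | self.members(entity_id)
        return frozenset({entity_id})

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())


class AdrTermIndex:
    def __init__(self, terms: Iterable[AdrTerm]) -> None:
        self.terms: dict[str, AdrTerm] = {}
        self._index = _SurfaceIndex("ADR term dictionary")
        for term in terms:
            if term.term_code in self.terms:
                raise LexiconError(f"duplicate term code {term.term_code!r}")
            if fold(term.preferred_label) not in {fold(s) for s in term.surface_forms}:
                raise LexiconError(
                    f"{term.term_code}: preferred label {term.preferred_label!r} "
                    "missing from surface forms"
                )
            self.terms[term.term_code] = term
            for surface in term.surface_forms:
                self._index.add(surface, term.term_code)

    def lookup(self, surface: str) -> AdrTerm | None:
        code = self._index.get(surface)
        return self.terms[code] if code is not None else None

    def __getitem__(self, term_code: str) -> AdrTerm:
        return self.terms[term_code]

    def __contains__(self, term_code: str) -> bool:
        return term_code in self.terms

    @property
    def surfaces(self) -> Mapping[str, str]:
        return self._index.surfaces

    def serious_codes(self) -> frozenset[str]:
        return frozenset(c for c, t in self.terms.items() if t.serious)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())


def lookup_term(surface: str, index: AdrTermIndex) -> AdrTerm | None:
    """Case- and diacritics-insensitive lookup of a reaction surface form."""
    return index.lookup(surface)


class TriggerLexicon:
    def __init__(self, triggers: Iterable[TriggerWord]) -> None:
        self.triggers: list[TriggerWord] = list(triggers)
        self._index = _SurfaceIndex("trigger list")
        self._kind: dict[str, str] = {}
        for t in self.triggers:
            self._index.add(t.surface, t.surface)
            self._kind[fold(t.surface)] = t.kind

    def kind_of(self, surface: str) -> str | None:
        return self._kind.get(fold(surface))

    @property
    def surfaces(self) -> Mapping[str, str]:
        return self._index.surfaces

    def __len__(self) -> int:
        return len(self.triggers)

    def __iter__(self):
        return iter(self.triggers)


@dataclass
class Lexicons:
    """The bundle the miner consumes."""

    drugs: DrugLexicon
    terms: AdrTermIndex
    triggers: TriggerLexicon
    indications: dict[str, frozenset[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loading / writing


def _read_rows(path: str | Path, columns: list[str]) -> list[tuple[int, dict[str, str]]]:
    path = Path(path)
    rows: list[tuple[int, dict[str, str]]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LexiconError(f"{path}: empty file, expected header {columns}")
        if [h.strip() for h in header] != columns:
            raise LexiconError(f"{path}: expected columns {columns}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(columns):
                raise LexiconError(
                    f"{path}: line {lineno}: expected {len(columns)} fields, got {len(row)}"
                )
            rows.append((lineno, dict(zip(columns, (c.strip() for c in row)))))
    return rows


_DRUG_COLUMNS = ["surface", "entity_id", "kind", "canonical_name", "group_names"]
_DRUG_KINDS = {"generic", "trade", "synonym", "group"}


def load_drug_lexicon(path: str | Path) -> DrugLexicon:
    """Load the tabular drug lexicon; rejects ambiguous surface forms."""
    by_id: dict[str, dict] = {}
    for lineno, row in _read_rows(path, _DRUG_COLUMNS):
        if row["kind"] not in _DRUG_KINDS:
            raise LexiconError(f"{path}: line {lineno}: unknown kind {row['kind']!r}")
        rec = by_id.setdefault(
            row["entity_id"],
            {"canonical": None, "trade": [], "synonyms": [], "groups": [], "is_group": False},
        )
        if row["kind"] in ("generic", "group"):
            if rec["canonical"] is not None:
                raise LexiconError(
                    f"{path}: line {lineno}: second canonical row for {row['entity_id']!r}"
                )
            rec["canonical"] = row["surface"]
            rec["is_group"] = row["kind"] == "group"
        elif row["kind"] == "trade":
            rec["trade"].append(row["surface"])
        else:
            rec["synonyms"].append(row["surface"])
        if row["canonical_name"]:
            rec.setdefault("declared_canonical", row["canonical_name"])
        for g in row["group_names"].split(";"):
            g = g.strip()
            if g and g not in rec["groups"]:
                rec["groups"].append(g)
    entries = []
    for eid, rec in sorted(by_id.items()):
        canonical = rec["canonical"] or rec.get("declared_canonical")
        if canonical is None:
            raise LexiconError(f"{path}: entity {eid!r} has no generic/group row")
        entries.append(
            DrugEntry(
                ingredient_id=eid,
                canonical_name=canonical,
                trade_names=tuple(rec["trade"]),
                group_names=tuple(rec["groups"]),
                synonyms=tuple(rec["synonyms"]),
                is_group=rec["is_group"],
            )
        )
    return DrugLexicon(entries)


def write_drug_lexicon(lexicon: DrugLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_DRUG_COLUMNS)
        for entry in lexicon:
            groups = ";".join(entry.group_names)
            kind = "group" if entry.is_group else "generic"
            writer.writerow([entry.canonical_name, entry.ingredient_id, kind,
                             entry.canonical_name, groups])
            for t in entry.trade_names:
                writer.writerow([t, entry.ingredient_id, "trade", entry.canonical_name, groups])
            for s in entry.synonyms:
                writer.writerow([s, entry.ingredient_id, "synonym", entry.canonical_name, groups])


_TERM_COLUMNS = ["surface", "term_code", "preferred_label", "organ_class"]


def load_ime_codes(path: str | Path) -> frozenset[str]:
    return frozenset(row["term_code"] for _, row in _read_rows(path, ["term_code"]))


def load_adr_terms(path: str | Path, ime_codes: frozenset[str] | str | Path = frozenset()) -> AdrTermIndex:
    """Load the reaction-term dictionary; ``serious`` is derived from the
    IME-like code list (a path or an already-loaded code set)."""
    if not isinstance(ime_codes, frozenset):
        ime_codes = load_ime_codes(ime_codes)
    by_code: dict[str, dict] = {}
    for lineno, row in _read_rows(path, _TERM_COLUMNS):
        rec = by_code.setdefault(
            row["term_code"], {"label": None, "organ": None, "surfaces": []}
        )
        for key, col in (("label", "preferred_label"), ("organ", "organ_class")):
            if rec[key] is None:
                rec[key] = row[col]
            elif rec[key] != row[col]:
                raise LexiconError(
                    f"{path}: line {lineno}: inconsistent {col} for {row['term_code']!r}"
                )
        rec["surfaces"].append(row["surface"])
    terms = [
        AdrTerm(
            term_code=code,
            preferred_label=rec["label"],
            surface_forms=tuple(rec["surfaces"]),
            organ_class=rec["organ"],
            serious=code in ime_codes,
        )
        for code, rec in sorted(by_code.items())
    ]
    return AdrTermIndex(terms)


def write_adr_terms(index: AdrTermIndex, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TERM_COLUMNS)
        for term in index:
            for surface in term.surface_forms:
                writer.writerow([surface, term.term_code, term.preferred_label, term.organ_class])


def load_triggers(path: str | Path) -> TriggerLexicon:
    return TriggerLexicon(
        TriggerWord(surface=row["surface"], kind=row["kind"])
        for _, row in _read_rows(path, ["surface", "kind"])
    )


def load_indications(path: str | Path) -> dict[str, frozenset[str]]:
    table: dict[str, set[str]] = {}
    for _, row in _read_rows(path, ["ingredient_id", "term_code"]):
        table.setdefault(row["ingredient_id"], set()).add(row["term_code"])
    return {k: frozenset(v) for k, v in table.items()}


def bundled_path(name: str) -> Path:
    """Path to one of the bundled toy vocabulary files (``drugs.tsv`` ...)."""
    return Path(resources.files("adrmine").joinpath("data", name))  # type: ignore[arg-type]


def load_bundled(language: str = "nl") -> Lexicons:
    """Load the bundled illustrative toy vocabularies.

    These stand in for the licensed national drug database, MedDRA/SNOMED-CT
    reaction vocabulary and the trigger inventory of a production deployment;
    they are small, open and user-replaceable. The drug and reaction files
    carry both Dutch and English surface forms as synonyms; the trigger list
    is language-specific.
    """
    if language not in ("nl", "en"):
        raise LexiconError(f"unknown lexicon language {language!r}")
    return Lexicons(
        drugs=load_drug_lexicon(bundled_path("drugs.tsv")),
        terms=load_adr_terms(bundled_path("adr_terms.tsv"), bundled_path("ime_codes.tsv")),
        triggers=load_triggers(bundled_path(f"triggers_{language}.tsv")),
        indications=load_indications(bundled_path("indications.tsv")),
    )
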