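import datetime as dt

import pytest

from adrmine import lexicons, synthdata
from adrmine.corpus_io import Note


@pytest.fixture(scope="session")
def lex():
    return lexicons.load_bundled()


@pytest.fixture(scope="session")
def lex_en():
    return lexicons.load_bundled("en")


@pytest.fixture
def make_note():
    counter = {"n": 0}

    def _make(
        text: str,
        patient_id: str = "P1",
        date: dt.date = dt.date(2023, 6, 1),
        category: str = "consultation",
        author_role: str = "physician",
    ) -> Note:
        counter["n"] += 1
        return Note(
            patient_id=patient_id,
            note_id=f"note{counter['n']}",
            category=category,
            author_role=author_role,
            specialty="geriatrics",
            timestamp=date,
            text=text,
        )

    return _make


@pytest.fixture(scope="session")
def small_corpus(lex):
    """A modest synthetic corpus (8 patients) shared across tests."""
    config = synthdata.SynthConfig(
        seed=7,
        patients={
            ("CZE", "geriatric"): 2,
            ("CZE", "orthopedic"): 2,
            ("JBZ", "geriatric"): 2,
            ("JBZ", "orthopedic"): 2,
        },
    )
    return synthdata.generate(config, lex) + (config,)
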