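from datetime import date

import pytest

from wearsurv.corpus import ClinicalNote
from wearsurv.lexicons import load_lexicon


@pytest.fixture(scope="session")
def wearable_lex():
    return load_lexicon("wearable")


@pytest.fixture(scope="session")
def af_lex():
    return load_lexicon("af")


@pytest.fixture(scope="session")
def action_lex():
    return load_lexicon("action")


@pytest.fixture(scope="session")
def event_lex():
    return load_lexicon("event")


def make_note(note_id="N1", patient_id="P1", note_date="2020-06-01",
              text="AF noted on Apple Watch."):
    return ClinicalNote(note_id, patient_id, date.fromisoformat(note_date), text)


@pytest.fixture
def note_factory():
    return make_note
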