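"""Shared fixtures: schemes, a worked-example document, small corpora."""

from __future__ import annotations

import pytest

from chqakit import GenConfig, generate_gold, load_scheme
from chqakit.corpus_tools import AnnotatorProfile, build_noisy_corpus


@pytest.fixture(scope="session")
def email_scheme():
    return load_scheme("chqa-email")


@pytest.fixture(scope="session")
def web_scheme():
    return load_scheme("chqa-web")


@pytest.fixture(scope="session")
def tb_example():
    """Synthetic reconstruction of the canonical tuberculosis question.

    A long consumer email asking, about a relative with active lung
    tuberculosis: what to do for her (treatment), whether it is contagious
    (susceptibility, triggered by the writer's own word "contages"), and
    who needs testing (diagnosis).  One PROBLEM entity ("ACTIVE LUNG TB")
    is the topic and the shared THEME of all three frames.
    """
    text = (
        "pls guide us . recently we found she has ACTIVE LUNG TB . "
        "so what we have to do for her ? is this contages ? "
        "who is the pople staying with her need to do test ?"
    )

    def span(word: str, occurrence: int = 0) -> tuple[int, int]:
        start = -1
        for _ in range(occurrence + 1):
            start = text.index(word, start + 1)
        return start, start + len(word)

    tb = span("ACTIVE LUNG TB")
    do = span("do")  # "to do for her", not the later "to do test"
    contages = span("contages")
    test = span("test")
    ann = "\n".join(
        [
            f"T1\tPROBLEM {tb[0]} {tb[1]}\tACTIVE LUNG TB",
            f"T2\tTREATMENT {do[0]} {do[1]}\tdo",
            f"T3\tSUSCEPTIBILITY {contages[0]} {contages[1]}\tcontages",
            f"T4\tDIAGNOSIS {test[0]} {test[1]}\ttest",
            "E1\tTREATMENT:T2 THEME:T1",
            "E2\tSUSCEPTIBILITY:T3 THEME:T1",
            "E3\tDIAGNOSIS:T4 THEME:T1",
            "A1\tTopic T1",
        ]
    )
    return text, ann


@pytest.fixture
def gold_corpus():
    return generate_gold(GenConfig(scheme="chqa-email", n_questions=8, seed=42))


@pytest.fixture
def noisy_pair(gold_corpus):
    """Gold corpus double-annotated by one good and one sloppier annotator."""
    profiles = [
        AnnotatorProfile("ann1", competence=0.95, spurious_rate=0.2,
                         span_jitter=1, type_confusion=0.02, seed=101),
        AnnotatorProfile("ann2", competence=0.8, spurious_rate=0.5,
                         span_jitter=1, type_confusion=0.08, seed=102),
    ]
    return build_noisy_corpus(gold_corpus, profiles)
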