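import pytest
from hypothesis import HealthCheck, settings

from speechmarkers.corpus_io import (
    Corpus,
    Participant,
    Segment,
    Session,
    tokenize_segment,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def pretagged_segment(question_id: int, tagged_text: str) -> Segment:
    """Segment built from 'surface/TAG ...' text via the fallback tokenizer."""
    tokens = tokenize_segment(tagged_text)
    return Segment(question_id, "".join(t.surface for t in tokens), tokens)


def make_session(pid: str, partner: str, tagged_texts: list[str]) -> Session:
    return Session(pid, partner, [
        pretagged_segment(i + 1, text) for i, text in enumerate(tagged_texts)
    ])


@pytest.fixture
def tiny_corpus() -> Corpus:
    """2 participants x 2 partners, pre-tokenized Japanese answers."""
    participants = [
        Participant("P01", 74, "female", "silver_centre", 28),
        Participant("P02", 83, "male", "day_service", 18),
    ]
    sessions = [
        make_session("P01", "human", [
            "あのー/filler 東京/proper_noun に/particle 住む/verb 。/symbol",
            "えーと/filler 今日/noun は/particle 散歩/noun です/auxiliary",
        ]),
        make_session("P01", "ai", [
            "はい/interjection 公園/noun に/particle 行く/verb",
            "京都/proper_noun が/particle 好き/adjective です/auxiliary",
        ]),
        make_session("P02", "human", [
            "うーん/filler 家/noun に/particle いる/verb",
        ]),
        make_session("P02", "ai", [
            "え？/interjection なに/other を/particle です/auxiliary か/particle",
        ]),
    ]
    return Corpus(participants, sessions)
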