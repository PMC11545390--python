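"""Transcript data model, JSON-Lines I/O, surface normalization and tokenization.

A *corpus* holds the answers of community-dwelling older adults to a fixed
inventory of up to 30 daily-conversation questions, recorded once with a
human interviewer and once with an on-screen AI agent.  Each session is one
JSON-Lines record; answer segments may ship pre-tokenized (surface + coarse
POS tag) or be tokenized on ingest through a pluggable tokenizer contract.

Coarse POS tags form a closed 11-tag set.  Mapping tables translate the
feature strings of the common Japanese morphological dictionaries
(IPADIC-style, UniDic-style) onto it; the mapping is longest-prefix based
and config-overridable, and unmapped native tags are an error unless the
caller explicitly opts into ``other``.
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import yaml

from .errors import CorpusParseError, CorpusValidationError, PosMappingError

logger = logging.getLogger(__name__)

#: Closed coarse POS tag set.  ``symbol`` marks punctuation-like tokens,
#: which the feature denominator excludes by default.
POS_TAGS: tuple[str, ...] = (
    "noun",
    "proper_noun",
    "verb",
    "adjective",
    "adverb",
    "particle",
    "auxiliary",
    "filler",
    "interjection",
    "symbol",
    "other",
)
_POS_SET = frozenset(POS_TAGS)

PARTNERS: tuple[str, ...] = ("human", "ai")
SEXES: tuple[str, ...] = ("male", "female", "unspecified")
FACILITIES: tuple[str, ...] = ("silver_centre", "day_service", "unspecified")

MAX_SEGMENTS = 30  # fixed question inventory: 30 items in 5 areas


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class Token:
    """One morphological unit: surface form plus coarse POS tag.

    ``pos_detail`` optionally keeps the analyzer-native feature string.
    Construction is deliberately unchecked for speed; :func:`validate_corpus`
    and :func:`read_corpus` enforce the invariants at the I/O boundary.
    """

    surface: str
    pos: str
    pos_detail: str | None = None


@dataclass(slots=True)
class Segment:
    """One question-answer unit: raw answer text and its tokens (may be empty)."""

    question_id: int
    text: str
    tokens: list[Token] = field(default_factory=list)


@dataclass(slots=True)
class Participant:
    id: str
    age: int
    sex: str = "unspecified"
    facility: str = "unspecified"
    mmse: int = 0


@dataclass(slots=True)
class Session:
    """One participant x partner conversation: an ordered list of segments."""

    participant_id: str
    partner: str
    segments: list[Segment] = field(default_factory=list)


@dataclass(slots=True)
class Corpus:
    participants: list[Participant] = field(default_factory=list)
    sessions: list[Session] = field(default_factory=list)

    def participant(self, participant_id: str) -> Participant:
        for p in self.participants:
            if p.id == participant_id:
                return p
        raise CorpusValidationError(f"unknown participant id {participant_id!r}")


# ---------------------------------------------------------------------------
# Surface normalization
# ---------------------------------------------------------------------------

# Katakana -> hiragana: fold the contiguous block U+30A1..U+30F6 down by 0x60.
# The long-vowel mark U+30FC is outside the block and is preserved as-is.
_KATA2HIRA = {cp: cp - 0x60 for cp in range(0x30A1, 0x30F7)}


def normalize_surface(text: str) -> str:
    """NFKC-normalize, fold katakana to hiragana, lowercase.

    Total and idempotent; used on both lexicon entries and token surfaces so
    matching is insensitive to script variant (katakana vs hiragana, full-
    vs half-width, ASCII case).
    """
    return unicodedata.normalize("NFKC", text).translate(_KATA2HIRA).lower()


@lru_cache(maxsize=65536)
def cached_normalize(surface: str) -> str:
    """Memoized :func:`normalize_surface` for hot counting loops."""
    return normalize_surface(surface)


# ---------------------------------------------------------------------------
# Tokenization contract
# ---------------------------------------------------------------------------

#: A tokenizer maps raw text to ordered (surface, native-tag) pairs.
Tokenizer = Callable[[str], Iterable[tuple[str, str]]]


def pretagged_tokenizer(text: str) -> Iterator[tuple[str, str]]:
    """Built-in fallback tokenizer for pre-tagged text.

    Splits on whitespace; each chunk must be ``surface/TAG`` where TAG is
    already a coarse tag.  Lets the whole pipeline run with no external
    morphological dictionary installed.
    """
    for chunk in text.split():
        surface, sep, tag = chunk.rpartition("/")
        if not sep or not surface:
            raise CorpusParseError(
                f"pre-tagged chunk {chunk!r} is not of the form 'surface/TAG'"
            )
        yield surface, tag


#: Identity mapping for tokenizers that already emit coarse tags.
IDENTITY_POS_MAP: Mapping[str, str] = {t: t for t in POS_TAGS}

#: IPADIC-style feature-string prefixes (e.g. "名詞,固有名詞,人名,...").
IPADIC_POS_MAP: Mapping[str, str] = {
    "名詞,固有名詞": "proper_noun",
    "名詞": "noun",
    "動詞": "verb",
    "形容詞": "adjective",
    "副詞": "adverb",
    "助詞": "particle",
    "助動詞": "auxiliary",
    "フィラー": "filler",
    "感動詞": "interjection",
    "記号": "symbol",
    "連体詞": "other",
    "接続詞": "other",
    "接頭詞": "other",
    "その他": "other",
}

#: UniDic-style prefixes; fillers live under 感動詞,フィラー.
UNIDIC_POS_MAP: Mapping[str, str] = {
    "名詞,固有名詞": "proper_noun",
    "代名詞": "noun",
    "名詞": "noun",
    "動詞": "verb",
    "形容詞": "adjective",
    "形状詞": "adjective",
    "副詞": "adverb",
    "助詞": "particle",
    "助動詞": "auxiliary",
    "感動詞,フィラー": "filler",
    "感動詞": "interjection",
    "補助記号": "symbol",
    "記号": "symbol",
    "連体詞": "other",
    "接続詞": "other",
    "接頭辞": "other",
    "接尾辞": "other",
    "その他": "other",
}


def map_native_pos(
    native: str, table: Mapping[str, str], *, on_unknown: str = "error"
) -> str:
    """Map an analyzer-native tag to a coarse tag by longest matching prefix.

    ``on_unknown="other"`` downgrades unmapped tags instead of raising; the
    default is to raise, naming the offending tag, so silent category loss
    has to be an explicit configuration choice.
    """
    best = None
    best_len = -1
    for prefix, coarse in table.items():
        if native.startswith(prefix) and len(prefix) > best_len:
            best, best_len = coarse, len(prefix)
    if best is None:
        if on_unknown == "other":
            return "other"
        raise PosMappingError(f"native POS tag {native!r} has no mapping")
    return best


def tokenize_segment(
    text: str,
    tokenizer: Tokenizer | None = None,
    pos_map: Mapping[str, str] | None = None,
    *,
    on_unknown: str = "error",
) -> list[Token]:
    """Tokenize raw text into coarse-tagged tokens, preserving surface order.

    With no arguments the pre-tagged fallback tokenizer and the identity
    mapping are used.  When a real mapping table is given the native feature
    string is retained in ``pos_detail``.
    """
    tokenizer = tokenizer or pretagged_tokenizer
    identity = pos_map is None or pos_map is IDENTITY_POS_MAP
    tokens: list[Token] = []
    for surface, native in tokenizer(text):
        if identity:
            if native not in _POS_SET:
                raise PosMappingError(
                    f"tag {native!r} is not in the coarse tag set {sorted(_POS_SET)}"
                )
            tokens.append(Token(surface, native))
        else:
            coarse = map_native_pos(native, pos_map, on_unknown=on_unknown)
            tokens.append(Token(surface, coarse, native))
    return tokens


def mecab_tokenizer() -> Tokenizer:  # pragma: no cover - optional dependency
    """Tokenizer backed by a MeCab binding (fugashi), imported lazily.

    Returns (surface, feature-string) pairs suitable for
    :data:`UNIDIC_POS_MAP` / :data:`IPADIC_POS_MAP`.
    """
    from fugashi import Tagger  # deferred: optional, not a hard dependency

    tagger = Tagger()

    def _tokenize(text: str) -> list[tuple[str, str]]:
        return [(word.surface, str(word.feature_raw or word.feature)) for word in tagger(text)]

    return _tokenize


def load_pos_map(path: str | Path) -> dict[str, str]:
    """Load a YAML mapping of native tag prefixes to coarse tags."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise CorpusValidationError(f"{path}: POS map must be a mapping")
    for native, coarse in raw.items():
        if coarse not in _POS_SET:
            raise CorpusValidationError(
                f"{path}: coarse tag {coarse!r} (for {native!r}) not in the closed tag set"
            )
    return dict(raw)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _validate_participant(p: Participant, where: str = "") -> None:
    if not p.id:
        raise CorpusValidationError(f"{where}participant id must be non-empty")
    if p.sex not in SEXES:
        raise CorpusValidationError(f"{where}unknown sex {p.sex!r}")
    if p.facility not in FACILITIES:
        raise CorpusValidationError(f"{where}unknown facility {p.facility!r}")
    if not 0 <= int(p.mmse) <= 30:
        raise CorpusValidationError(f"{where}MMSE {p.mmse} outside [0, 30]")


def _validate_session(s: Session, where: str = "") -> None:
    if s.partner not in PARTNERS:
        raise CorpusValidationError(
            f"{where}unknown partner label {s.partner!r} (expected one of {PARTNERS})"
        )
    if len(s.segments) > MAX_SEGMENTS:
        raise CorpusValidationError(
            f"{where}session has {len(s.segments)} segments (maximum {MAX_SEGMENTS})"
        )
    for seg in s.segments:
        if not 1 <= int(seg.question_id) <= MAX_SEGMENTS:
            raise CorpusValidationError(
                f"{where}question_id {seg.question_id} outside [1, {MAX_SEGMENTS}]"
            )
        for tok in seg.tokens:
            if not tok.surface:
                raise CorpusValidationError(f"{where}empty token surface")
            if tok.pos not in _POS_SET:
                raise CorpusValidationError(f"{where}unknown POS tag {tok.pos!r}")


def validate_corpus(corpus: Corpus) -> None:
    """Check all corpus invariants; raise :class:`CorpusValidationError` on the first violation."""
    ids = [p.id for p in corpus.participants]
    if len(ids) != len(set(ids)):
        raise CorpusValidationError("duplicate participant ids")
    known = set(ids)
    for p in corpus.participants:
        _validate_participant(p)
    seen: set[tuple[str, str]] = set()
    for s in corpus.sessions:
        _validate_session(s)
        if s.participant_id not in known:
            raise CorpusValidationError(
                f"session references unknown participant {s.participant_id!r}"
            )
        key = (s.participant_id, s.partner)
        if key in seen:
            raise CorpusValidationError(
                f"more than one session for participant {s.participant_id!r} with partner {s.partner!r}"
            )
        seen.add(key)


# ---------------------------------------------------------------------------
# JSON Lines I/O
# ---------------------------------------------------------------------------

def _token_to_dict(t: Token) -> dict:
    d = {"surface": t.surface, "pos": t.pos}
    if t.pos_detail is not None:
        d["pos_detail"] = t.pos_detail
    return d


def _session_record(corpus: Corpus, session: Session) -> dict:
    p = corpus.participant(session.participant_id)
    return {
        "participant": {
            "id": p.id,
            "age": p.age,
            "sex": p.sex,
            "facility": p.facility,
            "mmse": p.mmse,
        },
        "partner": session.partner,
        "segments": [
            {
                "question_id": seg.question_id,
                "text": seg.text,
                "tokens": [_token_to_dict(t) for t in seg.tokens],
            }
            for seg in session.segments
        ],
    }


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write one session per line as UTF-8 JSON Lines; byte-stable across runs."""
    validate_corpus(corpus)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for session in corpus.sessions:
            fh.write(json.dumps(_session_record(corpus, session), ensure_ascii=False,
                                separators=(",", ":")))
            fh.write("\n")
    return path


def _parse_record(record: dict, where: str) -> tuple[Participant, Session]:
    try:
        praw = record["participant"]
        partner = record["partner"]
        segs = record.get("segments", [])
        participant = Participant(
            id=str(praw["id"]),
            age=int(praw.get("age", 0)),
            sex=praw.get("sex", "unspecified"),
            facility=praw.get("facility", "unspecified"),
            mmse=int(praw["mmse"]),
        )
        segments = [
            Segment(
                question_id=int(s["question_id"]),
                text=str(s.get("text", "")),
                tokens=[
                    Token(str(t["surface"]), str(t["pos"]), t.get("pos_detail"))
                    for t in s.get("tokens", [])
                ],
            )
            for s in segs
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusParseError(f"{where}missing or ill-typed field: {exc}") from exc
    session = Session(participant.id, partner, segments)
    _validate_participant(participant, where)
    _validate_session(session, where)
    return participant, session


def read_corpus(path: str | Path, *, strict: bool = True) -> Corpus:
    """Read a JSON-Lines corpus; one validated session per non-blank line.

    In strict mode (default) the first bad line raises, naming the line
    number.  With ``strict=False`` rejected lines are logged with their line
    numbers and skipped.
    """
    path = Path(path)
    participants: dict[str, Participant] = {}
    sessions: list[Session] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            where = f"{path.name}:{lineno}: "
            try:
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(f"{where}malformed JSON: {exc}") from exc
                participant, session = _parse_record(record, where)
                prior = participants.get(participant.id)
                if prior is not None and prior != participant:
                    raise CorpusValidationError(
                        f"{where}participant {participant.id!r} re-declared with different metadata"
                    )
                key = (session.participant_id, session.partner)
                if key in seen:
                    raise CorpusValidationError(
                        f"{where}duplicate session for {key[0]!r} with partner {key[1]!r}"
                    )
            except (CorpusParseError, CorpusValidationError):
                if strict:
                    raise
                logger.warning("rejected corpus record at %s line %d", path, lineno)
                continue
            participants.setdefault(participant.id, participant)
            seen.add(key)
            sessions.append(session)
    if not sessions:
        logger.warning("corpus file %s contains no session records", path)
    return Corpus(list(participants.values()), sessions)
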