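"""Filler, proper-noun and listen-back counting and POS-ratio features.

The three speech markers compared across dialogue partners and cognitive
groups are:

* **fillers** -- semantically empty flow-keeping tokens (あのー, えーと, "un",
  ...), matched against a categorized lexicon after surface normalization;
* **proper nouns** -- tokens the morphological analysis tagged
  ``proper_noun``;
* **listen-backs** -- clarification requests ("え？", "はい？") detected in the
  opening window (default: first 10 code points) of an answer segment, at
  most one per segment, because a participant who did not catch the question
  asks back before answering.

Because participants talk different amounts, raw counts are normalized by
the session's total POS-tagged token count (symbols excluded by default)
and expressed per 100 tokens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .corpus_io import Segment, Session, Token, cached_normalize, normalize_surface
from .errors import (
    ConfigurationError,
    DegenerateSessionError,
    UntokenizedSegmentError,
)

RATIO_SCALE = 100.0  # ratios are reported per 100 denominator tokens

FEATURES: tuple[str, ...] = ("filler", "proper_noun", "listen_back")

#: POS tags accepted as filler evidence in ``pos_gated`` mode.  Analyzers
#: tag fillers either フィラー (-> filler) or 感動詞 (-> interjection).
FILLER_POS_GATE = frozenset({"filler", "interjection"})

FILLER_CATEGORIES: tuple[str, ...] = (
    "A-type", "An-type", "E-type", "En-type", "O-type", "N-type",
    "Etto-type", "Ano-type", "Maa-type", "Hai-type", "Iya-type", "Un-type",
    "Others",
)

# Target filler inventory, by category, in romanized and kana surface forms.
# Vowel types, lexical types and response words; "ano" is listed again under
# Others in the source inventory -- first-listed category wins (Ano-type).
_DEFAULT_FILLER_TABLE: dict[str, tuple[str, ...]] = {
    "A-type": ("a", "ā", "あ", "あー"),
    "An-type": ("an", "ān", "あん", "あーん"),
    "E-type": ("e", "ē", "え", "えー"),
    "En-type": ("en", "ēn", "えん", "えーん"),
    "O-type": ("o", "ō", "お", "おー"),
    "N-type": ("n", "n̄", "u", "ū", "ん", "んー", "う", "うー"),
    "Etto-type": ("etto", "ettō", "ēto", "eto", "to",
                  "えっと", "えっとー", "えーと", "えと", "と"),
    "Ano-type": ("ano", "anō", "あの", "あのー"),
    "Maa-type": ("ma", "mā", "ま", "まー"),
    "Hai-type": ("hai", "hāi", "はい", "はーい"),
    "Iya-type": ("iya", "iyā", "いや", "いやー"),
    "Un-type": ("un", "ūn", "うん", "うーん"),
    "Others": ("ano", "sono", "unto", "nanka", "nante iuka", "mō",
               "あの", "その", "うんと", "なんか", "なんていうか", "もー", "もう"),
}

#: Default clarification-request expressions (stored un-normalized; the
#: lexicon constructor normalizes, e.g. fullwidth ？ becomes ASCII ?).
DEFAULT_LISTENBACK_ENTRIES: tuple[str, ...] = (
    "え？", "えっ", "はい？", "は？", "なに？", "なんですか", "もういちど", "もう一度",
)

DEFAULT_LISTENBACK_WINDOW = 10  # code points of the normalized segment opening


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FillerLexicon:
    """Normalized filler surfaces with a unique category per entry."""

    category_of: Mapping[str, str]

    @property
    def entries(self) -> frozenset[str]:
        return frozenset(self.category_of)

    @classmethod
    def from_table(cls, table: Mapping[str, Iterable[str]]) -> "FillerLexicon":
        """Build from {category: [surfaces...]}; duplicate surfaces keep the
        first-listed category, so counts are unaffected and only the
        breakdown is resolved deterministically."""
        category_of: dict[str, str] = {}
        for category, surfaces in table.items():
            for surface in surfaces:
                norm = normalize_surface(surface)
                if not norm:
                    raise ConfigurationError(
                        f"filler lexicon entry {surface!r} normalizes to empty"
                    )
                category_of.setdefault(norm, category)
        if not category_of:
            raise ConfigurationError("filler lexicon is empty")
        return cls(category_of)


@dataclass(frozen=True)
class ListenBackLexicon:
    """Normalized clarification expressions plus the opening-window width."""

    entries: frozenset[str]
    window: int = DEFAULT_LISTENBACK_WINDOW

    @classmethod
    def from_entries(
        cls, entries: Iterable[str], window: int = DEFAULT_LISTENBACK_WINDOW
    ) -> "ListenBackLexicon":
        if window < 1:
            raise ConfigurationError(f"listen-back window must be >= 1, got {window}")
        normalized = frozenset(normalize_surface(e) for e in entries if e)
        if not normalized:
            raise ConfigurationError("listen-back lexicon is empty")
        return cls(normalized, window)


@lru_cache(maxsize=1)
def default_filler_lexicon() -> FillerLexicon:
    """The built-in categorized filler inventory (romanized + kana forms)."""
    return FillerLexicon.from_table(_DEFAULT_FILLER_TABLE)


@lru_cache(maxsize=1)
def default_listenback_lexicon() -> ListenBackLexicon:
    return ListenBackLexicon.from_entries(DEFAULT_LISTENBACK_ENTRIES)


def load_filler_lexicon(path: str | Path) -> FillerLexicon:
    """Load a YAML/JSON {category: [surfaces...]} filler lexicon."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: filler lexicon must map categories to lists")
    return FillerLexicon.from_table(raw)


def load_listenback_lexicon(path: str | Path) -> ListenBackLexicon:
    """Load a YAML/JSON {"window": int, "entries": [...]} listen-back lexicon."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "entries" not in raw:
        raise ConfigurationError(f"{path}: expected mapping with 'entries'")
    return ListenBackLexicon.from_entries(
        raw["entries"], int(raw.get("window", DEFAULT_LISTENBACK_WINDOW))
    )


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FillerCounts:
    total: int
    by_category: Mapping[str, int]


def count_fillers(
    tokens: Sequence[Token],
    lexicon: FillerLexicon | None = None,
    mode: str = "pos_gated",
) -> FillerCounts:
    """Count filler tokens, with a per-category breakdown summing to the total.

    ``pos_gated`` (default) requires the normalized surface to be a lexicon
    entry *and* the POS tag to be filler/interjection, which avoids false
    hits such as the quotative particle と.  ``surface_only`` drops the POS
    gate, for analyzers that rarely emit filler tags for bare "to"/"u".
    """
    if mode not in ("pos_gated", "surface_only"):
        raise ConfigurationError(f"unknown filler counting mode {mode!r}")
    lexicon = lexicon or default_filler_lexicon()
    category_of = lexicon.category_of
    gated = mode == "pos_gated"
    by: Counter[str] = Counter()
    for tok in tokens:
        if gated and tok.pos not in FILLER_POS_GATE:
            continue
        category = category_of.get(cached_normalize(tok.surface))
        if category is not None:
            by[category] += 1
    return FillerCounts(sum(by.values()), dict(by))


def count_proper_nouns(tokens: Sequence[Token]) -> int:
    """Number of tokens the morphological analysis tagged ``proper_noun``."""
    return sum(1 for tok in tokens if tok.pos == "proper_noun")


def segment_has_listen_back(segment: Segment, lexicon: ListenBackLexicon) -> bool:
    """True iff a lexicon entry occurs within the normalized opening window.

    Only a raw prefix (4x the window) is normalized: NFKC can contract at
    most two code points into one (combining voicing marks), so this always
    covers the first ``window`` normalized code points.
    """
    head = normalize_surface(segment.text[: lexicon.window * 4])[: lexicon.window]
    return any(entry in head for entry in lexicon.entries)


def count_listen_backs(
    segments: Sequence[Segment], lexicon: ListenBackLexicon | None = None
) -> int:
    """Number of segments opening with a clarification request (max one each)."""
    lexicon = lexicon or default_listenback_lexicon()
    return sum(1 for seg in segments if segment_has_listen_back(seg, lexicon))


# ---------------------------------------------------------------------------
# Per-session feature profile
# ---------------------------------------------------------------------------

@dataclass(slots=True, frozen=True)
class FeatureProfile:
    """Per-session marker counts and their per-100-token ratios."""

    participant_id: str
    partner: str
    token_total: int
    filler_count: int
    proper_noun_count: int
    listenback_count: int
    filler_ratio: float
    proper_noun_ratio: float
    listenback_ratio: float

    def ratio(self, feature: str) -> float:
        try:
            return {
                "filler": self.filler_ratio,
                "proper_noun": self.proper_noun_ratio,
                "listen_back": self.listenback_ratio,
            }[feature]
        except KeyError:
            raise ConfigurationError(f"unknown feature {feature!r}") from None


def compute_profile(
    session: Session,
    fillers: FillerLexicon | None = None,
    listenbacks: ListenBackLexicon | None = None,
    mode: str = "pos_gated",
    *,
    exclude_symbols: bool = True,
) -> FeatureProfile:
    """Pool counts over all segments of a session and derive ratios.

    The denominator is the total number of POS-tagged tokens, excluding
    ``symbol`` tokens by default (punctuation is a transcription artifact);
    pass ``exclude_symbols=False`` to keep them.  A session with no
    denominator tokens is an error, never a silent NaN.
    """
    untokenized = [s.question_id for s in session.segments if s.text and not s.tokens]
    if untokenized:
        raise UntokenizedSegmentError(
            f"session ({session.participant_id!r}, {session.partner!r}) has "
            f"untokenized segments with question_id {untokenized}; run a tokenizer first"
        )
    tokens = [t for seg in session.segments for t in seg.tokens]
    if exclude_symbols:
        token_total = sum(1 for t in tokens if t.pos != "symbol")
    else:
        token_total = len(tokens)
    if token_total == 0:
        raise DegenerateSessionError(
            f"session ({session.participant_id!r}, {session.partner!r}) has no denominator tokens"
        )
    filler_count = count_fillers(tokens, fillers, mode).total
    proper_count = count_proper_nouns(tokens)
    listenback_count = count_listen_backs(session.segments, listenbacks)
    scale = RATIO_SCALE / token_total
    return FeatureProfile(
        participant_id=session.participant_id,
        partner=session.partner,
        token_total=token_total,
        filler_count=filler_count,
        proper_noun_count=proper_count,
        listenback_count=listenback_count,
        filler_ratio=filler_count * scale,
        proper_noun_ratio=proper_count * scale,
        listenback_ratio=listenback_count * scale,
    )


# ---------------------------------------------------------------------------
# Tabular export (also the classifier-ready labeled text table)
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = [
    "participant_id", "partner", "token_total",
    "filler_count", "proper_noun_count", "listenback_count",
    "filler_ratio", "proper_noun_ratio", "listenback_ratio",
]


def profiles_to_frame(profiles: Sequence[FeatureProfile]) -> pd.DataFrame:
    """One row per (participant, partner) with all profile fields."""
    return pd.DataFrame(
        [{c: getattr(p, c) for c in _PROFILE_COLUMNS} for p in profiles],
        columns=_PROFILE_COLUMNS,
    )


def profiles_from_frame(frame: pd.DataFrame) -> list[FeatureProfile]:
    """Inverse of :func:`profiles_to_frame` (extra columns are ignored)."""
    missing = [c for c in _PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"feature table is missing columns {missing}")
    return [
        FeatureProfile(
            participant_id=str(row.participant_id),
            partner=str(row.partner),
            token_total=int(row.token_total),
            filler_count=int(row.filler_count),
            proper_noun_count=int(row.proper_noun_count),
            listenback_count=int(row.listenback_count),
            filler_ratio=float(row.filler_ratio),
            proper_noun_ratio=float(row.proper_noun_ratio),
            listenback_ratio=float(row.listenback_ratio),
        )
        for row in frame.itertuples(index=False)
    ]
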