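"""Seeded generator of pre-tokenized synthetic conversation corpora.

The study's recordings are available only on request, so this module
produces corpora with the *statistical* structure the analysis assumes:
two sessions (human, AI) per participant, ~17 participants per cognitive
group, 30 answer segments per session of roughly one minute of Japanese
speech each (~300 tokens), and per-cell filler / proper-noun / listen-back
ratio means and SDs calibrated to the observed group x partner summaries.

Noise model.  Each session's target ratio for a feature is a zero-censored
normal draw ``max(0, mean + sd * (sqrt(b)*z_p + sqrt(1-b)*z_s))`` where
``z_p`` is a participant effect shared by that participant's two sessions,
``z_s`` is session noise, and ``b`` (default 0.7) is the between-participant
variance share.  The shared effect is what gives paired partner contrasts
their power.  Token identities are then assigned multinomially within each
segment so that expected per-session counts match the targets: filler
tokens are drawn from the built-in filler lexicon (tagged ``filler``),
proper-noun tokens from a small name inventory, the remainder from a
filler-free common-word inventory.  Listen-back expressions are prepended
to segment openings with a per-segment probability matching the target
listen-back ratio -- which also imposes a structural ceiling of one
clarification per segment, i.e. a maximum attainable listen-back ratio of
``100 * S / N`` per 100 tokens; :func:`expected_profile` accounts for it.

Vocabulary inventories are deliberately tiny: they exist to exercise the
matching pipeline, not to be linguistically realistic.  Generated corpora
are fully tokenized, validate against the corpus schema, and are byte-
identical for a fixed seed.  Token objects inside a generated corpus may be
shared between positions; treat generated corpora as immutable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.stats import norm

from .corpus_io import Corpus, Participant, Segment, Session, Token
from .errors import ConfigurationError
from .features import (
    DEFAULT_LISTENBACK_ENTRIES,
    FEATURES,
    RATIO_SCALE,
    default_filler_lexicon,
    normalize_surface,
)
from .grouping import GROUPS

PARTNERS = ("human", "ai")


@dataclass(frozen=True)
class CellParams:
    """Per-(group, partner) ratio means/SDs, all per 100 tokens."""

    filler_ratio_mean: float
    filler_ratio_sd: float
    proper_ratio_mean: float
    proper_ratio_sd: float
    listenback_ratio_mean: float
    listenback_ratio_sd: float

    def mean(self, feature: str) -> float:
        return {"filler": self.filler_ratio_mean,
                "proper_noun": self.proper_ratio_mean,
                "listen_back": self.listenback_ratio_mean}[feature]

    def sd(self, feature: str) -> float:
        return {"filler": self.filler_ratio_sd,
                "proper_noun": self.proper_ratio_sd,
                "listen_back": self.listenback_ratio_sd}[feature]


#: Calibration defaults: observed mean/SD of each ratio per cognitive group
#: (high = silver human-resource centre, low = day-service centre) and
#: dialogue partner.
DEFAULT_CELLS: Mapping[tuple[str, str], CellParams] = {
    ("high", "human"): CellParams(11.69, 2.18, 1.34, 0.31, 0.04, 0.08),
    ("high", "ai"): CellParams(7.03, 2.69, 2.55, 0.73, 0.03, 0.08),
    ("low", "human"): CellParams(11.01, 2.72, 1.39, 0.87, 0.17, 0.25),
    ("low", "ai"): CellParams(11.26, 3.30, 1.36, 1.18, 0.37, 0.28),
}

#: Cohort age mean/SD and male share per group, matching the two facilities.
_AGE_PARAMS = {"high": (74.35, 5.3), "low": (83.06, 4.78)}
_MALE_SHARE = {"high": 9 / 17, "low": 3 / 17}
_FACILITY = {"high": "silver_centre", "low": "day_service"}


@dataclass(frozen=True)
class GeneratorConfig:
    n_high: int = 17
    n_low: int = 17
    cells: Mapping[tuple[str, str], CellParams] = field(
        default_factory=lambda: dict(DEFAULT_CELLS)
    )
    segments_per_session: int = 30
    tokens_per_segment_mean: float = 300.0
    tokens_per_segment_sd: float = 60.0
    mmse_high: tuple[int, int] = (24, 30)
    mmse_low: tuple[int, int] = (0, 23)
    between_participant_share: float = 0.7
    seed: int = 0


def validate_config(config: GeneratorConfig) -> None:
    if config.n_high < 2 or config.n_low < 2:
        raise ConfigurationError("cohort sizes must be >= 2 per group")
    if not 1 <= config.segments_per_session <= 30:
        raise ConfigurationError("segments_per_session must be in [1, 30]")
    if config.tokens_per_segment_mean <= 0:
        raise ConfigurationError("tokens_per_segment_mean must be > 0")
    if config.tokens_per_segment_sd < 0:
        raise ConfigurationError("tokens_per_segment_sd must be >= 0")
    if not 0.0 <= config.between_participant_share <= 1.0:
        raise ConfigurationError("between_participant_share must be in [0, 1]")
    for group in GROUPS:
        for partner in PARTNERS:
            if (group, partner) not in config.cells:
                raise ConfigurationError(f"missing cell parameters for {(group, partner)}")
            cell = config.cells[(group, partner)]
            for feature in FEATURES:
                if cell.mean(feature) < 0 or cell.sd(feature) < 0:
                    raise ConfigurationError(
                        f"cell {(group, partner)}: negative mean or sd for {feature}"
                    )
            if cell.filler_ratio_mean + cell.proper_ratio_mean > RATIO_SCALE:
                raise ConfigurationError(
                    f"cell {(group, partner)}: filler + proper-noun mean ratios exceed "
                    f"{RATIO_SCALE} per {RATIO_SCALE} tokens"
                )
    for lo, hi in (config.mmse_high, config.mmse_low):
        if not (0 <= lo <= hi <= 30):
            raise ConfigurationError("MMSE ranges must satisfy 0 <= lo <= hi <= 30")


# ---------------------------------------------------------------------------
# Vocabulary inventories (small, fixed; they exercise matching, nothing more)
# ---------------------------------------------------------------------------

_PROPER_SURFACES = (
    "東京", "新宿", "渋谷", "銀座", "上野", "横浜", "大阪", "京都",
    "田中", "佐藤", "鈴木", "富士山",
)

_COMMON_WORDS = (
    ("今日", "noun"), ("天気", "noun"), ("家", "noun"), ("時間", "noun"),
    ("公園", "noun"), ("散歩", "noun"), ("友達", "noun"), ("買い物", "noun"),
    ("元気", "noun"), ("音楽", "noun"),
    ("行く", "verb"), ("見る", "verb"), ("食べる", "verb"), ("思う", "verb"),
    ("話す", "verb"),
    ("が", "particle"), ("を", "particle"), ("に", "particle"), ("で", "particle"),
    ("です", "auxiliary"), ("ます", "auxiliary"),
    ("とても", "adverb"), ("毎日", "adverb"),
    ("楽しい", "adjective"),
)

#: Clarification openers the generator can prepend (single tokens).
_LISTENBACK_WORDS = (("え?", "interjection"), ("はい?", "interjection"),
                     ("なに?", "interjection"))


def _filler_sampling_tokens() -> tuple[Token, ...]:
    """Kana filler surfaces, excluding any whose normalized form contains a
    clarification expression as a substring (えっと would false-trigger
    listen-back detection when it lands in a segment's opening window)."""
    listenbacks = [normalize_surface(e) for e in DEFAULT_LISTENBACK_ENTRIES]
    surfaces = [
        s for s in default_filler_lexicon().entries
        if any(ord(ch) >= 0x3040 for ch in s)
        and not any(lb in s for lb in listenbacks)
    ]
    return tuple(Token(s, "filler") for s in sorted(surfaces))


_FILLER_TOKENS = _filler_sampling_tokens()
_PROPER_TOKENS = tuple(Token(s, "proper_noun") for s in _PROPER_SURFACES)
_COMMON_TOKENS = tuple(Token(s, p) for s, p in _COMMON_WORDS)
_LISTENBACK_TOKENS = tuple(Token(s, p) for s, p in _LISTENBACK_WORDS)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_targets(
    rng: np.random.Generator, cell: CellParams, z_participant: np.ndarray, share: float
) -> np.ndarray:
    """Zero-censored session target ratios (filler, proper, listen-back)."""
    means = np.array([cell.mean(f) for f in FEATURES])
    sds = np.array([cell.sd(f) for f in FEATURES])
    z_session = rng.standard_normal(3)
    raw = means + sds * (math.sqrt(share) * z_participant
                         + math.sqrt(1.0 - share) * z_session)
    return np.clip(raw, 0.0, None)


def _build_session(
    rng: np.random.Generator,
    participant_id: str,
    partner: str,
    cell: CellParams,
    z_participant: np.ndarray,
    config: GeneratorConfig,
) -> Session:
    targets = _draw_targets(rng, cell, z_participant, config.between_participant_share)
    n_segments = config.segments_per_session
    lengths = np.maximum(
        1,
        np.rint(rng.normal(config.tokens_per_segment_mean,
                           config.tokens_per_segment_sd, n_segments)),
    ).astype(int)
    total = int(lengths.sum())

    p_filler = targets[0] / RATIO_SCALE
    p_proper = targets[1] / RATIO_SCALE
    if p_filler + p_proper > 1.0:  # extreme draws under very large SDs
        scale = 1.0 / (p_filler + p_proper)
        p_filler *= scale
        p_proper *= scale
    counts = rng.multinomial(lengths, [p_filler, p_proper, 1.0 - p_filler - p_proper])

    # One clarification opener at most per segment; its probability matches
    # the target ratio against the realized token total (capped at 1).
    q = min(targets[2] * total / (RATIO_SCALE * n_segments), 1.0)
    hits = rng.random(n_segments) < q

    segments = []
    for i in range(n_segments):
        n_f, n_p, n_c = counts[i]
        toks = (
            [_FILLER_TOKENS[j] for j in rng.integers(0, len(_FILLER_TOKENS), n_f)]
            + [_PROPER_TOKENS[j] for j in rng.integers(0, len(_PROPER_TOKENS), n_p)]
            + [_COMMON_TOKENS[j] for j in rng.integers(0, len(_COMMON_TOKENS), n_c)]
        )
        order = rng.permutation(len(toks))
        toks = [toks[j] for j in order]
        if hits[i]:
            toks.insert(0, _LISTENBACK_TOKENS[rng.integers(0, len(_LISTENBACK_TOKENS))])
        segments.append(
            Segment(question_id=i + 1, text="".join(t.surface for t in toks),
                    tokens=toks)
        )
    return Session(participant_id, partner, segments)


def generate_cohort(config: GeneratorConfig | None = None) -> Corpus:
    """Generate a full two-session-per-participant corpus, deterministically per seed."""
    config = config or GeneratorConfig()
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    participants: list[Participant] = []
    sessions: list[Session] = []
    plan = (("high", config.n_high, "H", config.mmse_high),
            ("low", config.n_low, "L", config.mmse_low))
    for group, n, prefix, (mmse_lo, mmse_hi) in plan:
        age_mean, age_sd = _AGE_PARAMS[group]
        for i in range(n):
            pid = f"{prefix}{i + 1:02d}"
            mmse = int(rng.integers(mmse_lo, mmse_hi + 1))
            age = int(np.clip(round(rng.normal(age_mean, age_sd)), 65, 99))
            sex = "male" if rng.random() < _MALE_SHARE[group] else "female"
            participants.append(Participant(pid, age, sex, _FACILITY[group], mmse))
            z_participant = rng.standard_normal(3)
            for partner in PARTNERS:
                sessions.append(
                    _build_session(rng, pid, partner,
                                   config.cells[(group, partner)],
                                   z_participant, config)
                )
    return Corpus(participants, sessions)


# ---------------------------------------------------------------------------
# Closed-form expectations
# ---------------------------------------------------------------------------

def _censored_normal_mean(mu: float, sigma: float, cap: float | None = None) -> float:
    """E[min(max(X, 0), cap)] for X ~ N(mu, sigma^2).

    With a = -mu/sigma and b = (cap-mu)/sigma:
    E = mu*(Phi(b)-Phi(a)) + sigma*(phi(a)-phi(b)) + cap*(1-Phi(b)),
    reducing to mu*(1-Phi(a)) + sigma*phi(a) without a cap.
    """
    if sigma <= 0:
        v = max(mu, 0.0)
        return min(v, cap) if cap is not None else v
    a = -mu / sigma
    if cap is None:
        return mu * norm.sf(a) + sigma * norm.pdf(a)
    b = (cap - mu) / sigma
    return (mu * (norm.cdf(b) - norm.cdf(a))
            + sigma * (norm.pdf(a) - norm.pdf(b))
            + cap * norm.sf(b))


def expected_profile(
    config: GeneratorConfig, group: str, partner: str
) -> dict[str, float]:
    """Expected extracted ratios for one cell, censoring-corrected.

    Applies the zero-censoring correction for all features and, for
    listen-backs, the one-per-segment capacity cap ``100/tokens_mean``
    (the expected maximum ratio when every segment opens with a
    clarification).  The small denominator inflation caused by prepended
    clarification tokens (< 0.5% at default sizes) is neglected.
    """
    try:
        cell = config.cells[(group, partner)]
    except KeyError:
        raise KeyError(f"no cell parameters for {(group, partner)!r}") from None
    cap = RATIO_SCALE / config.tokens_per_segment_mean
    return {
        "filler": _censored_normal_mean(cell.filler_ratio_mean, cell.filler_ratio_sd),
        "proper_noun": _censored_normal_mean(cell.proper_ratio_mean, cell.proper_ratio_sd),
        "listen_back": _censored_normal_mean(
            cell.listenback_ratio_mean, cell.listenback_ratio_sd, cap=cap
        ),
    }


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a GeneratorConfig from YAML; omitted fields keep their defaults.

    Cell structure::

        cells:
          high:
            human: {filler: [11.69, 2.18], proper_noun: [1.34, 0.31],
                    listen_back: [0.04, 0.08]}
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: generator config must be a mapping")
    config = GeneratorConfig()
    cells = dict(DEFAULT_CELLS)
    if "cells" in raw:
        for group, partners in raw.pop("cells").items():
            for partner, feats in partners.items():
                try:
                    cells[(group, partner)] = CellParams(
                        *feats["filler"], *feats["proper_noun"], *feats["listen_back"]
                    )
                except (KeyError, TypeError) as exc:
                    raise ConfigurationError(
                        f"{path}: bad cell spec for ({group}, {partner}): {exc}"
                    ) from exc
    simple = {}
    for key in ("n_high", "n_low", "segments_per_session", "tokens_per_segment_mean",
                "tokens_per_segment_sd", "between_participant_share", "seed"):
        if key in raw:
            simple[key] = raw.pop(key)
    for key in ("mmse_high", "mmse_low"):
        if key in raw:
            simple[key] = tuple(raw.pop(key))
    if raw:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(raw)}")
    config = replace(config, cells=cells, **simple)
    validate_config(config)
    return config
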