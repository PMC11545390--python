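# Methods

## The measurement model

Each participant contributes two sessions (partner ∈ {human, ai}), each
session up to 30 answer segments keyed to a fixed question inventory.
After tokenization, three marker counts are pooled over a session's
segments and normalized by the session's denominator *N* — the number of
POS-tagged tokens excluding `symbol` tokens (punctuation is a
transcription artifact; the exclusion is a toggle) — into per-100-token
ratios. The ratio scale is a single constant (`features.RATIO_SCALE`),
chosen so the generator's calibration defaults (cell means like 11.69 or
0.04) are unit-consistent with the extracted quantities.

**Fillers.** Matching is exact on the normalized surface against a
categorized lexicon (12 named categories plus *Others*; romanized and kana
forms). Normalization is NFKC, katakana→hiragana folding (U+30A1–U+30F6;
the long-vowel mark ー is preserved) and lowercasing, applied identically
to lexicon entries and token surfaces, so matching is invariant to script
variant. A surface listed under two categories keeps the first-listed one
(あの → Ano-type, not Others); this affects only the per-category
breakdown, never the total. The default counting mode is **POS-gated**:
a token counts only if its surface is in the lexicon *and* its tag is
`filler`/`interjection`. The gate exists because the lexicon contains bare
と and う, which as particles/verb endings would otherwise produce massive
false counts; `surface_only` mode is retained for analyzers that rarely
emit filler tags for those forms.

**Proper nouns.** A pure tag count (`pos == "proper_noun"`); the mapping
tables send 名詞,固有名詞-prefixed native features there by
longest-prefix match.

**Listen-backs.** A segment contributes 1 (at most) iff a clarification
expression occurs as a substring of the first *w* code points (default
w = 10) of the normalized segment text — clarifications happen at the
opening of an answer. The expression inventory is configurable; the
default (え？, えっ, はい？, は？, なに？, なんですか, もういちど, もう一度) is a
documented package choice, since only English glosses of the expressions
are published. Only a 4·w raw prefix is normalized before windowing: NFKC
contracts at most two code points into one (combining voicing marks), so
the margin always covers the window.

## Grouping and the comparison battery

Participants with MMSE > 23 form the high cognitive-function group;
23 or below (the conventional suspected-dementia side of the cutoff) is
low. The cutoff is a parameter (`--cutoff`), e.g. 26 for the split used by
text classifiers.

The battery crosses the three markers with six contrasts:

| contrast | samples | test |
|---|---|---|
| partner_all | human vs ai ratios, all participants | paired |
| group_all | per-participant mean of both sessions, high vs low | Welch |
| partner_within_high / _low | human vs ai within one group | paired |
| group_within_ai / _human | high vs low within one partner | Welch |

Sign conventions: partner contrasts are human − ai; group contrasts are
high − low. Between-group comparisons default to Welch's test because the
groups are independent samples; an `index_paired` option pairs the sorted
cohorts by index instead, reproducing analyses that treated those
comparisons as paired, without endorsing that choice. `group_all` defaults
to per-participant session means (keeps observations independent);
`pooling="stack"` enters both sessions separately. No multiple-testing
correction is applied by default (18 raw p-values, annotated at the 0.05
and 0.01 thresholds); a clearly labeled Holm adjustment is available.

t statistics and Welch–Satterthwaite degrees of freedom are computed from
their closed forms; two-tailed p-values via the regularized incomplete
beta function `p = I_{ν/(ν+t²)}(ν/2, ½)` (scipy's `betainc`). Degenerate
inputs are errors, never NaNs: n < 2, zero-variance differences, both
group variances zero, a participant missing one session, an empty group.
Inside the battery these are captured per contrast as explicit skip
records so the 18-cell grid is always complete.

## The synthetic cohort

The generator emulates the *statistical* structure the analysis assumes,
not Japanese conversation. Defaults: 17 participants per group; MMSE
uniform on 24–30 (high) and 0–23 (low); ages and sex ratios matching the
two recruiting facilities; 30 segments per session; segment lengths
normal(300, 60) truncated at 1 token (~one minute of Japanese speech per
answer); per-cell ratio means/SDs calibrated to the published
group × partner summaries.

Per session and marker, the target ratio is a **zero-censored normal**,

    r = max(0, μ_cell + σ_cell · (√b · z_participant + √(1−b) · z_session)),

with b = 0.7 the between-participant variance share (configurable; no
published decomposition exists — the shared participant effect is what
gives paired contrasts realistic power). Censoring was chosen over
rejection truncation because a participant effect shared across two
sessions cannot be re-drawn per session without distorting the
decomposition, and censoring has exact closed-form expectations.

Token identities are then assigned per segment by a multinomial over
(filler, proper noun, common word) with probabilities r/100, so expected
session counts match the targets; surfaces are drawn from small fixed
inventories (they exercise the matching pipeline, nothing more). Filler
positions are not modeled — the analysis never uses position — but
clarification openers are prepended to segment starts with per-segment
probability q = min(r_lb·N/(100·S), 1), because detection is defined on
the opening window. Filler surfaces whose normalized form contains a
clarification expression as a substring (えっと ⊃ えっ) are excluded from
the *sampling* inventory (not the lexicon) so detection is not
false-triggered.

`expected_profile` returns the closed-form expectation of what the
extraction pipeline recovers: the censored-normal mean
E[max(X, 0)] = μ·Φ(μ/σ) + σ·φ(μ/σ), and for listen-backs additionally the
**capacity cap** E[min(max(X, 0), c)] with c = 100/m̄ (m̄ = mean tokens per
segment): with at most one countable clarification per segment, the
attainable ratio is bounded by 100·S/N ≈ 0.333 at the defaults. The
published low×AI cell mean (0.37) exceeds that bound, so the generator
cannot reach it under the stated session geometry; the cap makes the
expectation honest rather than aspirational. The ~0.5% denominator
inflation from prepended openers is neglected (it is an order of magnitude
below the tightest test tolerance).

## What passing tests do and do not show

Parameter recovery (cell means over 200 seeded cohorts within
±0.5/±0.3/±0.05 of the corrected expectations), effect-direction
reproduction (significant at p < 0.05 with the expected sign in ≥ 90% of
100 cohorts) and type-I calibration (each contrast rejecting in 5% ± 2pp
of 1,000 null cohorts) validate the *pipeline* — counting, grouping,
testing — under a known generative model. They do not validate the
generative model against real elderly speech: real fillers are positionally
clustered, segment lengths and markers are correlated with cognitive
status in ways the cells do not capture, and ASR/transcription noise is
absent.

One measured consequence of the capacity cap and censoring: the
listen-back *partner* contrast is structurally attenuated at the default
calibration (the low×AI cell is pulled down to ≈ 0.25 while zero-censoring
pushes the human cells up), and its significant-direction rate over
replicate cohorts — computed by the acceptance suite and
`scripts/acceptance.py` — is only ≈ 50–60%, unlike the other three
headline directions (≈ 100%). A cohort of 34 with this cell geometry
simply does not carry that effect reliably; the corresponding acceptance
check is left failing by design rather than recalibrated, because the cell
parameters are the study conditions, not free dials.

## Problem sizes and numerical choices

* Recovery uses 200 seeds and direction rates 100 seeds at full scale
  (~612k tokens per cohort, ≈ 0.4 s each); the null calibration uses 1,000
  seeds on a scaled-down geometry (6 segments × ~40 tokens, n = 17 per
  group) — the null distribution of a t statistic does not depend on the
  corpus size, so the small geometry measures the same property.
* Seeds: every stochastic component flows from one `numpy` `default_rng`
  seed; identical seeds give byte-identical corpora on disk.
* p-value accuracy: verified to 1e-10 against high-precision numeric
  integration of the t density; t statistics to 1e-9 against closed forms
  and an independent reference implementation.
* JSON-Lines output is UTF-8 with unescaped Japanese, compact separators,
  one session per line; corpora round-trip field-for-field. A participant
  with no sessions has no record to live in and would be dropped on write;
  the generator never produces such corpora.

## Known limitations

* Filler matching is token-exact; multi-token fillers ("nante iuka" as
  three tokens) are only matched if the tokenizer keeps them whole.
* The MeCab adapter is untested where no MeCab binding is installed; the
  POS-mapping tables are exercised against simulated analyzer output.
* The generator's MMSE draw is uniform within the group range; MMSE feeds
  only the grouping, so its distribution is immaterial to the battery.
* Whether the published SDs are across-participant SDs of ratios (as the
  generator assumes) or SDs of raw counts cannot be determined from the
  source; the calibration would differ in the latter case.
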