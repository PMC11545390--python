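"""MMSE-based cognitive-function grouping.

The Mini-Mental State Examination (MMSE) is a 30-point cognitive screen.
A score of 23 or below conventionally indicates suspected dementia, so the
default cutoff assigns participants with MMSE > 23 to the *high* cognitive
function group and everyone else (boundary included) to *low*.  The cutoff
is a parameter: e.g. 26 matches the split some text classifiers use.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_io import Corpus
from .errors import CorpusValidationError

DEFAULT_CUTOFF = 23

GROUPS: tuple[str, ...] = ("high", "low")


@dataclass(frozen=True)
class GroupAssignment:
    participant_id: str
    group: str
    cutoff_used: int


def assign_group(mmse: int, cutoff: int = DEFAULT_CUTOFF) -> str:
    """``high`` iff mmse > cutoff; the boundary score itself is ``low``."""
    if not 0 <= mmse <= 30:
        raise CorpusValidationError(f"MMSE score {mmse} outside [0, 30]")
    return "high" if mmse > cutoff else "low"


def group_cohort(
    corpus: Corpus, cutoff: int = DEFAULT_CUTOFF
) -> tuple[list[GroupAssignment], dict[str, int]]:
    """Assign every participant exactly once; sizes sum to the cohort size."""
    assignments = [
        GroupAssignment(p.id, assign_group(p.mmse, cutoff), cutoff)
        for p in corpus.participants
    ]
    sizes = {g: sum(1 for a in assignments if a.group == g) for g in GROUPS}
    return assignments, sizes
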