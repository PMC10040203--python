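"""Meaning/sense dominance scoring from rater-classified free associates.

Participants supply two free associates per ambiguous word; two raters
classify every response against the word's 2-5 candidate definitions (or
mark it OTHER when it matches multiple, undifferentiable, or none).  Each
rater's sense label counts as one rating — when the raters disagree, both
senses are credited — and percentages are taken over the ratings aligned
with any selected sense.  The dominance score over the top two sense
proportions p1 >= p2 is

    D = (p1 - p2) / p1,

ranging from 0.00 (perfectly balanced senses) to 1.00 (one sense completely
dominant).  Words with D at or below a cutoff (default 0.75) are classed as
meaning/sense-balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ambignorm._common import OTHER


class EmptyTallyError(ValueError):
    """No classified ratings for a word; it must be skipped."""


@dataclass(frozen=True)
class SenseTally:
    """Per-word rating counts over candidate senses (OTHER excluded)."""

    word: str
    counts: tuple[int, ...]
    total_classified: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("negative count")
        if sum(self.counts) != self.total_classified:
            raise ValueError("counts do not sum to total_classified")

    @property
    def percentages(self) -> tuple[float, ...]:
        if self.total_classified == 0:
            raise EmptyTallyError(self.word)
        return tuple(c / self.total_classified for c in self.counts)


@dataclass(frozen=True)
class DominanceRecord:
    """Top-two sense proportions and dominance score for one word."""

    word: str
    top1: int
    top2: int
    p1: float
    p2: float
    score: float
    n_responses: int
    balanced: bool


def tally_sense_assignments(
    assignments: pd.DataFrame, n_senses: int, word: str | None = None
) -> SenseTally:
    """Tally rater sense labels for one word.

    ``assignments`` columns: rater_id, participant_id, word, slot, label —
    labels are sense indices 1..n_senses or the OTHER sentinel (0).  Every
    non-OTHER label contributes one rating: a response both raters assigned
    to sense A adds 2 to A, while a disagreement adds 1 to each rater's
    sense.  A response one rater classified and the other marked OTHER
    contributes the single sense rating.  OTHER never enters the counts or
    the denominator.
    """
    if not (2 <= n_senses <= 5):
        raise ValueError(f"n_senses must be in 2..5, got {n_senses}")
    words = assignments["word"].unique()
    if word is None:
        if len(words) != 1:
            raise ValueError(f"assignments span {len(words)} words; pass word=")
        word = str(words[0])
    else:
        assignments = assignments[assignments["word"] == word]

    labels = assignments["label"].to_numpy()
    if ((labels < 0) | (labels > n_senses)).any():
        bad = sorted(set(labels) - set(range(n_senses + 1)))
        raise ValueError(f"labels outside 0..{n_senses}: {bad}")
    classified = labels[labels != OTHER]
    if classified.size == 0:
        raise EmptyTallyError(word)
    counts = np.bincount(classified, minlength=n_senses + 1)[1:]
    return SenseTally(
        word=word,
        counts=tuple(int(c) for c in counts),
        total_classified=int(classified.size),
    )


def dominance_score(tally: SenseTally, cutoff: float = 0.75) -> DominanceRecord:
    """Dominance D = (p1 - p2)/p1 over the word's top two sense proportions.

    Ties between equally frequent senses break toward the lower sense
    index; D is unaffected by the tie-break.  ``balanced`` flags D <= cutoff.
    """
    pct = np.asarray(tally.percentages)
    order = np.lexsort((np.arange(len(pct)), -pct))  # stable: lower index first
    top1 = int(order[0])
    p1 = float(pct[top1])
    if p1 == 0.0:
        raise EmptyTallyError(tally.word)
    if len(pct) >= 2:
        top2 = int(order[1])
        p2 = float(pct[top2])
    else:
        top2, p2 = top1, 0.0
    score = (p1 - p2) / p1
    return DominanceRecord(
        word=tally.word,
        top1=top1 + 1,
        top2=top2 + 1,
        p1=p1,
        p2=p2,
        score=score,
        n_responses=tally.total_classified,
        balanced=score <= cutoff,
    )


def dominance_from_proportions(
    p1: float, p2: float, word: str = "", cutoff: float = 0.75
) -> DominanceRecord:
    """Dominance score directly from two sense proportions p1 >= p2 > -1."""
    if not (0.0 < p1 <= 1.0) or not (0.0 <= p2 <= p1):
        raise ValueError(f"need 0 < p1 <= 1 and 0 <= p2 <= p1, got {p1}, {p2}")
    score = (p1 - p2) / p1
    return DominanceRecord(
        word=word, top1=1, top2=2, p1=p1, p2=p2, score=score,
        n_responses=0, balanced=score <= cutoff,
    )


def interrater_reliability(assignments: pd.DataFrame) -> tuple[float, float]:
    """Coverage and consistency of the dual-rater sense classification.

    Coverage: proportion of responses assigned a (non-OTHER) sense by both
    raters.  Consistency: among double-labeled responses, the proportion
    with matching labels.  Raises if no response is double-labeled (the
    consistency is then undefined) or if more than two raters appear — the
    procedure is defined for exactly two.
    """
    raters = assignments["rater_id"].unique()
    if len(raters) > 2:
        raise ValueError(f"procedure defined for two raters, got {len(raters)}")
    key = ["participant_id", "word", "slot"]
    labeled = assignments[assignments["label"] != OTHER]
    per_resp = labeled.groupby(key)["label"].agg(["size", "nunique"])
    n_total = assignments.groupby(key).ngroups
    both = per_resp[per_resp["size"] == 2]
    coverage = len(both) / n_total
    if len(both) == 0:
        raise ValueError("no response labeled by both raters; consistency undefined")
    consistency = float((both["nunique"] == 1).mean())
    return coverage, consistency


def response_meaning_consistency(resolved: pd.DataFrame) -> float:
    """Proportion of first/second response pairs mapping to the same sense.

    ``resolved`` columns: participant_id, word, slot, sense — one consensus
    sense per response, with OTHER (0) marking unresolved responses.  Pairs
    are formed per (participant, word); pairs missing a slot or containing
    an unresolved response are dropped.  Quantifies "doubling down": the
    tendency to free-associate twice to the same meaning.
    """
    ok = resolved[resolved["sense"] != OTHER]
    wide = ok.pivot_table(
        index=["participant_id", "word"], columns="slot", values="sense",
        aggfunc="first",
    )
    if not {1, 2}.issubset(wide.columns):
        raise ValueError("need responses in both slots to form pairs")
    pairs = wide[[1, 2]].dropna()
    if len(pairs) == 0:
        raise ValueError("no valid first/second response pairs")
    return float((pairs[1] == pairs[2]).mean())


def dominance_table(
    assignments: pd.DataFrame,
    n_senses_by_word: dict[str, int],
    cutoff: float = 0.75,
) -> tuple[pd.DataFrame, list[str]]:
    """Dominance records for every word, skipping words with empty tallies.

    Returns (table, skipped_words); the table has columns word, p1, p2,
    score, balanced, n_responses, with proportions and scores rounded
    half-up to 3 decimals for reporting.
    """
    rows, skipped = [], []
    for word, k in n_senses_by_word.items():
        sub = assignments[assignments["word"] == word]
        try:
            rec = dominance_score(tally_sense_assignments(sub, k, word=word), cutoff)
        except EmptyTallyError:
            skipped.append(word)
            continue
        rows.append(
            {
                "word": word,
                "p1": _round3(rec.p1),
                "p2": _round3(rec.p2),
                "score": _round3(rec.score),
                "balanced": rec.balanced,
                "n_responses": rec.n_responses,
            }
        )
    return pd.DataFrame(rows), skipped


def _round3(x: float) -> float:
    """Round half-up to 3 decimals (0.0005 -> 0.001)."""
    return float(np.floor(x * 1000 + 0.5) / 1000)
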