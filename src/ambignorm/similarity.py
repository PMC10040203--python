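"""Zeugma-based similarity norm analysis.

Participants rate, on a 1-7 scale, how similar the two coerced meanings of
an ambiguous word feel inside a single zeugmatic sentence.  This module
applies the study's participant and item exclusions, computes item-level
and condition-level descriptive statistics, leave-one-out inter-annotator
agreement (Spearman's rho of each participant against the mean of the
rest), and Bonferroni-corrected pairwise Welch t tests between the four
ambiguity conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

FLAT_THRESHOLD = 0.5  # max |Homonym mean - Unambiguous mean| flagged as flat


@dataclass(frozen=True)
class ExclusionReport:
    kept: tuple[str, ...]
    excluded: pd.DataFrame  # columns: participant_id, reason


def exclude_participants(
    ratings: pd.DataFrame,
    item_conditions: Mapping[str, str] | pd.Series,
    flat_threshold: float = FLAT_THRESHOLD,
    completeness_threshold: float = 0.0,
    flagged: Iterable[str] = (),
) -> ExclusionReport:
    """Drop uncooperative participants before analysis.

    A participant is excluded when the spread between their Homonym and
    Unambiguous condition means is at most ``flat_threshold`` (they rated
    items the same regardless of type), when they rated less than
    ``completeness_threshold`` of the items, when they appear in the
    externally adjudicated ``flagged`` list, or when they have no ratings
    in one of the two anchor conditions.  Reason codes: ``flat``,
    ``incomplete``, ``flagged``, ``insufficient anchor data``.
    """
    conds = pd.Series(item_conditions)
    missing = set(ratings["item"]) - set(conds.index)
    if missing:
        raise KeyError(f"items without condition labels: {sorted(missing)[:5]}")
    df = ratings.assign(condition=ratings["item"].map(conds))

    flagged = set(flagged)
    n_items = conds.index.nunique()
    kept, rows = [], []
    for pid, grp in df.groupby("participant_id", sort=True):
        pid = str(pid)
        if pid in flagged:
            rows.append((pid, "flagged"))
            continue
        if len(grp) < completeness_threshold * n_items:
            rows.append((pid, "incomplete"))
            continue
        by_cond = grp.groupby("condition")["rating"].mean()
        if "Homonym" not in by_cond or "Unambiguous" not in by_cond:
            rows.append((pid, "insufficient anchor data"))
            continue
        if abs(by_cond["Homonym"] - by_cond["Unambiguous"]) <= flat_threshold:
            rows.append((pid, "flat"))
            continue
        kept.append(pid)
    return ExclusionReport(
        kept=tuple(kept),
        excluded=pd.DataFrame(rows, columns=["participant_id", "reason"]),
    )


def exclude_items(
    items: pd.DataFrame, exclusion_list: Iterable[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove a supplied list of defective items from the item table.

    Returns the retained table and per-condition retained counts; excluding
    an unknown item raises, and emptying a whole condition warns.
    """
    excl = set(exclusion_list)
    unknown = excl - set(items["item"])
    if unknown:
        raise KeyError(f"exclusion list names unknown items: {sorted(unknown)}")
    retained = items[~items["item"].isin(excl)].reset_index(drop=True)
    counts = retained.groupby("condition")["item"].count()
    for cond in items["condition"].unique():
        if counts.get(cond, 0) == 0:
            warnings.warn(f"condition {cond!r} has no retained items", stacklevel=2)
    return retained, counts


def item_statistics(
    ratings: pd.DataFrame, item_conditions: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-item n, mean, sample SD (n-1), and SEM = SD/sqrt(n).

    Items rated by fewer than 2 participants get NaN SD and SEM (undefined).
    """
    conds = pd.Series(item_conditions)
    g = ratings.groupby("item")["rating"]
    out = pd.DataFrame(
        {"n": g.size(), "mean": g.mean(), "sd": g.std(ddof=1)}
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, ["sd", "sem"]] = np.nan
    out.insert(0, "condition", out.index.map(conds))
    return out.reset_index(names="item")


@dataclass(frozen=True)
class PairwiseTest:
    cond_a: str
    cond_b: str
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool  # at alpha = 0.01 after adjustment


@dataclass(frozen=True)
class ConditionSummary:
    stats: pd.DataFrame  # condition, n_items, mean, sd (across item means)
    tests: tuple[PairwiseTest, ...]


def condition_statistics(
    item_stats: pd.DataFrame, alpha: float = 0.01
) -> ConditionSummary:
    """Condition means/SDs across item means, plus pairwise Welch t tests.

    The SD is taken across item means, not pooled ratings.  All pairwise
    two-sided Welch (unequal-variance) t tests between conditions are
    Bonferroni-adjusted for the number of pairs; conditions with fewer than
    2 items raise.
    """
    grouped = item_stats.groupby("condition")["mean"]
    summary = pd.DataFrame(
        {
            "n_items": grouped.size(),
            "mean": grouped.mean(),
            "sd": grouped.std(ddof=1),
        }
    ).reset_index()
    short = summary[summary["n_items"] < 2]["condition"].tolist()
    if short:
        raise ValueError(f"conditions with < 2 items: {short}")

    conds = sorted(grouped.groups)
    pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    m = len(pairs)
    tests = []
    for a, b in pairs:
        xa = grouped.get_group(a).to_numpy()
        xb = grouped.get_group(b).to_numpy()
        res = stats.ttest_ind(xa, xb, equal_var=False)
        p_adj = min(1.0, m * float(res.pvalue))
        tests.append(
            PairwiseTest(
                cond_a=a,
                cond_b=b,
                t=float(res.statistic),
                df=float(res.df),
                p_raw=float(res.pvalue),
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return ConditionSummary(stats=summary, tests=tuple(tests))


@dataclass(frozen=True)
class AgreementResult:
    """Leave-one-out inter-annotator agreement.

    ``per_participant_rho`` maps each usable participant to the Spearman
    rank correlation between their ratings and the mean rating of all
    remaining participants over the items both sides rated.
    """

    per_participant_rho: dict[str, float]
    dropped: tuple[str, ...]  # participants with too few usable items

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_participant_rho.values())))

    @property
    def sd(self) -> float:
        return float(np.std(list(self.per_participant_rho.values()), ddof=1))

    @property
    def median(self) -> float:
        return float(np.median(list(self.per_participant_rho.values())))

    @property
    def min(self) -> float:
        return float(np.min(list(self.per_participant_rho.values())))

    @property
    def max(self) -> float:
        return float(np.max(list(self.per_participant_rho.values())))


def loo_agreement(ratings: pd.DataFrame, min_items: int = 3) -> AgreementResult:
    """Leave-one-out Spearman agreement per participant.

    For each participant, correlate their ratings with the mean rating each
    item received from all other participants, over items the participant
    rated that at least one other participant also rated.  Participants
    with fewer than ``min_items`` usable items are dropped from the summary
    with a warning.  Ties get average ranks (Spearman's default).
    """
    participants = ratings["participant_id"].unique()
    if len(participants) < 3:
        raise ValueError("leave-one-out agreement needs >= 3 participants")
    sums = ratings.groupby("item")["rating"].agg(["sum", "size"])
    rhos: dict[str, float] = {}
    dropped = []
    for pid, grp in ratings.groupby("participant_id", sort=True):
        pid = str(pid)
        grp = grp.drop_duplicates("item").set_index("item")
        rest_n = sums.loc[grp.index, "size"] - 1
        usable = rest_n > 0
        if usable.sum() < min_items:
            warnings.warn(f"participant {pid}: too few usable items", stacklevel=2)
            dropped.append(pid)
            continue
        own = grp.loc[usable.index[usable], "rating"].to_numpy(dtype=float)
        others_mean = (
            (sums.loc[usable.index[usable], "sum"] - grp.loc[usable.index[usable], "rating"])
            / rest_n[usable]
        ).to_numpy(dtype=float)
        rho, _ = stats.spearmanr(own, others_mean)
        rhos[pid] = float(rho)
    if not rhos:
        raise ValueError("no participant had enough usable items")
    return AgreementResult(per_participant_rho=rhos, dropped=tuple(dropped))


def summarize_deposit(
    item_stats: pd.DataFrame, dominance_table: pd.DataFrame, cutoff: float = 0.75
) -> dict[str, float]:
    """Summary statistics from deposited norm tables.

    ``item_stats`` needs columns item, condition, mean; ``dominance_table``
    needs column score.  Returns per-condition means of item means, the
    mean dominance score, and the count of words at or below the
    balanced-word cutoff.
    """
    out: dict[str, float] = {}
    for cond, grp in item_stats.groupby("condition"):
        out[f"mean_similarity_{cond}"] = float(grp["mean"].mean())
    scores = dominance_table["score"].astype(float)
    out["mean_dominance"] = float(scores.mean())
    out["n_balanced"] = int((scores <= cutoff).sum())
    return out
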