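"""Score trial logs into the seven behavioural outcomes.

For each subject x condition x modality cell, the whole 8-minute block
and its two 4-minute halves are tallied into a hit/false-alarm confusion
table and summarised as:

* hit rate ``H`` and false-alarm rate ``F``,
* the nonparametric sensitivity index ``A'`` and response-bias index
  ``B''`` of signal detection theory,
* working-memory capacity ``wm = 2 * (H - F)`` (range -2..2),
* mean response latency and its within-segment SD (intrasubject
  variability), over all responded trials by default.

Derived outcomes follow: half-block deltas (second half minus first),
intermodality discrepancies (verbal minus visuospatial), and per-subject
midranks of each outcome across the five conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SEGMENTS",
    "DELTA_OUTCOMES",
    "ConfusionCounts",
    "BlockScore",
    "tabulate",
    "rates",
    "a_prime",
    "b_double_prime",
    "wm_capacity",
    "rt_summary",
    "score_segment",
    "delta",
    "discrepancy",
    "rank_within_subject",
    "score_cohort",
    "delta_table",
    "discrepancy_table",
    "rank_table",
    "scores_to_long",
]

SEGMENTS = ("whole", "first_half", "second_half")

#: Outcomes for which half-block deltas are defined.
DELTA_OUTCOMES = ("H", "F", "a_prime", "wm", "rt_mean")

#: Outcomes carried by a scored segment, in reporting order.
OUTCOMES = ("H", "F", "a_prime", "b_double_prime", "wm", "rt_mean", "rt_sd")


@dataclass(frozen=True)
class ConfusionCounts:
    """Hit/false-alarm tallies for one scored segment."""

    n_targets: int
    n_nontargets: int
    hits: int
    false_alarms: int
    segment: str = "whole"

    def __post_init__(self) -> None:
        if min(self.n_targets, self.n_nontargets, self.hits, self.false_alarms) < 0:
            raise ValueError("counts must be non-negative")
        if self.hits > self.n_targets or self.false_alarms > self.n_nontargets:
            raise ValueError("hits/false alarms cannot exceed their denominators")

    @property
    def misses(self) -> int:
        return self.n_targets - self.hits

    @property
    def correct_rejections(self) -> int:
        return self.n_nontargets - self.false_alarms


@dataclass(frozen=True)
class BlockScore:
    """The seven outcomes for one subject x condition x modality x segment."""

    H: float
    F: float
    a_prime: float
    b_double_prime: Optional[float]
    wm: float
    rt_mean: float
    rt_sd: float
    segment: str = "whole"

    def as_dict(self) -> Dict[str, float]:
        d = {k: getattr(self, k) for k in OUTCOMES}
        d["b_double_prime"] = np.nan if d["b_double_prime"] is None else d["b_double_prime"]
        return d


def _half_boundary(n_trials: int) -> int:
    """Last 1-based trial of the first half; the odd trial goes second."""
    return n_trials // 2


def tabulate(
    trials: pd.DataFrame, n_trials: Optional[int] = None
) -> Dict[str, ConfusionCounts]:
    """Tally one subject x block x modality log into per-segment counts.

    ``trials`` needs 1-based ``trial``, boolean ``is_target`` and
    ``responded`` columns. The whole block plus the first half (trials
    1..n//2) and second half (the rest) are tallied; a pure count over
    (is_target x responded).
    """
    if n_trials is None:
        n_trials = int(trials["trial"].max())
    cut = _half_boundary(n_trials)
    masks = {
        "whole": np.ones(len(trials), dtype=bool),
        "first_half": (trials["trial"] <= cut).to_numpy(),
        "second_half": (trials["trial"] > cut).to_numpy(),
    }
    tgt = trials["is_target"].to_numpy(bool)
    resp = trials["responded"].to_numpy(bool)
    out = {}
    for segment, mask in masks.items():
        out[segment] = ConfusionCounts(
            n_targets=int((tgt & mask).sum()),
            n_nontargets=int((~tgt & mask).sum()),
            hits=int((tgt & resp & mask).sum()),
            false_alarms=int((~tgt & resp & mask).sum()),
            segment=segment,
        )
    return out


def rates(counts: ConfusionCounts) -> Tuple[float, float]:
    """(H, F) = (hits / targets, false alarms / non-targets).

    A zero denominator yields ``nan`` for that rate rather than a
    fabricated value; downstream indices propagate the missingness.
    """
    h = counts.hits / counts.n_targets if counts.n_targets > 0 else np.nan
    f = (
        counts.false_alarms / counts.n_nontargets
        if counts.n_nontargets > 0
        else np.nan
    )
    return h, f


def _check_rate(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def a_prime(h: float, f: float) -> float:
    """Nonparametric sensitivity A' in [0, 1].

    For H >= F: ``0.5 + (H-F)(1+H-F) / (4H(1-F))``; mirrored for H < F.
    A'(H, H) = 0.5 by the limit convention, including H in {0, 1}.
    """
    if np.isnan(h) or np.isnan(f):
        return np.nan
    _check_rate(h, "H")
    _check_rate(f, "F")
    if h == f:
        return 0.5
    if h > f:
        return 0.5 + ((h - f) * (1 + h - f)) / (4 * h * (1 - f))
    return 0.5 - ((f - h) * (1 + f - h)) / (4 * f * (1 - h))


def b_double_prime(h: float, f: float) -> Optional[float]:
    """Nonparametric response bias B'' in [-1, 1]; positive = conservative.

    Grier's index ``(H(1-H) - F(1-F)) / (H(1-H) + F(1-F))`` for H >= F,
    with the mirrored numerator for H < F. Undefined (None) when the
    denominator vanishes, i.e. both rates are at the 0/1 extremes — such
    cells are reported missing, matching the reduced n in published
    tables, rather than corrected.
    """
    if np.isnan(h) or np.isnan(f):
        return None
    _check_rate(h, "H")
    _check_rate(f, "F")
    hh = h * (1 - h)
    ff = f * (1 - f)
    denom = hh + ff
    if denom == 0:
        return None
    if h >= f:
        return (hh - ff) / denom
    return (ff - hh) / denom


def wm_capacity(h: float, f: float) -> float:
    """Working-memory capacity ``2 * (H - F)``, range -2..2.

    Linear in both rates, so a group's mean capacity equals
    ``2 * (mean H - mean F)`` exactly — unlike A' and B''.
    """
    if not (np.isnan(h) or np.isnan(f)):
        _check_rate(h, "H")
        _check_rate(f, "F")
    return 2.0 * (h - f)


def rt_summary(latencies: Sequence[float]) -> Tuple[float, float]:
    """(mean, sample SD) of responded-trial latencies in a segment.

    The SD uses the n-1 denominator and is the intrasubject-variability
    outcome. Fewer than 1 latency -> mean missing; fewer than 2 -> SD
    missing.
    """
    lat = np.asarray(latencies, dtype=float)
    lat = lat[~np.isnan(lat)]
    if lat.size == 0:
        return np.nan, np.nan
    mean = float(lat.mean())
    sd = float(lat.std(ddof=1)) if lat.size >= 2 else np.nan
    return mean, sd


def score_segment(
    counts: ConfusionCounts, latencies: Sequence[float]
) -> BlockScore:
    """Assemble the seven outcomes for one tallied segment."""
    h, f = rates(counts)
    mean, sd = rt_summary(latencies)
    return BlockScore(
        H=h,
        F=f,
        a_prime=a_prime(h, f),
        b_double_prime=b_double_prime(h, f),
        wm=wm_capacity(h, f),
        rt_mean=mean,
        rt_sd=sd,
        segment=counts.segment,
    )


def delta(first_half: BlockScore, second_half: BlockScore) -> Dict[str, float]:
    """Second-half minus first-half value for the five delta outcomes."""
    return {
        k: second_half.as_dict()[k] - first_half.as_dict()[k]
        for k in DELTA_OUTCOMES
    }


def discrepancy(verbal: BlockScore, visuospatial: BlockScore) -> Dict[str, float]:
    """Verbal minus visuospatial value per outcome (antisymmetric)."""
    v = verbal.as_dict()
    s = visuospatial.as_dict()
    return {k: v[k] - s[k] for k in OUTCOMES}


def rank_within_subject(
    values: Sequence[float], ascending: bool = True
) -> np.ndarray:
    """Midrank the five condition values of one subject and outcome.

    Default direction: rank 1 = smallest (so rank 5 = largest). Missing
    values stay missing and the remaining values are ranked 1..m.
    """
    vals = np.asarray(values, dtype=float)
    out = np.full(vals.shape, np.nan)
    mask = ~np.isnan(vals)
    if mask.sum() == 0:
        return out
    ranked = rankdata(vals[mask] if ascending else -vals[mask], method="average")
    out[mask] = ranked
    return out


# ---------------------------------------------------------------------------
# DataFrame-level pipeline


def _segment_latencies(
    trials: pd.DataFrame, n_trials: int, rt_pool: str
) -> Dict[str, np.ndarray]:
    cut = _half_boundary(n_trials)
    resp = trials["responded"].to_numpy(bool)
    if rt_pool == "all":
        pool = resp
    elif rt_pool == "hits_only":
        pool = resp & trials["is_target"].to_numpy(bool)
    else:
        raise ValueError("rt_pool must be 'all' or 'hits_only'")
    rt = trials["rt"].to_numpy(float)
    trial = trials["trial"].to_numpy()
    return {
        "whole": rt[pool],
        "first_half": rt[pool & (trial <= cut)],
        "second_half": rt[pool & (trial > cut)],
    }


def score_cohort(trial_log: pd.DataFrame, rt_pool: str = "all") -> pd.DataFrame:
    """Score a trial log into a wide per-cell outcome table.

    One output row per (subject_id, condition, time_block, modality,
    segment) carrying the seven outcomes. ``rt_pool`` selects whether
    latencies of all responded trials (default) or hits only enter the
    response-time summaries.
    """
    keys = ["subject_id", "condition", "time_block", "modality"]
    rows = []
    for key_vals, grp in trial_log.groupby(keys, sort=True, observed=True):
        n_trials = int(grp["trial"].max())
        counts = tabulate(grp, n_trials)
        lats = _segment_latencies(grp, n_trials, rt_pool)
        for segment in SEGMENTS:
            score = score_segment(counts[segment], lats[segment])
            row = dict(zip(keys, key_vals))
            row["segment"] = segment
            row.update(score.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def scores_to_long(scores: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide score table into (..., outcome, value) long format."""
    keys = ["subject_id", "condition", "time_block", "modality", "segment"]
    return scores.melt(
        id_vars=keys, value_vars=list(OUTCOMES),
        var_name="outcome", value_name="value",
    )


def delta_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Half-block deltas per cell: columns ``delta_<outcome>``.

    Missing half-segment values propagate to missing deltas.
    """
    keys = ["subject_id", "condition", "time_block", "modality"]
    first = scores[scores["segment"] == "first_half"].set_index(keys)
    second = scores[scores["segment"] == "second_half"].set_index(keys)
    out = pd.DataFrame(index=first.index)
    for k in DELTA_OUTCOMES:
        out[f"delta_{k}"] = second[k] - first[k]
    return out.reset_index()


def discrepancy_table(
    scores: pd.DataFrame, segment: str = "whole"
) -> pd.DataFrame:
    """Verbal-minus-visuospatial discrepancy per outcome and cell."""
    keys = ["subject_id", "condition", "time_block"]
    seg = scores[scores["segment"] == segment]
    verbal = seg[seg["modality"] == "auditory_verbal"].set_index(keys)
    visuo = seg[seg["modality"] == "visuospatial"].set_index(keys)
    out = pd.DataFrame(index=verbal.index)
    for k in OUTCOMES:
        out[f"disc_{k}"] = verbal[k] - visuo[k]
    return out.reset_index()


def rank_table(
    scores: pd.DataFrame,
    outcome: str,
    modality: str,
    segment: str = "whole",
    ascending: bool = True,
) -> pd.DataFrame:
    """Per-subject midranks of one outcome across the five conditions.

    Returns a subjects x conditions table of ranks 1..5 (midranks on
    ties); the Friedman test consumes this directly.
    """
    seg = scores[(scores["segment"] == segment) & (scores["modality"] == modality)]
    wide = seg.pivot_table(
        index="subject_id", columns="condition", values=outcome, observed=True
    )
    ranked = wide.apply(
        lambda row: pd.Series(
            rank_within_subject(row.to_numpy(), ascending=ascending),
            index=row.index,
        ),
        axis=1,
    )
    return ranked
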