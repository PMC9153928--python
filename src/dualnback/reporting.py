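"""Publication-style summary tables.

Renders per-condition and per-time-block descriptive tables: one row per
(grouping level, parameter, sex stratum) with n, mean, SD, the t-based
95% CI, min, max, and — for the delta parameters — the p value of the
one-sample t test of the mean delta against zero.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .inference import format_p, one_sample_t
from .scoring import DELTA_OUTCOMES, OUTCOMES

__all__ = ["confidence_interval", "summary_table", "render_text_table"]

#: Display labels for the whole-block and delta parameters, in table order.
PARAM_LABELS = {
    "H": "Hit rate",
    "delta_H": "Delta hit rate",
    "F": "FA rate",
    "delta_F": "Delta FA rate",
    "a_prime": "A'",
    "delta_a_prime": "Delta A'",
    "b_double_prime": "B''",
    "wm": "WM",
    "delta_wm": "Delta WM",
    "rt_mean": "RT",
    "delta_rt_mean": "Delta RT",
    "rt_sd": "RTSD",
}


def confidence_interval(
    mean: float, sd: float, n: int, level: float = 0.95
) -> Tuple[float, float]:
    """Two-sided t-based CI: ``mean ± t(1-(1-level)/2, n-1) * sd / sqrt(n)``.

    Undefined (nan, nan) for n < 2; collapses to the mean when sd = 0.
    """
    if n < 2 or np.isnan(mean) or np.isnan(sd):
        return np.nan, np.nan
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / math.sqrt(n)
    return mean - half, mean + half


def _stratum_rows(
    values: pd.Series, sexes: pd.Series, group: str, parameter: str
) -> List[Dict]:
    rows = []
    is_delta = parameter.startswith("delta_")
    strata = [("Female", sexes == "female"), ("Male", sexes == "male"),
              ("Total", pd.Series(True, index=sexes.index))]
    for label, mask in strata:
        vals = values[mask].dropna().to_numpy()
        n = vals.size
        if n == 0:
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n >= 2 else np.nan
        lo, hi = confidence_interval(mean, sd, n)
        p = np.nan
        if is_delta and label == "Total" and n >= 2 and sd > 0:
            p = one_sample_t(values=vals).p_value
        rows.append(
            {
                "group": group,
                "parameter": PARAM_LABELS.get(parameter, parameter),
                "sex": label,
                "n": n,
                "mean": mean,
                "sd": sd,
                "ci_low": lo,
                "ci_high": hi,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "p": p,
            }
        )
    return rows


def summary_table(
    scores: pd.DataFrame,
    deltas: pd.DataFrame,
    profiles: pd.DataFrame,
    modality: str,
    by: str = "condition",
) -> pd.DataFrame:
    """Descriptive table for one modality, grouped by condition or time_block.

    ``scores`` is the wide per-cell table from :func:`scoring.score_cohort`
    (whole-block rows are used), ``deltas`` the output of
    :func:`scoring.delta_table`, ``profiles`` supplies each subject's sex.
    """
    sex_map = profiles.set_index("subject_id")["sex"]
    whole = scores[(scores["segment"] == "whole") & (scores["modality"] == modality)]
    dmod = deltas[deltas["modality"] == modality]
    rows: List[Dict] = []
    for group, grp in whole.groupby(by, sort=False, observed=True):
        dgrp = dmod[dmod[by] == group]
        sexes = grp["subject_id"].map(sex_map)
        dsexes = dgrp["subject_id"].map(sex_map)
        for outcome in OUTCOMES:
            rows.extend(_stratum_rows(grp[outcome], sexes, str(group), outcome))
            if outcome in DELTA_OUTCOMES:
                rows.extend(
                    _stratum_rows(
                        dgrp[f"delta_{outcome}"], dsexes, str(group),
                        f"delta_{outcome}",
                    )
                )
    return pd.DataFrame(rows)


def render_text_table(table: pd.DataFrame, decimals: int = 3) -> str:
    """Plain-text rendering with 3-decimal rates and the <0.0005 convention."""
    out = table.copy()
    for col in ("mean", "sd", "min", "max"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.{decimals}f}")
    for col in ("ci_low", "ci_high"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out["p"] = out["p"].map(format_p)
    return out.to_string(index=False)
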