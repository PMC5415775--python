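"""Immunostaining score handling.

Scores are on a 0-3 ordinal scale; 0-1 ("negative-to-low") dichotomises
to "low" and 2-3 ("moderate-to-strong") to "high".  The combined
two-marker grouping is the three-level factor both-low / one-high /
both-high from the two binarized scores.
"""
from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from ..errors import ConfigError

LOW, HIGH = "low", "high"
COMBINED_LEVELS = ("both-low", "one-high", "both-high")


def binarize_score(score) -> Optional[str]:
    """Map a 0-3 score to 'low' (0-1) / 'high' (2-3); missing stays missing.

    Accepts scalars or pandas Series.
    """
    if isinstance(score, pd.Series):
        return score.map(binarize_score)
    if score is None or (isinstance(score, float) and np.isnan(score)) or pd.isna(score):
        return None
    s = int(score)
    if s not in (0, 1, 2, 3):
        raise ConfigError(f"score {score!r} outside 0-3")
    return HIGH if s >= 2 else LOW


def combined_fgfr_group(score1, score2) -> Optional[str]:
    """Three-level combination of two binarized scores; missing if either is."""
    b1, b2 = binarize_score(score1), binarize_score(score2)
    if b1 is None or b2 is None:
        return None
    n_high = (b1 == HIGH) + (b2 == HIGH)
    return COMBINED_LEVELS[n_high]


def add_derived_columns(cohort: pd.DataFrame,
                        pediatric_cutoff: float = 16.0) -> pd.DataFrame:
    """Attach fgfr1/fgfr3 low-high, the combined group, and the age split."""
    out = cohort.copy()
    out["fgfr1"] = binarize_score(out["fgfr1_score"])
    out["fgfr3"] = binarize_score(out["fgfr3_score"])
    out["fgfr_combined"] = [
        combined_fgfr_group(a, b)
        for a, b in zip(out["fgfr1_score"], out["fgfr3_score"])]
    out["age16"] = np.where(out["age_years"] < pediatric_cutoff, "pediatric", "adult")
    return out
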