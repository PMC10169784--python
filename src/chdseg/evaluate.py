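"""Per-structure Dice reporting and paired comparison between methods.

A score table has one row per case and one column per structure
(LV, RV, LA, RA, Myo, Ao, PA) plus ``overall`` — the per-case mean over
the seven structures.  Structures absent from both prediction and truth
score 1.0 (correctly absent; CHD cases can genuinely lack a structure)
and are flagged separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (FOREGROUND_CODES, STRUCTURE_NAMES, LabelVolume,
                   check_same_geometry, dice_score)

COLUMNS = [STRUCTURE_NAMES[c] for c in FOREGROUND_CODES] + ["overall"]


class DegeneratePairingError(ValueError):
    """Paired differences have zero variance: t is undefined."""


def evaluate_case(pred: LabelVolume, truth: LabelVolume) -> pd.Series:
    """One score-table row: seven per-structure Dice values plus their mean.

    Attributes ``absent`` on the returned Series lists structures missing
    from both volumes (scored 1.0 by convention).
    """
    check_same_geometry(pred, truth)
    row = {}
    absent = []
    for code in FOREGROUND_CODES:
        name = STRUCTURE_NAMES[code]
        row[name] = dice_score(pred, truth, code)
        if not (pred.data == code).any() and not (truth.data == code).any():
            absent.append(name)
    row["overall"] = float(np.mean([row[STRUCTURE_NAMES[c]]
                                    for c in FOREGROUND_CODES]))
    s = pd.Series(row)[COLUMNS]
    s.attrs["absent"] = absent
    return s


def score_table(rows) -> pd.DataFrame:
    """Stack per-case rows into a score table (row index = case index)."""
    df = pd.DataFrame(list(rows))[COLUMNS].reset_index(drop=True)
    if ((df < -1e-12) | (df > 1 + 1e-12)).any().any():
        raise ValueError("Dice values must lie in [0, 1]")
    return df


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Column means and sample standard deviations (n-1 denominator).

    With a single row the deviation is reported absent (NaN).
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1) if len(table) > 1 else pd.Series(
        np.nan, index=table.columns)
    return pd.DataFrame({"mean": mean, "sd": sd})


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on case-matched score lists.

    ``t = mean(d) / (sd(d)/sqrt(n))`` on differences ``d = a - b`` with
    n-1 degrees of freedom.  Zero-variance differences raise
    :class:`DegeneratePairingError` rather than returning an infinite t.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegeneratePairingError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
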