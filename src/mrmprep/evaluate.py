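"""Evaluation instruments: confusion metrics, replicate variability and
correlation against reference values.

A processed cell (one metabolite in one sample) is classified against the
expert/ground truth as TP (the correct peak was reported), TN (no correct
peak exists and none was reported), FP (a peak was reported but no correct
peak exists, or the reported apex lies outside the true peak borders) or
FN (a correct peak exists but nothing was reported).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

logger = logging.getLogger("mrmprep")

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "classify_outputs",
    "replicate_sd",
    "correlate_to_reference",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float]:
    """(accuracy, specificity), rounded to 3 decimals.

    accuracy = (TP+TN)/total; specificity = TN/(TN+FP).  When TN+FP = 0
    the specificity is undefined and returned as NaN.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero counts")
    accuracy = round((c.tp + c.tn) / c.total, 3)
    if c.tn + c.fp == 0:
        logger.warning("specificity undefined (TN + FP = 0)")
        return accuracy, float("nan")
    specificity = round(c.tn / (c.tn + c.fp), 3)
    return accuracy, specificity


def classify_outputs(
    reported: pd.DataFrame, truth: pd.DataFrame
) -> ConfusionCounts:
    """Compare reported peaks with ground truth per (metabolite, sample).

    ``reported`` needs columns ``metabolite, sample, apex_time`` where
    ``apex_time`` is NaN for unreported cells; ``truth`` needs
    ``metabolite, sample, present, true_start, true_end``.  Both tables
    must cover exactly the same cells.
    """
    key = ["metabolite", "sample"]
    r = reported.set_index(key)
    t = truth.set_index(key)
    if not r.index.sort_values().equals(t.index.sort_values()):
        raise ValueError("reported and truth tables index different cells")
    tp = tn = fp = fn = 0
    for cell in t.index:
        present = bool(t.at[cell, "present"])
        apex = r.at[cell, "apex_time"]
        was_reported = np.isfinite(apex)
        if present and was_reported:
            if t.at[cell, "true_start"] <= apex <= t.at[cell, "true_end"]:
                tp += 1
            else:
                fp += 1
        elif present and not was_reported:
            fn += 1
        elif not present and was_reported:
            fp += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp, tn, fp, fn)
    assert counts.total == len(t)
    return counts


def replicate_sd(
    areas: pd.DataFrame, groups: Mapping[str, str]
) -> pd.Series:
    """Per-metabolite mean relative SD of peak area within replicate groups.

    ``areas`` is metabolites x samples; ``groups`` maps sample id to group
    label.  Within each group the sample SD (ddof=1) divided by the group
    mean is computed over available (non-NaN) members; groups with fewer
    than 2 usable members are skipped.  The result is the mean over groups
    per metabolite (NaN when no group is usable).
    """
    by_group: dict[str, list[str]] = {}
    for sample, group in groups.items():
        by_group.setdefault(group, []).append(sample)
    out = {}
    for metab in areas.index:
        rels = []
        for members in by_group.values():
            vals = areas.loc[metab, [m for m in members if m in areas.columns]]
            vals = vals.dropna().to_numpy(dtype=float)
            if vals.size < 2:
                continue
            mean = vals.mean()
            if mean == 0:
                continue
            rels.append(vals.std(ddof=1) / mean)
        out[metab] = float(np.mean(rels)) if rels else float("nan")
    return pd.Series(out, name="mean_relative_sd")


def correlate_to_reference(ours: pd.Series, reference: pd.Series) -> float:
    """Pearson r between our reported intensities and published values.

    Only pairs we actually report (non-NaN in ``ours``) enter the
    correlation.  A metabolite for which we report nothing is assigned
    r = 0; with fewer than 3 reporting pairs the value is flagged
    unreliable with a warning.
    """
    ours, reference = ours.align(reference, join="inner")
    mask = ours.notna() & reference.notna()
    n = int(mask.sum())
    if n == 0:
        return 0.0
    if n < 3:
        warnings.warn(
            f"only {n} reporting pair(s): correlation unreliable", stacklevel=2
        )
        if n == 1:
            return float("nan")
    r, _ = pearsonr(ours[mask], reference[mask])
    return float(r)
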