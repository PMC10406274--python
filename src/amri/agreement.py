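"""Agreement statistics for repeated volumetric measurements.

The intraclass correlation coefficient (ICC) quantifies how well different
measurement methods (e.g. volumetry on reference vs. denoised accelerated
acquisitions) agree across subjects.  The form used here is the two-way
mixed-effects, absolute-agreement, single-measure ICC -- ICC(2,1) in the
Shrout & Fleiss taxonomy -- computed from repeated-measures ANOVA mean
squares:

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with n subjects (rows), k methods (columns), MS_R/MS_C/MS_E the row, column
and residual mean squares.  Values > 0.9 are classed excellent, (0.75, 0.9]
good, (0.5, 0.75] moderate, <= 0.5 poor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["ICCTable", "ICCResult", "icc_repeated_measures", "classify_icc",
           "icc_summary", "icc_from_long", "load_reference_volumetry_icc"]


@dataclass
class ICCTable:
    """Subjects x methods matrix of volumetric values for one location."""

    measurements: np.ndarray
    location: str = ""

    def __post_init__(self):
        self.measurements = np.asarray(self.measurements, dtype=np.float64)
        if self.measurements.ndim != 2:
            raise ValueError("measurements must be a 2D subjects x methods matrix")
        n, k = self.measurements.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 methods")
        if not np.isfinite(self.measurements).all():
            raise ValueError("missing or non-finite cells are not supported")


@dataclass
class ICCResult:
    icc: float
    category: str
    variance_components: tuple[float, float, float]  # (MS_R, MS_C, MS_E)
    location: str = ""


def icc_repeated_measures(t: ICCTable) -> ICCResult:
    """ICC(2,1) from two-way repeated-measures ANOVA mean squares."""
    x = t.measurements
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError(f"{t.location or 'table'}: zero total variance, ICC undefined")
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    return ICCResult(icc=float(icc), category=classify_icc(icc),
                     variance_components=(float(ms_r), float(ms_c), float(ms_e)),
                     location=t.location)


def classify_icc(icc: float) -> str:
    """Agreement category: >0.9 excellent, (0.75,0.9] good, (0.5,0.75] moderate."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc > 0.9:
        return "excellent"
    if icc > 0.75:
        return "good"
    if icc > 0.5:
        return "moderate"
    return "poor"


def icc_summary(results: dict[str, "ICCResult | float"]) -> dict:
    """Category counts plus a listing sorted by descending ICC."""
    if not results:
        raise ValueError("need at least one result")
    items = []
    for loc, r in results.items():
        icc = r.icc if isinstance(r, ICCResult) else float(r)
        items.append((loc, icc, classify_icc(icc)))
    items.sort(key=lambda t: -t[1])
    counts = Counter(cat for _, _, cat in items)
    return {
        "counts": {c: counts.get(c, 0) for c in ("excellent", "good", "moderate", "poor")},
        "listing": items,
    }


def icc_from_long(df: pd.DataFrame, repeat_handling: str = "rows") -> dict[str, ICCResult]:
    """ICC per location from a long table (location, subject_id, method, value).

    When a ``repeat_id`` column is present, repeats either become extra rows
    (``rows``, subject x repeat as the row unit) or are averaged per subject
    (``mean``).
    """
    required = {"location", "subject_id", "method", "value"}
    if missing := required - set(df.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if repeat_handling not in ("rows", "mean"):
        raise ValueError("repeat_handling must be 'rows' or 'mean'")
    out = {}
    row_keys = ["subject_id"]
    if "repeat_id" in df.columns and repeat_handling == "rows":
        row_keys.append("repeat_id")
    for loc, grp in df.groupby("location", sort=True):
        wide = grp.pivot_table(index=row_keys, columns="method", values="value",
                               aggfunc="mean")
        if wide.isna().any().any():
            raise ValueError(f"{loc}: incomplete design (missing cells)")
        out[str(loc)] = icc_repeated_measures(
            ICCTable(wide.to_numpy(), location=str(loc))
        )
    return out


def load_reference_volumetry_icc() -> pd.DataFrame:
    """Published ICC values for 27 brain subregions and 3 tissues.

    Reported agreement of volumetry across reference and denoised
    accelerated acquisitions; used as fixture data for the category summary.
    Columns: ``location``, ``icc``.
    """
    with resources.files("amri.data").joinpath("brain_volumetry_icc.csv").open() as f:
        return pd.read_csv(f)
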