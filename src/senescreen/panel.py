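"""Responder classification for the multi-line CDK4/6-inhibitor panel.

Crystal-violet absorbance (570 nm) per well is normalized to the mean
vehicle (DMSO) absorbance of its (cell line, drug) condition, so 1.0 means
vehicle-like growth. "Dose-dependent, statistically significant response"
is operationalized as the least-squares slope of normalized absorbance on
log10(dose) over the nonzero doses, with a one-sided t-test for slope < 0.
A line is a responder when it responds to at least ``min_drugs`` of the
drugs tested (default 2 of 3); a secondary screen re-applies the same rule
and confirms the lines that respond in both rounds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("cell_line", "drug", "dose_uM", "replicate", "absorbance")


def _check_panel(panel: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel table missing columns {sorted(missing)}")


def normalize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Add a ``norm`` column: absorbance over the (line, drug) vehicle mean."""
    _check_panel(panel)
    out = panel.copy()
    out["norm"] = np.nan
    for (line, drug), grp in panel.groupby(["cell_line", "drug"]):
        vehicle = grp.loc[grp["dose_uM"] == 0, "absorbance"]
        if vehicle.empty:
            raise ValueError(f"no vehicle wells for ({line!r}, {drug!r})")
        v = vehicle.mean()
        if v <= 0:
            raise ValueError(f"vehicle mean absorbance <= 0 for ({line!r}, {drug!r})")
        out.loc[grp.index, "norm"] = grp["absorbance"] / v
    return out


def trend_test(values, doses) -> tuple[float, float]:
    """Log-dose trend: least-squares slope and one-sided p for slope < 0.

    ``values`` are vehicle-normalized absorbances and ``doses`` their doses
    in uM; vehicle (dose 0) entries are ignored. Requires at least three
    distinct nonzero doses with two or more replicates each.
    """
    values = np.asarray(values, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if values.shape != doses.shape:
        raise ValueError("values and doses must have equal length")
    mask = doses > 0
    values, doses = values[mask], doses[mask]
    levels, counts = np.unique(doses, return_counts=True)
    if len(levels) < 3:
        raise ValueError("need >= 3 distinct nonzero doses for a trend test")
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates at every nonzero dose")
    fit = stats.linregress(np.log10(doses), values)
    slope = float(fit.slope)
    p_two = float(fit.pvalue)
    if np.isnan(p_two):
        # perfectly flat response: zero slope with zero residual variance
        p_two = 1.0
    p_one = p_two / 2.0 if slope < 0 else 1.0 - p_two / 2.0
    return slope, p_one


def call_responders(
    panel: pd.DataFrame,
    alpha: float = 0.05,
    min_drugs: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every cell line of a dose panel.

    Returns ``(summary, details)``: ``details`` holds one row per
    (cell_line, drug) with slope, one-sided p, the responsive flag and a
    failure reason when the trend test was not applicable (such pairs count
    as non-responsive); ``summary`` holds one row per line with the number
    of responsive drugs and the responder decision
    (n_drugs_responsive >= min_drugs).
    """
    if not (0 < alpha < 1) or min_drugs < 1:
        raise ValueError("alpha must lie in (0, 1) and min_drugs be >= 1")
    norm = normalize_panel(panel)
    detail_rows = []
    for (line, drug), grp in norm.groupby(["cell_line", "drug"]):
        try:
            slope, p = trend_test(grp["norm"], grp["dose_uM"])
            responsive = bool(p < alpha and slope < 0)
            reason = ""
        except ValueError as err:
            slope, p, responsive, reason = np.nan, np.nan, False, str(err)
        detail_rows.append((line, drug, slope, p, responsive, reason))
    details = pd.DataFrame(
        detail_rows,
        columns=["cell_line", "drug", "slope", "p_value", "responsive", "reason"],
    )
    grouped = details.groupby("cell_line")
    summary = pd.DataFrame(
        {
            "n_drugs_tested": grouped.size(),
            "n_drugs_responsive": grouped["responsive"].sum().astype(int),
        }
    )
    summary["is_responder"] = summary["n_drugs_responsive"] >= min_drugs
    summary.index.name = "cell_line"
    summary.attrs.update(alpha=alpha, min_drugs=min_drugs)
    return summary, details


def responder_lines(summary: pd.DataFrame) -> list[str]:
    return list(summary.index[summary["is_responder"]])


def secondary_confirmation(
    primary_summary: pd.DataFrame,
    secondary_panel: pd.DataFrame,
    alpha: float = 0.05,
    min_drugs: int = 2,
) -> tuple[list[str], pd.DataFrame]:
    """Confirm primary responders on a secondary screen.

    Re-runs responder calling on the secondary panel (restricted to the
    primary responders; extra lines trigger a warning and are ignored) and
    returns the lines classified as responders in both rounds, together
    with the secondary summary.
    """
    primary = set(responder_lines(primary_summary))
    present = set(secondary_panel["cell_line"].unique())
    extra = present - primary
    if extra:
        warnings.warn(
            f"secondary panel contains non-primary-responder lines, ignored: {sorted(extra)}",
            stacklevel=2,
        )
    restricted = secondary_panel[secondary_panel["cell_line"].isin(primary)]
    if restricted.empty:
        return [], pd.DataFrame(
            columns=["n_drugs_tested", "n_drugs_responsive", "is_responder"]
        )
    summary, _ = call_responders(restricted, alpha=alpha, min_drugs=min_drugs)
    confirmed = [line for line in responder_lines(summary) if line in primary]
    return confirmed, summary
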