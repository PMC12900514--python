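"""Densitometry arithmetic for slot-blot and northern quantification:
5S-normalization, composite Pol I signals, size-window integration of lane
traces, and fold-change statistics across conditions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import ProbeCatalog
from .compare import star_label, welch_ttest

__all__ = [
    "QUANT_COLUMNS",
    "LANE_COLUMNS",
    "normalize_to_5s",
    "composite_poli_signal",
    "poli_composite_default",
    "window_quant",
    "fold_change_stats",
    "read_quant_table",
    "read_lane_profiles",
]

QUANT_COLUMNS = ["condition", "replicate", "probe", "intensity"]
LANE_COLUMNS = ["condition", "replicate", "size_nt", "intensity"]

#: abortive-species integration window (nt) on denaturing-gel lane traces
DEFAULT_ABORTIVE_WINDOW = (70.0, 90.0)


def read_quant_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if (table["intensity"] < 0).any():
        raise ValueError(f"{path}: negative intensities")
    return table


def read_lane_profiles(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in LANE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return table


def normalize_to_5s(table: pd.DataFrame, catalog: ProbeCatalog) -> pd.DataFrame:
    """Divide every probe intensity by the mean of the two 5S loading-control
    probes of the same (condition, replicate).

    Returns the table with an added ``ratio`` column (5S rows included, their
    ratios averaging 1 by construction).
    """
    table = table.copy()
    names_5s = [p.name for p in catalog.with_role("control_5S")]
    out = []
    for (cond, rep), group in table.groupby(["condition", "replicate"],
                                            sort=False):
        present = group.loc[group["probe"].isin(names_5s), "intensity"]
        if len(present) != 2:
            raise ValueError(
                f"replicate {rep!r} of condition {cond!r} needs both 5S "
                f"probes {names_5s}, found {len(present)}"
            )
        denom = present.mean()
        if denom == 0:
            raise ValueError(
                f"zero 5S denominator in replicate {rep!r} of {cond!r}")
        g = group.copy()
        g["ratio"] = g["intensity"] / denom
        out.append(g)
    return pd.concat(out, ignore_index=True)


def composite_poli_signal(ratios: pd.DataFrame,
                          members: Sequence[str]) -> pd.DataFrame:
    """Arithmetic mean of the member probes' 5S-ratios per replicate.

    Returns one row per (condition, replicate) with the composite ratio.
    """
    members = list(members)
    if not members:
        raise ValueError("member probe list must not be empty")
    sub = ratios[ratios["probe"].isin(members)]
    rows = []
    for (cond, rep), group in sub.groupby(["condition", "replicate"],
                                          sort=False):
        missing = set(members) - set(group["probe"])
        if missing:
            raise ValueError(
                f"replicate {rep!r} of {cond!r} missing member probe(s) "
                f"{sorted(missing)}"
            )
        rows.append((cond, rep, float(group["ratio"].mean())))
    return pd.DataFrame(rows, columns=["condition", "replicate", "ratio"])


def poli_composite_default(ratios: pd.DataFrame) -> pd.DataFrame:
    """Default composite Pol I signal: the three 5'ETS probes averaged into a
    single 5'ETS value, then meaned with 18S.2, 25S.1 and 3'ETS."""
    fiveets = composite_poli_signal(
        ratios, ["5'ETS.1", "5'ETS.2", "5'ETS.3"]).rename(
        columns={"ratio": "fiveets"})
    rest = composite_poli_signal(ratios, ["18S.2", "25S.1", "3'ETS"])
    merged = fiveets.merge(rest, on=["condition", "replicate"])
    merged["ratio"] = (merged["fiveets"] + 3 * merged["ratio"]) / 4
    return merged[["condition", "replicate", "ratio"]]


def window_quant(sizes: np.ndarray, intensities: np.ndarray,
                 window: tuple[float, float] = DEFAULT_ABORTIVE_WINDOW) -> float:
    """Trapezoidal integral of a calibrated lane trace over a size window.

    ``sizes`` must be strictly monotone increasing (nt); the window must lie
    within the trace range.  Intensity at the window edges is linearly
    interpolated.
    """
    sizes = np.asarray(sizes, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if sizes.ndim != 1 or sizes.size < 2:
        raise ValueError("lane trace needs at least two points")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("size axis must be strictly increasing")
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must have positive width")
    if lo < sizes[0] or hi > sizes[-1]:
        raise ValueError(
            f"window {window} outside trace range "
            f"[{sizes[0]}, {sizes[-1]}]"
        )
    inside = (sizes > lo) & (sizes < hi)
    xs = np.concatenate(([lo], sizes[inside], [hi]))
    ys = np.interp(xs, sizes, intensities)
    return float(np.trapezoid(ys, xs))


def fold_change_stats(ratios: pd.DataFrame, reference: str,
                      value: str = "ratio") -> pd.DataFrame:
    """Fold changes vs a reference condition with Welch t-tests.

    ``ratios`` holds per-replicate values (columns condition, replicate and
    ``value``; an optional ``probe`` column is analysed probe-wise).  Fold
    change = mean(condition) / mean(reference); the test compares the
    per-replicate values of each condition against the reference's.
    """
    if reference not in set(ratios["condition"]):
        raise ValueError(f"reference condition {reference!r} absent from table")
    group_cols = ["probe"] if "probe" in ratios.columns else []
    rows = []
    for keys, group in (ratios.groupby(group_cols, sort=False)
                        if group_cols else [((), ratios)]):
        if not group_cols:
            probe = ""
        else:
            probe = keys if isinstance(keys, str) else keys[0]
        ref = group.loc[group["condition"] == reference, value].to_numpy()
        for cond, sub in group.groupby("condition", sort=False):
            vals = sub[value].to_numpy()
            if cond == reference:
                fc, t, p = 1.0, 0.0, 1.0
            else:
                fc = float(vals.mean() / ref.mean())
                t, p = welch_ttest(vals, ref)
            rows.append((probe, cond, vals.mean(),
                         vals.std(ddof=1) if vals.size > 1 else np.nan,
                         fc, t, p, star_label(p)))
    out = pd.DataFrame(
        rows, columns=["probe", "condition", "mean", "sd", "fold_change",
                       "t", "p", "stars"],
    )
    if not group_cols:
        out = out.drop(columns="probe")
    return out
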