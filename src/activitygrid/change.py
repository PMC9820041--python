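"""Window-based activity-intensity aggregation and period change rates.

Activity intensity arrives as 48 half-hourly counts per cell per
observation day: one pre-restriction baseline day and three later days
(during lockdown, at first-stage work resuming, and at total work
resuming).  Because a residential cell peaks when a working cell is
idle, intensity is summed only over the clock window characteristic of
the cell's land-use class rather than over the whole day.  The change
rate of period k compares day k+1 with the baseline:

    period_k = (S_{k+1} - S_1) / S_1 * 100   (percent),

where S_d is the day-d window sum.  Cells whose baseline window sum is
zero have undefined rates and are excluded (and counted) per period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BINS = 48  # half-hour bins per day
DAY_LABELS = ("day1", "day2", "day3", "day4")
PERIODS = ("period1", "period2", "period3")

#: class -> half-open clock window [start, end) in hours
DEFAULT_WINDOWS = {
    "residential": (22.0, 24.0),
    "working": (9.0, 17.0),
    "entertainment": (17.0, 22.0),
    "mixed": (9.0, 24.0),
}


@dataclass(frozen=True)
class WindowPolicy:
    """Half-open clock windows per land-use class.

    A bin belongs to a window when its *start* time lies in
    ``[start, end)``; 24:00 is an exclusive end-of-day bound.
    """

    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))

    def __post_init__(self):
        for cls, (s, e) in self.windows.items():
            if not (0 <= s < e <= 24):
                raise ValueError(f"window for {cls!r} not within [0, 24]")

    def bin_mask(self, label: str) -> np.ndarray:
        """Boolean mask of the 48 bins selected for ``label``."""
        if label not in self.windows:
            raise KeyError(f"no window for land-use label {label!r}")
        start, end = self.windows[label]
        starts = np.arange(N_BINS) * 0.5
        return (starts >= start) & (starts < end)


def window_sum(bins, policy: WindowPolicy, label: str):
    """Sum the bins whose start time lies in the label's clock window.

    Accepts one 48-bin series or an ``(n, 48)`` stack of series.
    """
    b = np.asarray(bins, dtype=float)
    if b.shape[-1] != N_BINS:
        raise ValueError(f"expected {N_BINS} half-hour bins, got {b.shape}")
    if (b < 0).any():
        raise ValueError("intensity bins must be nonnegative")
    s = b @ policy.bin_mask(label).astype(float)
    return float(s) if b.ndim == 1 else s


def change_rates(day_sums) -> dict:
    """Three period change rates (percent) from the four day window sums.

    Returns ``{"period1": ..., "period2": ..., "period3": ...,
    "defined": bool}``; rates are NaN when the baseline sum is zero.
    """
    s = np.asarray(day_sums, dtype=float)
    if s.shape != (4,):
        raise ValueError("need window sums for exactly 4 days")
    if (s < 0).any():
        raise ValueError("window sums must be nonnegative")
    defined = s[0] > 0
    out = {}
    for k, period in enumerate(PERIODS, start=1):
        out[period] = (s[k] - s[0]) / s[0] * 100.0 if defined else np.nan
    out["defined"] = bool(defined)
    return out


def change_table(intensity: pd.DataFrame, labels: pd.Series,
                 policy: WindowPolicy | None = None) -> pd.DataFrame:
    """Per-cell change rates from a long intensity table.

    Parameters
    ----------
    intensity : DataFrame with columns ``cell_id``, ``day`` (day1..day4)
        and ``bin_0`` .. ``bin_47``.
    labels : land-use label per cell_id.  Cells whose label has no
        window (other / non_human_activity) are skipped.

    Returns
    -------
    DataFrame indexed by cell_id with the four window sums, the three
    period rates (percent) and a ``defined`` flag.
    """
    policy = policy or WindowPolicy()
    bin_cols = [f"bin_{i}" for i in range(N_BINS)]

    lab = labels[labels.isin(policy.windows.keys())]
    n_skipped = len(labels) - len(lab)
    if n_skipped:
        logger.info("%d cells without a class window skipped", n_skipped)

    mask_mat = np.stack([policy.bin_mask(l).astype(float)
                         for l in lab.to_numpy()])
    out = pd.DataFrame({"label": lab.to_numpy()}, index=lab.index)
    out.index.name = "cell_id"
    for day in DAY_LABELS:
        sub = intensity.loc[intensity["day"] == day].set_index("cell_id")
        bins = sub.reindex(lab.index)[bin_cols].to_numpy(dtype=float)
        if np.isnan(bins).any():
            raise ValueError(f"missing intensity bins for {day}")
        if (bins < 0).any():
            raise ValueError("intensity bins must be nonnegative")
        out[f"sum_{day}"] = (bins * mask_mat).sum(axis=1)

    base = out["sum_day1"].to_numpy()
    defined = base > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        for k, period in enumerate(PERIODS, start=2):
            rate = (out[f"sum_day{k}"].to_numpy() - base) / base * 100.0
            out[period] = np.where(defined, rate, np.nan)
    out["defined"] = defined
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("%d cells with zero baseline window sum", n_undef)
    return out


def summarize(changes: pd.DataFrame, sectors: pd.Series | None = None,
              sides: pd.Series | None = None) -> dict:
    """Group summaries of the per-cell change table.

    Returns a dict of tidy DataFrames:

    ``by_class``    mean change per land-use class per period (with the
                    count of defined cells per group);
    ``by_sector``   mean change per (class, sector) per period;
    ``negative``    count and share of cells with negative change per
                    period (among defined cells);
    ``by_side``     east/west mean change per period;
    ``excluded``    per-period counts of undefined (zero-baseline) cells.

    Undefined cells are excluded pairwise per period; empty groups are
    simply absent from the tables.
    """
    periods = list(PERIODS)

    def group_means(df, keys):
        g = df.groupby(keys, observed=True)
        out = g[periods].mean()
        out["n_cells"] = g[periods[0]].count()
        return out.reset_index()

    res = {}
    res["by_class"] = group_means(changes, ["label"])

    if sectors is not None:
        sec = changes.join(sectors.rename("sector"), how="left")
        sec = sec[sec["sector"].fillna("").ne("")]
        res["by_sector"] = group_means(sec, ["label", "sector"])

    neg = []
    for p in periods:
        vals = changes[p].dropna()
        neg.append({
            "period": p,
            "n_defined": len(vals),
            "n_negative": int((vals < 0).sum()),
            "share_negative": (vals < 0).mean() * 100 if len(vals) else np.nan,
            "mean_change": vals.mean() if len(vals) else np.nan,
        })
    res["negative"] = pd.DataFrame(neg)

    if sides is not None:
        sid = changes.join(sides.rename("side"), how="left")
        res["by_side"] = group_means(sid.dropna(subset=["side"]), ["side"])

    res["excluded"] = pd.DataFrame({
        "period": periods,
        "n_undefined": [int(changes[p].isna().sum()) for p in periods],
    })
    return res
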