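"""Normalized-frequency dominance classifier for grid-cell land use.

A cell's function is inferred from the mix of POIs it contains.  Raw
counts are misleading because category totals differ wildly nationwide
(residential POIs are far rarer than working or entertainment ones), so
each per-cell count is first normalized by its national total,

    F_i = n_i / N_i,

and converted to a percentage share

    C_i = F_i / sum_j F_j * 100.

A cell is labelled type *i* when C_i is the unique maximum and reaches
the dominance threshold (50% by default); when no share reaches the
threshold (or the top share is tied) the cell is mixed-use.  Cells with
POIs but none in the three classes are "other"; cells without any POIs
are "non_human_activity".  The same rule, applied over the sub-category
totals of a working (6 sectors) or entertainment (5 sectors) cell,
yields its sector label.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .taxonomy import (
    CategoryTaxonomy,
    LAND_USE_CLASSES,
    MIXED,
    MIXED_SECTOR,
    NON_HUMAN_ACTIVITY,
    OTHER,
)

logger = logging.getLogger(__name__)

DOMINANCE_THRESHOLD = 50.0  # percent; a share "reaching" it wins


def normalized_frequency(n_i, N_i):
    """Per-cell count divided by national total, elementwise.

    ``N_i = 0`` with a positive cell count is an inconsistency and
    raises; ``N_i = 0`` with ``n_i = 0`` yields 0 (logged).
    """
    n = np.asarray(n_i, dtype=float)
    N = np.asarray(N_i, dtype=float)
    if (n < 0).any():
        raise ValueError("cell counts must be nonnegative")
    bad = (N == 0) & (n > 0)
    if bad.any():
        raise ValueError("national total 0 with positive cell count")
    zero = N == 0
    if zero.any():
        logger.info("%d zero national totals; F set to 0", int(zero.sum()))
    out = np.divide(n, N, out=np.zeros_like(n, dtype=float), where=~zero)
    return out if out.ndim else float(out)


def category_share(F):
    """Percentage shares C_i = F_i / sum F * 100.

    Works on a single vector or on an ``(n_cells, k)`` matrix (rows are
    cells).  Rows with ``sum F = 0`` return NaN shares: they are
    undefined and the caller must fall back to a residual label.
    """
    F = np.asarray(F, dtype=float)
    if (F < 0).any():
        raise ValueError("normalized frequencies must be nonnegative")
    tot = F.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(tot > 0, F / tot * 100.0, np.nan)
    return C


def classify_shares(C, threshold: float = DOMINANCE_THRESHOLD,
                    labels=LAND_USE_CLASSES, mixed_label: str = MIXED,
                    undefined_label: str = OTHER):
    """Label rows of a share matrix by the dominance rule.

    label = labels[i]  iff C_i is the unique maximum and C_i >= threshold;
    mixed_label        iff no unique share reaches the threshold;
    undefined_label    iff the row is all-NaN (no mass to share).
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != len(labels):
        raise ValueError("share width does not match label count")
    out = np.full(C.shape[0], mixed_label, dtype=object)
    undef = np.isnan(C).all(axis=1)
    out[undef] = undefined_label
    ok = ~undef
    if ok.any():
        Cv = C[ok]
        top = Cv.max(axis=1)
        winner = Cv.argmax(axis=1)
        unique = (Cv == top[:, None]).sum(axis=1) == 1
        dominant = unique & (top >= threshold)
        lab = out[ok]
        lab[dominant] = np.asarray(labels, dtype=object)[winner[dominant]]
        out[ok] = lab
    return out


def classify_cell(C, threshold: float = DOMINANCE_THRESHOLD) -> str:
    """Label one cell from its three-class share vector."""
    return str(classify_shares(np.asarray(C, dtype=float)[None, :],
                               threshold)[0])


def classify_table(category_counts: pd.DataFrame,
                   taxonomy: CategoryTaxonomy | None = None,
                   national_totals: pd.Series | None = None,
                   threshold: float = DOMINANCE_THRESHOLD) -> pd.DataFrame:
    """Classify every cell of a per-cell, per-category count table.

    Parameters
    ----------
    category_counts : DataFrame indexed by cell_id, one column per
        first-level POI category (missing taxonomy columns count as 0).
    national_totals : per-category national totals; defaults to the
        column sums of ``category_counts`` (the study-area totals).

    Returns
    -------
    DataFrame indexed by cell_id with normalized frequencies ``F_*``,
    shares ``C_*`` (percent), ``label`` and ``sector_label``.
    """
    taxonomy = taxonomy or CategoryTaxonomy()
    counts = category_counts.reindex(
        columns=list(taxonomy.categories), fill_value=0)
    if national_totals is None:
        national_totals = counts.sum(axis=0)
    national_totals = national_totals.reindex(counts.columns, fill_value=0)

    # class-level counts and totals (Eq. 1 operates on the three classes)
    class_n = {}
    class_N = {}
    for cls in LAND_USE_CLASSES:
        cats = list(taxonomy.classes[cls])
        class_n[cls] = counts[cats].sum(axis=1).to_numpy()
        class_N[cls] = float(national_totals[cats].sum())
    F = np.column_stack([
        normalized_frequency(class_n[cls],
                             np.full(len(counts), class_N[cls]))
        for cls in LAND_USE_CLASSES
    ])
    C = category_share(F)
    labels = classify_shares(C, threshold)

    # cells with no class POIs: "other" if they hold any POI at all,
    # "non_human_activity" if truly empty
    any_poi = category_counts.sum(axis=1).to_numpy() > 0
    labels[(labels == OTHER) & ~any_poi] = NON_HUMAN_ACTIVITY

    out = pd.DataFrame(index=counts.index)
    short = {"residential": "res", "working": "work", "entertainment": "ent"}
    for j, cls in enumerate(LAND_USE_CLASSES):
        out[f"F_{short[cls]}"] = F[:, j]
        out[f"C_{short[cls]}"] = C[:, j]
    out["label"] = labels
    out["sector_label"] = [
        classify_sector(lab, counts.loc[cid], national_totals, taxonomy,
                        threshold)
        if lab in taxonomy.sector_classes else ""
        for cid, lab in zip(counts.index, labels)
    ]
    return out


def classify_sector(label: str, sub_counts, national_sub_totals,
                    taxonomy: CategoryTaxonomy | None = None,
                    threshold: float = DOMINANCE_THRESHOLD) -> str:
    """Sector of a working (6 sectors) or entertainment (5) cell.

    Reuses the normalized-frequency dominance rule over the class's
    sub-categories; no unique dominant sub-share -> ``mixed_sector``.
    """
    taxonomy = taxonomy or CategoryTaxonomy()
    if label not in taxonomy.sector_classes:
        raise ValueError(
            f"sector classification undefined for label {label!r}")
    sectors = list(taxonomy.sectors(label))
    n = np.asarray([sub_counts[s] for s in sectors], dtype=float)
    N = np.asarray([national_sub_totals[s] for s in sectors], dtype=float)
    F = normalized_frequency(n, N)
    C = category_share(F)
    return str(classify_shares(C[None, :], threshold, labels=sectors,
                               mixed_label=MIXED_SECTOR,
                               undefined_label=MIXED_SECTOR)[0])
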