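"""Trait-table assembly and phenotype normalisation.

Two microscope batches acquire the imaging phenotypes, and slight
temperature differences between them shift the clock period; the two
supported corrections are (a) a rank-based inverse normal transform
applied within each batch, z = qnorm(rank/(N + 0.5)), and (b) an additive
shift equating every batch's mean to a reference batch's mean.  The
inverse normal transform is the default input to the association stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

TRAIT_COLUMNS = [
    "sample",
    "period_mean",
    "period_intercept",
    "psm_area_um2",
    "somite_area_um2",
    "batch",
]


def inverse_normalize(values, batch_labels) -> np.ndarray:
    """Within-batch rank-based inverse normal transform.

    For observation i in batch j of size N_j (non-missing values only),
    ``z = ndtri(rank_i / (N_j + 0.5))`` with 1-based average ranks; NaNs
    propagate and do not enter the ranking.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    labels = np.asarray(batch_labels)
    if labels.shape != v.shape:
        raise ValueError("values and batch labels differ in length")
    out = np.full(v.shape, np.nan)
    for b in np.unique(labels):
        m = (labels == b) & ~np.isnan(v)
        n = int(m.sum())
        if n == 0:
            continue
        ranks = rankdata(v[m], method="average")
        out[m] = ndtri(ranks / (n + 0.5))
    return out


def equate_batch_means(values, batch_labels, reference_batch) -> np.ndarray:
    """Shift every non-reference batch additively so its mean equals the
    reference batch's mean; the reference batch is returned unchanged."""
    v = np.asarray(values, dtype=float)
    labels = np.asarray(batch_labels)
    ref_mask = labels == reference_batch
    if not ref_mask.any():
        raise ValueError(f"unknown reference batch {reference_batch!r}")
    ref_mean = np.nanmean(v[ref_mask])
    out = v.copy()
    for b in np.unique(labels):
        if b == reference_batch:
            continue
        m = labels == b
        out[m] = v[m] + (ref_mean - np.nanmean(v[m]))
    return out


def egg_volume(semi_major_b: float, semi_minor_c: float) -> float:
    """Oblate-spheroid volume V = (4/3)*pi*b^2*c (eggs approximated as
    oblate spheroids with semi-major axis b and semi-minor axis c)."""
    b = np.asarray(semi_major_b, dtype=float)
    c = np.asarray(semi_minor_c, dtype=float)
    if np.any(b < 0) or np.any(c < 0):
        raise ValueError("axes must be non-negative")
    out = (4.0 / 3.0) * np.pi * b**2 * c
    return float(out) if out.ndim == 0 else out


def assemble_trait_table(
    period_summaries: pd.DataFrame,
    size_measurements: pd.DataFrame | None = None,
    batch_map: dict[str, str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Outer-join per-sample phenotypes into one table, never dropping rows.

    ``period_summaries`` needs columns (sample, period_mean,
    period_intercept); ``size_measurements`` (sample, psm_area_um2,
    somite_area_um2) is optional, as is the sample->batch map.  Returns the
    joined table plus a join audit: ids missing from either input and
    per-column missing-value counts.
    """
    for df, name in ((period_summaries, "period summaries"), (size_measurements, "sizes")):
        if df is not None and df["sample"].duplicated().any():
            raise ValueError(f"duplicate sample ids in {name}")
    table = period_summaries.copy()
    if size_measurements is not None:
        table = table.merge(size_measurements, on="sample", how="outer")
    if batch_map is not None:
        bm = pd.Series(batch_map) if isinstance(batch_map, dict) else batch_map
        table["batch"] = table["sample"].map(bm)
    for col in TRAIT_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[TRAIT_COLUMNS + [c for c in table.columns if c not in TRAIT_COLUMNS]]
    audit = {
        "n_rows": int(len(table)),
        "only_in_periods": sorted(
            set(period_summaries["sample"])
            - (set(size_measurements["sample"]) if size_measurements is not None else set(period_summaries["sample"]))
        ),
        "only_in_sizes": sorted(
            (set(size_measurements["sample"]) if size_measurements is not None else set())
            - set(period_summaries["sample"])
        ),
        "missing_per_column": {c: int(table[c].isna().sum()) for c in TRAIT_COLUMNS if c != "sample"},
    }
    return table, audit
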