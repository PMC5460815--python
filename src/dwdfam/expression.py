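"""Tissue-expression statistics over an FPKM matrix.

The central statistic is the per-gene *maximal fold change*: the ratio of
the maximum to the minimum FPKM across tissues. The ratio is reported only
when the gene is detectable (FPKM above a detection floor) in every tissue;
a gene undetectable in some tissue gets an undefined fold change with a
reason, mirroring how genome-wide surveys exclude such genes from the
range statistic. Each gene is also assigned the tissue where it peaks
(deterministic first-column tie-break) and a flag for exceeding a fold
threshold (default 2.0).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DwdfamError


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[1] < 2:
        raise DwdfamError("expression matrix needs at least 2 tissues")
    if (matrix.values < 0).any():
        raise DwdfamError("negative FPKM values are invalid")


def max_fold_change(fpkm, detection_floor: float = 0.0) -> float:
    """max/min FPKM over tissues, or NaN when any tissue is at/below the
    detection floor (fold change undefined for partially undetectable genes)."""
    values = np.asarray(fpkm, dtype=float)
    if values.size < 2:
        raise DwdfamError("max_fold_change needs at least 2 tissues")
    if (values < 0).any():
        raise DwdfamError("negative FPKM values are invalid")
    lo = values.min()
    if lo <= detection_floor:
        return math.nan
    return float(values.max() / lo)


def specificity_calls(
    matrix: pd.DataFrame,
    fold_threshold: float = 2.0,
    detection_floor: float = 0.0,
    dominance_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene tissue-specificity statistics plus per-tissue peak counts.

    Returns ``(calls, tissue_counts)``. ``calls`` has one row per gene:

    - ``max_tissue``: tissue with the highest FPKM (ties -> first tissue in
      column order);
    - ``max_fold_change``: max/min ratio, NaN when undefined;
    - ``fold_defined`` and ``undefined_reason``;
    - ``above_threshold``: defined fold change strictly greater than
      ``fold_threshold``;
    - ``dominant``: peak tissue carries >= ``dominance_fraction`` of the row
      total ("highly expressed in one or few tissues" descriptor).

    ``tissue_counts`` counts genes peaking per tissue and sums to the gene
    count.
    """
    _check_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    tissues = list(matrix.columns)
    peak_idx = values.argmax(axis=1)  # argmax takes the first maximum: our tie-break
    mfc = np.array([max_fold_change(row, detection_floor) for row in values])
    defined = ~np.isnan(mfc)
    totals = values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        peak_share = values[np.arange(len(values)), peak_idx] / np.where(
            totals > 0, totals, np.nan
        )
    calls = pd.DataFrame(
        {
            "max_tissue": [tissues[i] for i in peak_idx],
            "max_fold_change": mfc,
            "fold_defined": defined,
            "undefined_reason": [
                "" if d else f"FPKM <= detection floor ({detection_floor:g}) in some tissue"
                for d in defined
            ],
            "above_threshold": defined & (mfc > fold_threshold),
            "dominant": np.nan_to_num(peak_share) >= dominance_fraction,
        },
        index=matrix.index,
    )
    tissue_counts = (
        calls["max_tissue"].value_counts().reindex(tissues, fill_value=0).astype(int)
    )
    return calls, tissue_counts


def normalize_for_heatmap(
    matrix: pd.DataFrame, method: str = "row-zscore"
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize each gene's row across tissues for heatmap display.

    ``row-zscore``: (x - mean)/sd per row; constant rows become all zeros and
    are flagged. ``row-max``: x/max per row, in [0, 1] (all-zero rows stay
    zero and are flagged). Returns ``(normalized, constant_row_flags)``. Gene
    order is preserved (no clustering).
    """
    _check_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    if method == "row-zscore":
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=0, keepdims=True)
        flat = sd[:, 0] == 0
        sd[flat] = 1.0
        out = (values - mean) / sd
        out[flat] = 0.0
    elif method == "row-max":
        mx = values.max(axis=1, keepdims=True)
        flat = mx[:, 0] == 0
        mx[flat] = 1.0
        out = values / mx
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return (
        pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
        pd.Series(flat, index=matrix.index, name="constant_row"),
    )
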