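"""Symmetric Kullback-Leibler comparison of connectivity patterns.

Two grey-matter locations, one per blueprint, are compared through their
rows ``m`` and ``h`` (probability vectors over a shared tract set) with the
symmetric KL divergence in bits:

    D = sum_k m_k log2(m_k / h_k) + sum_k h_k log2(h_k / m_k)

To avoid degeneracies from zeros, both rows are shifted elementwise by a
small delta (default 1e-6) before evaluation, without renormalisation.
Homologue matching picks, for each reference region in one blueprint, the
minimum-divergence region in the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blueprint import ConnectivityBlueprint

logger = logging.getLogger(__name__)

__all__ = [
    "DivergenceResult",
    "symmetric_kl",
    "reference_pattern",
    "divergence_map",
    "best_match_region",
    "match_structures",
]

TRACT_SUBSETS = ("all", "cortico-cortical", "cortico-subcortical")


@dataclass
class DivergenceResult:
    reference_label: str
    row_ids: list[str]
    values: np.ndarray  # bits, one per location
    delta: float
    tract_subset: str = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("divergences must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.row_ids, name=self.reference_label)


def symmetric_kl(m_row, h_row, delta: float = 1e-6) -> float:
    """Symmetric KL divergence in bits after an elementwise delta shift."""
    m = np.asarray(m_row, dtype=float)
    h = np.asarray(h_row, dtype=float)
    if m.shape != h.shape:
        raise ValueError("rows must have equal length")
    if np.any(m < 0) or np.any(h < 0):
        raise ValueError("rows must be non-negative")
    m = m + delta
    h = h + delta
    ratio = np.log2(m / h)
    return float(np.sum(m * ratio) - np.sum(h * ratio))


def reference_pattern(blueprint: ConnectivityBlueprint, roi_rows: list[str]) -> np.ndarray:
    """Mean of the selected rows, renormalised to a probability vector."""
    if not roi_rows:
        raise ValueError("empty ROI")
    idx = [blueprint.row_ids.index(r) for r in roi_rows]
    mean = blueprint.matrix[idx].mean(axis=0)
    total = mean.sum()
    if total <= 0:
        raise ValueError("ROI rows have zero total mass")
    return mean / total


def _subset_columns(blueprint: ConnectivityBlueprint, tract_subset: str) -> list[int]:
    if tract_subset == "all":
        return list(range(len(blueprint.tract_names)))
    if tract_subset not in TRACT_SUBSETS:
        raise ValueError(f"unknown tract subset {tract_subset!r}")
    classes = blueprint.tract_classes or {}
    cols = [
        i for i, t in enumerate(blueprint.tract_names) if classes.get(t) == tract_subset
    ]
    if not cols:
        raise ValueError(f"no tracts of class {tract_subset!r} in blueprint")
    return cols


def divergence_map(
    reference: np.ndarray,
    blueprint: ConnectivityBlueprint,
    tract_subset: str = "all",
    delta: float = 1e-6,
    reference_label: str = "reference",
) -> DivergenceResult:
    """Symmetric KL of every blueprint row against a reference pattern.

    With a tract subset, both the reference and each row are restricted to
    the subset columns and renormalised before comparison so the divergence
    operates on comparable masses.
    """
    cols = _subset_columns(blueprint, tract_subset)
    ref = np.asarray(reference, dtype=float)[cols]
    total = ref.sum()
    if total <= 0:
        raise ValueError("tract subset yields a zero-mass reference")
    ref = ref / total
    rows = blueprint.matrix[:, cols]
    sums = rows.sum(axis=1, keepdims=True)
    rows = np.divide(rows, sums, out=rows.astype(float).copy(), where=sums > 0)
    values = np.array([symmetric_kl(ref, row, delta=delta) for row in rows])
    return DivergenceResult(
        reference_label=reference_label,
        row_ids=list(blueprint.row_ids),
        values=values,
        delta=delta,
        tract_subset=tract_subset,
    )


def best_match_region(result: DivergenceResult, percentile: float = 7.0) -> set[str]:
    """Locations with divergence below the given percentile of the map."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    thr = np.percentile(result.values, percentile)
    sel = result.values < thr
    if not sel.any():
        logger.warning("best_match_region: degenerate (constant) divergence map")
        return set()
    return {rid for rid, s in zip(result.row_ids, sel) if s}


def match_structures(
    blueprint_a: ConnectivityBlueprint,
    blueprint_b: ConnectivityBlueprint,
    roi_sets_a: dict[str, list[str]],
    roi_sets_b: dict[str, list[str]],
    delta: float = 1e-6,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All-pairs divergence between ROI reference patterns plus the per-row
    argmin assignment (homologue identification)."""
    if len(roi_sets_a) < 2 or len(roi_sets_b) < 2:
        raise ValueError("need at least two ROIs per side")
    refs_a = {lab: reference_pattern(blueprint_a, rows) for lab, rows in roi_sets_a.items()}
    refs_b = {lab: reference_pattern(blueprint_b, rows) for lab, rows in roi_sets_b.items()}
    table = pd.DataFrame(
        {
            lab_b: [symmetric_kl(ra, rb, delta=delta) for ra in refs_a.values()]
            for lab_b, rb in refs_b.items()
        },
        index=list(refs_a),
    )
    assignment = {lab_a: table.loc[lab_a].idxmin() for lab_a in table.index}
    return table, assignment
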