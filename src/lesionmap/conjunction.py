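"""Conjunction of two lesion-symptom maps: shared vs selective voxels.

Given z maps from two analyses (here: an upper-limb paresis score and an
elbow-flexor spasticity threshold) thresholded at a common per-voxel
criterion, every tested voxel is classified as significant in neither, A
only, B only, or both. The selective fractions (share of each analysis'
significant voxels that the other analysis does not flag) quantify how much
of the two lesion-behavior networks is distinct. Unlike cluster reporting,
classification is per-voxel: no minimum contiguous extent is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lesion_io import AtlasVolume

__all__ = [
    "CATEGORY_NAMES",
    "ConjunctionResult",
    "classify",
    "selective_fractions",
    "tabulate",
]

CATEGORY_NAMES = {0: "none", 1: "A_only", 2: "B_only", 3: "both"}


@dataclass
class ConjunctionResult:
    """Per-voxel category volume plus the category counts."""

    category: np.ndarray  # int volume with values {0, 1, 2, 3}
    counts: dict[str, int]
    z_star: float
    score_a: str = "A"
    score_b: str = "B"

    def recount(self) -> dict[str, int]:
        """Recompute the counts from the category volume (consistency check)."""
        a_only = int((self.category == 1).sum())
        b_only = int((self.category == 2).sum())
        both = int((self.category == 3).sum())
        return {
            "A_only": a_only,
            "B_only": b_only,
            "both": both,
            "A_total": a_only + both,
            "B_total": b_only + both,
        }


def classify(
    z_a: np.ndarray,
    z_b: np.ndarray,
    inclusion: np.ndarray,
    z_star: float,
    score_a: str = "A",
    score_b: str = "B",
) -> ConjunctionResult:
    """Threshold both z maps at ``z_star`` within the tested voxels and label.

    Both analyses share the per-voxel criterion (a common z cutoff, e.g. the
    minimum z surviving FDR in the better-powered analysis) rather than each
    analysis' own corrected cutoff, so the categories are comparable.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    inclusion = np.asarray(inclusion, dtype=bool)
    if not (z_a.shape == z_b.shape == inclusion.shape):
        raise ValueError("z maps and inclusion mask must share one grid shape")
    sig_a = inclusion & (np.nan_to_num(z_a, nan=-np.inf) >= z_star)
    sig_b = inclusion & (np.nan_to_num(z_b, nan=-np.inf) >= z_star)
    category = sig_a.astype(np.int8) + 2 * sig_b.astype(np.int8)
    result = ConjunctionResult(
        category=category,
        counts={},
        z_star=float(z_star),
        score_a=score_a,
        score_b=score_b,
    )
    result.counts = result.recount()
    return result


def selective_fractions(
    counts: ConjunctionResult | dict[str, int],
) -> tuple[float, float]:
    """Percentage of each analysis' significant voxels that are selective.

    Accepts a :class:`ConjunctionResult` or a plain counts mapping with keys
    ``A_only``, ``B_only``, ``A_total``, ``B_total`` (so printed counts from a
    published table can be fed directly). Returns raw float percentages;
    round for reporting. Undefined (NaN) when a total is zero.
    """
    c = counts.counts if isinstance(counts, ConjunctionResult) else counts
    pct_a = 100.0 * c["A_only"] / c["A_total"] if c["A_total"] > 0 else float("nan")
    pct_b = 100.0 * c["B_only"] / c["B_total"] if c["B_total"] > 0 else float("nan")
    return pct_a, pct_b


def tabulate(
    result: ConjunctionResult,
    atlas: AtlasVolume,
    min_report: int = 10,
    row_filter: str = "any",
) -> pd.DataFrame:
    """Per-structure counts in the three categories.

    A structure is retained when it reaches ``min_report`` voxels in at least
    one category (``row_filter="any"``, the default) or summed over the three
    (``row_filter="sum"``). No contiguity requirement applies, so structures
    can appear here that never formed a reportable cluster.
    """
    if result.category.shape != atlas.grid.dims:
        raise ValueError("category volume does not match atlas grid")
    if row_filter not in ("any", "sum"):
        raise ValueError("row_filter must be 'any' or 'sum'")
    labels = atlas.labels.ravel()
    cat = result.category.ravel()
    rows = []
    for label in np.unique(labels[cat > 0]):
        here = labels == label
        a_only = int(((cat == 1) & here).sum())
        b_only = int(((cat == 2) & here).sum())
        both = int(((cat == 3) & here).sum())
        keep = (
            max(a_only, b_only, both) >= min_report
            if row_filter == "any"
            else a_only + b_only + both >= min_report
        )
        if keep:
            rows.append(
                {
                    "structure": atlas.name_of(int(label)),
                    "A_only": a_only,
                    "B_only": b_only,
                    "both": both,
                }
            )
    df = pd.DataFrame(rows, columns=["structure", "A_only", "B_only", "both"])
    if len(df):
        df = df.sort_values(
            ["A_only", "B_only", "both"], ascending=False, ignore_index=True
        )
    return df
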