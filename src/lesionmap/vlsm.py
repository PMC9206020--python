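"""Voxel-based lesion-symptom mapping (VLSM).

At every voxel covered by enough of the cohort, subjects are split into
lesioned-here vs intact-here groups and their behavioral scores compared with
a Mann-Whitney rank test. The z statistic is the tie-corrected normal
approximation of U, signed so that z > 0 means the lesioned group scores
WORSE (lower FMA-UL, lower TSRT); p is the one-sided upper normal tail.
Multiple comparisons are handled by Benjamini-Hochberg FDR over the tested
voxels, with a "lenient" fixed-z fallback whose threshold can be derived from
the minimum z surviving FDR in a reference analysis. Significant voxels are
reported as connected clusters of a minimum size, localized to atlas
structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm, rankdata

from .lesion_io import AtlasVolume, Cohort, VolumeGrid

__all__ = [
    "VlsmResult",
    "Cluster",
    "inclusion_mask",
    "voxel_test",
    "map_scores",
    "fdr_select",
    "lenient_select",
    "derive_lenient_threshold",
    "extract_clusters",
    "report_voxel",
    "tabulate_structures",
]

#: Default fraction of the cohort that must be lesioned at a voxel to test it.
DEFAULT_COVERAGE = 0.20
#: Default minimum cluster extent (contiguous significant voxels) to report.
DEFAULT_MIN_CLUSTER = 10
#: Default voxel adjacency for clustering (6, 18 or 26 neighbours).
DEFAULT_ADJACENCY = 26


@dataclass
class VlsmResult:
    """Maps and thresholds from one lesion-symptom analysis of one score."""

    score_name: str
    grid: VolumeGrid
    inclusion: np.ndarray  # bool volume: voxels actually tested
    z: np.ndarray  # float volume, NaN outside inclusion
    p: np.ndarray  # one-sided p, NaN outside inclusion
    min_lesioned: int
    n_subjects: int
    sig: np.ndarray | None = None  # bool volume after selection
    threshold_info: dict = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return int(self.inclusion.sum())

    @property
    def n_significant(self) -> int:
        return 0 if self.sig is None else int(self.sig.sum())


@dataclass(frozen=True)
class Cluster:
    """A connected component of significant voxels."""

    voxels: np.ndarray  # (k, 3) int indices
    size: int
    max_z: float
    report_voxel: tuple[int, int, int]
    report_mm: tuple[float, float, float]


def inclusion_mask(
    cohort: Cohort, coverage: float = DEFAULT_COVERAGE
) -> tuple[np.ndarray, int]:
    """Voxels lesioned in at least ``coverage`` of the cohort.

    The count threshold is floor(coverage * n): for n=41 at 20% this is 8
    subjects. A voxel additionally needs at least 2 intact subjects so the
    two-group comparison is non-degenerate.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    n = cohort.n_subjects
    if n < 2:
        raise ValueError("inclusion mask needs >= 2 subjects")
    min_lesioned = math.floor(coverage * n)
    counts = np.zeros(cohort.grid.dims, dtype=np.int32)
    for m in cohort.masks:
        counts += m.data
    included = (counts >= max(min_lesioned, 1)) & (n - counts >= 2)
    return included, min_lesioned


def _rank_stats(scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks of the pooled scores and the tie-correction term sum(t^3-t)."""
    ranks = rankdata(scores)
    _, counts = np.unique(scores, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    return ranks, tie_term


def _z_from_ranksum(
    rank_sum_lesioned: np.ndarray,
    n1: np.ndarray,
    n_total: int,
    tie_term: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed z and one-sided p from the lesioned group's rank sum.

    U1 = R1 - n1(n1+1)/2 counts lesioned-beats-intact pairs; z is
    (E[U] - U1) / sd(U) with the tie-corrected variance and no continuity
    correction, so z > 0 exactly when the lesioned group ranks lower (scores
    worse). Degenerate voxels (all scores tied) get z = 0, p = 0.5.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = n_total - n1
    u1 = np.asarray(rank_sum_lesioned, dtype=float) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = (
        n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1.0)))
    )
    z = np.zeros_like(u1)
    ok = var > 0
    z[ok] = (mu[ok] - u1[ok]) / np.sqrt(var[ok])
    p = norm.sf(z)
    return z, p


def voxel_test(
    lesioned_scores: np.ndarray, intact_scores: np.ndarray
) -> tuple[float, float]:
    """Mann-Whitney comparison of one voxel's lesioned vs intact scores.

    Returns (z, one-sided p) with z > 0 when the lesioned subjects score
    worse. If every observation is tied across both groups the voxel carries
    no signal and (0.0, 0.5) is returned.
    """
    x = np.asarray(lesioned_scores, dtype=float)
    y = np.asarray(intact_scores, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks, tie_term = _rank_stats(pooled)
    z, p = _z_from_ranksum(
        np.array([ranks[: len(x)].sum()]),
        np.array([len(x)]),
        len(pooled),
        tie_term,
    )
    return float(z[0]), float(p[0])


def map_scores(
    cohort: Cohort, score_name: str, inclusion: np.ndarray, min_lesioned: int = 0
) -> VlsmResult:
    """Run the voxelwise test at every included voxel for one score.

    Because the pooled sample at every voxel is the whole cohort, the score
    ranks and the tie correction are shared across voxels; only the group
    split varies, so the whole map reduces to one rank-sum matrix product.
    The scalar :func:`voxel_test` on the per-voxel partitions gives identical
    values (asserted in the test suite).
    """
    scores = cohort.score_vector(score_name)
    inclusion = np.asarray(inclusion, dtype=bool)
    if inclusion.shape != cohort.grid.dims:
        raise ValueError("inclusion mask shape does not match cohort grid")
    z_vol = np.full(cohort.grid.dims, np.nan)
    p_vol = np.full(cohort.grid.dims, np.nan)
    flat_idx = np.flatnonzero(inclusion.ravel())
    if len(flat_idx) == 0:
        import warnings

        warnings.warn(f"no voxels included for score '{score_name}'")
    else:
        lesions = cohort.lesion_matrix()[:, flat_idx]  # (n_subjects, m)
        ranks, tie_term = _rank_stats(scores)
        n1 = lesions.sum(axis=0).astype(float)
        rank_sums = ranks @ lesions
        z, p = _z_from_ranksum(rank_sums, n1, cohort.n_subjects, tie_term)
        z_vol.ravel()[flat_idx] = z
        p_vol.ravel()[flat_idx] = p
    return VlsmResult(
        score_name=score_name,
        grid=cohort.grid,
        inclusion=inclusion,
        z=z_vol,
        p=p_vol,
        min_lesioned=min_lesioned,
        n_subjects=cohort.n_subjects,
    )


def bh_reject(p_values: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: reject p_(i) <= i*q/m up to the largest i.

    Returns a boolean rejection vector and the realized p cutoff (NaN when
    nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), float("nan")
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(sorted_p <= thresholds)
    if len(passing) == 0:
        return np.zeros(m, dtype=bool), float("nan")
    cutoff = sorted_p[passing[-1]]
    return p <= cutoff, float(cutoff)


def fdr_select(result: VlsmResult, q: float = 0.05) -> VlsmResult:
    """Mark voxels significant by BH-FDR over the included voxels' p values."""
    flat_idx = np.flatnonzero(result.inclusion.ravel())
    reject, p_star = bh_reject(result.p.ravel()[flat_idx], q)
    sig = np.zeros(result.grid.dims, dtype=bool)
    sig.ravel()[flat_idx] = reject
    z_star = float(norm.isf(p_star)) if np.isfinite(p_star) else float("nan")
    info = {"mode": "fdr", "q": float(q), "p_star": p_star, "z_star": z_star}
    return replace(result, sig=sig, threshold_info=info)


def lenient_select(result: VlsmResult, z_star: float) -> VlsmResult:
    """Mark voxels with z >= z_star significant (uncorrected fixed criterion)."""
    with np.errstate(invalid="ignore"):
        sig = result.inclusion & (np.nan_to_num(result.z, nan=-np.inf) >= z_star)
    info = {
        "mode": "lenient",
        "q": None,
        "p_star": float(norm.sf(z_star)),
        "z_star": float(z_star),
    }
    return replace(result, sig=sig, threshold_info=info)


def derive_lenient_threshold(reference: VlsmResult) -> float:
    """Minimum z among the reference analysis' FDR-significant voxels.

    This is how a better-powered analysis (FMA-UL here) lends its realized
    per-voxel severity cutoff to an under-powered one (TSRT).
    """
    if reference.sig is None or reference.n_significant == 0:
        raise ValueError("reference analysis has no significant voxels")
    return float(np.nanmin(reference.z[reference.sig]))


def _adjacency_structure(adjacency: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[adjacency]
    except KeyError:
        raise ValueError("adjacency must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


def report_voxel(
    voxels: np.ndarray, z_values: np.ndarray, grid: VolumeGrid
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Pick the cluster's reported voxel among those attaining the maximum z.

    Ties on z are broken by world position: most superior (greatest world z),
    then most posterior (least world y), then most left (least world x). The
    centroid is deliberately not used - it may not attain the maximum, or even
    be significant.
    """
    voxels = np.asarray(voxels)
    z_values = np.asarray(z_values, dtype=float)
    if len(voxels) == 0:
        raise ValueError("empty cluster")
    at_max = voxels[z_values == z_values.max()]
    world = grid.voxel_to_world(at_max)
    order = np.lexsort((world[:, 0], world[:, 1], -world[:, 2]))
    pick = order[0]
    idx = tuple(int(v) for v in at_max[pick])
    mm = tuple(float(v) for v in world[pick])
    return idx, mm


def extract_clusters(
    result: VlsmResult,
    min_size: int = DEFAULT_MIN_CLUSTER,
    adjacency: int = DEFAULT_ADJACENCY,
) -> list[Cluster]:
    """Connected components of the significance mask, size-filtered.

    Thresholding happens first (``result.sig``), then components under the
    chosen adjacency, then the minimum-extent filter; clusters are returned
    largest-max-z first.
    """
    if result.sig is None:
        raise ValueError("run fdr_select or lenient_select before clustering")
    labeled, n_comp = ndimage.label(result.sig, structure=_adjacency_structure(adjacency))
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        voxels = np.argwhere(labeled == comp)
        if len(voxels) < min_size:
            continue
        z_vals = result.z[tuple(voxels.T)]
        idx, mm = report_voxel(voxels, z_vals, result.grid)
        clusters.append(
            Cluster(
                voxels=voxels,
                size=len(voxels),
                max_z=float(z_vals.max()),
                report_voxel=idx,
                report_mm=mm,
            )
        )
    clusters.sort(key=lambda c: -c.max_z)
    return clusters


def tabulate_structures(
    result: VlsmResult, clusters: list[Cluster], atlas: AtlasVolume
) -> pd.DataFrame:
    """Per-structure summary of the reported clusters' voxels.

    For each atlas structure intersecting any reported cluster: the count of
    in-cluster significant voxels it contains, that count as a percentage of
    the structure's size, the structure-wise max z and its reported voxel
    coordinates. Significant voxels on unlabeled atlas voxels appear under
    "unlabeled" (with undefined % area).
    """
    result.grid.require_match(atlas.grid, "atlas")
    if not clusters:
        return pd.DataFrame(
            columns=["structure", "max_z", "x_mm", "y_mm", "z_mm", "n_voxels", "percent_area"]
        )
    all_voxels = np.vstack([c.voxels for c in clusters])
    labels_at = atlas.labels[tuple(all_voxels.T)]
    z_at = result.z[tuple(all_voxels.T)]
    sizes = np.bincount(atlas.labels.ravel())
    rows = []
    for label in np.unique(labels_at):
        in_struct = labels_at == label
        voxels = all_voxels[in_struct]
        z_vals = z_at[in_struct]
        _, mm = report_voxel(voxels, z_vals, result.grid)
        struct_size = int(sizes[label]) if label < len(sizes) else 0
        rows.append(
            {
                "structure": atlas.name_of(int(label)),
                "max_z": float(z_vals.max()),
                "x_mm": mm[0],
                "y_mm": mm[1],
                "z_mm": mm[2],
                "n_voxels": int(in_struct.sum()),
                "percent_area": (
                    100.0 * in_struct.sum() / struct_size if label != 0 else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values("max_z", ascending=False, ignore_index=True)
    return df
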