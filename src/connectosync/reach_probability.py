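"""Tract-to-ROI reach probability and the binary structural connectome.

A tract is summarized by its probabilistic-tractography path distribution: a
non-negative 3-D grid of path counts.  For each grey-matter ROI the "reach
probability" of a tract is the mean, over the ROI's one-voxel-deep boundary
mask facing white matter, of the tract's normalized per-voxel path
probability, where normalization divides by the total path count over the
trimmed support (white matter plus all ROI boundary masks).  Thresholding the
resulting tract x ROI matrix yields the binary structural connectome, and
mapping expression regions onto atlas ROIs classifies region pairs as
not-bound, tract-bound, or AD-tract-bound.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from connectosync.exceptions import (
    DegenerateTractError,
    MappingError,
    ThresholdError,
)

#: Tracts whose diagnosis associations replicated across cohorts; used as the
#: default disease-associated tract list for region-pair classification.
DEFAULT_AD_TRACTS = ("L-CAB", "L-ILF", "L-SLFT", "L-SLFP")

NOT_BOUND = "not-bound"
TRACT_BOUND = "tract-bound"
AD_TRACT_BOUND = "AD-tract-bound"


@dataclass(frozen=True)
class LabelVolume:
    """3-D integer label grid: 0 = background, ``wm_label`` = white matter,
    remaining positive labels are grey-matter ROIs."""

    values: np.ndarray
    wm_label: int = 1
    background_label: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or not np.issubdtype(v.dtype, np.integer):
            raise ValueError("label volume must be a 3-D integer grid")
        if (v < 0).any():
            raise ValueError("labels must be non-negative")
        if not (v == self.wm_label).any():
            raise ValueError("white-matter label absent from volume")

    @property
    def roi_labels(self) -> list[int]:
        labels = np.unique(self.values)
        return [
            int(l)
            for l in labels
            if l not in (self.background_label, self.wm_label)
        ]


@dataclass(frozen=True)
class TractPathVolume:
    """Per-voxel path counts for one tract, same grid as the label volume."""

    tract_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("path-count volume must be 3-D")
        if (c < 0).any():
            raise ValueError(f"tract {self.tract_id}: negative path counts")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def boundary_mask(
    labels: LabelVolume, roi: int, connectivity: int = 6
) -> np.ndarray:
    """One-voxel-deep grey-matter mask of ``roi`` neighbouring white matter.

    A voxel belongs to the mask iff it carries the ROI label and at least one
    face-adjacent voxel (6-connectivity by default, 26 optional) is white
    matter.
    """
    if roi not in labels.roi_labels:
        raise MappingError(f"unknown ROI label {roi!r}")
    wm = labels.values == labels.wm_label
    near_wm = ndimage.binary_dilation(wm, structure=_structure(connectivity))
    return (labels.values == roi) & near_wm


def trimmed_support(
    labels: LabelVolume, rois: list[int] | None = None, connectivity: int = 6
) -> np.ndarray:
    """White matter plus the boundary masks of all requested ROIs."""
    if rois is None:
        rois = labels.roi_labels
    support = labels.values == labels.wm_label
    for roi in rois:
        support |= boundary_mask(labels, roi, connectivity)
    return support


def reach_probability(
    tract: TractPathVolume,
    labels: LabelVolume,
    rois: list[int] | None = None,
    connectivity: int = 6,
) -> pd.Series:
    """Reach probability of one tract toward each ROI.

    The tract's path counts are trimmed to white matter plus all ROI boundary
    masks, each surviving voxel is normalized by the total trimmed path count,
    and the normalized values are averaged over each ROI's boundary mask
    (zero-count mask voxels included).  An ROI with an empty boundary mask
    gets reach probability 0.
    """
    if tract.counts.shape != labels.values.shape:
        raise ValueError(
            f"tract {tract.tract_id}: shape {tract.counts.shape} does not "
            f"match label volume {labels.values.shape}"
        )
    if rois is None:
        rois = labels.roi_labels
    masks = {roi: boundary_mask(labels, roi, connectivity) for roi in rois}
    support = labels.values == labels.wm_label
    for m in masks.values():
        support |= m

    counts = np.asarray(tract.counts, dtype=float)
    total = counts[support].sum()
    if total <= 0:
        raise DegenerateTractError(
            f"tract {tract.tract_id}: no path mass on trimmed support"
        )
    norm = np.where(support, counts / total, 0.0)

    out = {}
    for roi, mask in masks.items():
        out[roi] = float(norm[mask].mean()) if mask.any() else 0.0
    return pd.Series(out, name=tract.tract_id)


def reach_probability_matrix(
    tracts: list[TractPathVolume],
    labels: LabelVolume,
    rois: list[int] | None = None,
    connectivity: int = 6,
) -> pd.DataFrame:
    """Tract x ROI reach-probability matrix (rows = tracts, columns = ROIs)."""
    rows = [reach_probability(t, labels, rois, connectivity) for t in tracts]
    return pd.DataFrame(rows)


def ecdf_reflection_cutoff(values: np.ndarray) -> float:
    """Elbow ("reflection point") of the reach-probability ECDF.

    The sorted non-zero values are placed on axes normalized to [0, 1] with
    the origin anchoring the zero-probability mass; the cutoff is the value
    maximizing the distance between the ECDF point and the chord joining the
    origin to the largest value.  For a heavy-zero matrix with a separated
    cluster of genuine connections this lands at the bottom edge of the
    cluster; for extreme-value-like data it lands at the shoulder where the
    steep rise flattens.
    """
    v = np.asarray(values, dtype=float)
    nz = np.sort(v[v > 0])
    if nz.size == 0:
        raise ThresholdError("all reach probabilities are zero")
    if nz.size == 1:
        return float(nz[0])
    x = nz / nz[-1]
    f = np.arange(1, nz.size + 1) / nz.size
    dist = np.abs(f - x)
    # ties -> smallest value, via argmax on first occurrence of max
    return float(nz[int(np.argmax(dist))])


@dataclass
class ConnectionSet:
    """Binary tract x ROI connectome at a reach-probability cutoff."""

    cutoff: float
    connected: pd.DataFrame
    mode: str
    gumbel_fit: tuple[float, float] | None = None

    @property
    def n_connections(self) -> int:
        return int(self.connected.to_numpy().sum())


def connection_threshold(
    matrix: pd.DataFrame,
    mode: str = "ecdf_reflection",
    cutoff: float | None = None,
) -> ConnectionSet:
    """Binarize a reach-probability matrix into a ConnectionSet.

    ``mode="fixed"`` uses the supplied cutoff (the original study shipped
    0.002); ``mode="ecdf_reflection"`` derives it from the ECDF elbow of the
    non-zero entries.  A Gumbel (extreme-value) fit of the non-zero entries is
    reported as a distributional diagnostic.
    """
    values = matrix.to_numpy(dtype=float)
    nz = values[values > 0]
    if nz.size == 0:
        raise ThresholdError("all reach probabilities are zero")
    if mode == "fixed":
        if cutoff is None:
            raise ValueError("fixed mode requires a cutoff")
        cut = float(cutoff)
    elif mode == "ecdf_reflection":
        cut = ecdf_reflection_cutoff(values)
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    loc, scale = stats.gumbel_r.fit(nz)
    return ConnectionSet(
        cutoff=cut,
        connected=matrix >= cut,
        mode=mode,
        gumbel_fit=(float(loc), float(scale)),
    )


@dataclass
class RegionPairClasses:
    """Classification of expression-region pairs by tract binding."""

    pairs: pd.DataFrame  # columns: region_a, region_b, klass
    counts: dict[str, int] = field(default_factory=dict)

    def klass(self, region_a: str, region_b: str) -> str:
        a, b = sorted((region_a, region_b))
        row = self.pairs[
            (self.pairs.region_a == a) & (self.pairs.region_b == b)
        ]
        if row.empty:
            raise MappingError(f"unknown region pair ({region_a}, {region_b})")
        return row.klass.iloc[0]


def classify_region_pairs(
    conn: ConnectionSet,
    region_map: pd.DataFrame,
    ad_tracts: tuple[str, ...] = DEFAULT_AD_TRACTS,
) -> RegionPairClasses:
    """Classify every unordered region pair by tract binding.

    ``region_map`` maps expression-region ids to atlas ROI labels
    (columns ``region_id``, ``roi_id``; a region may map to several ROIs).
    A pair (A, B) is tract-bound iff some connected tract reaches an ROI of A
    and an ROI of B; AD-tract-bound iff such a tract is in ``ad_tracts``.
    """
    if not {"region_id", "roi_id"}.issubset(region_map.columns):
        raise ValueError("region_map needs columns region_id, roi_id")
    rois_of = {
        str(r): set(g.roi_id.tolist())
        for r, g in region_map.groupby("region_id")
    }
    regions = sorted(rois_of)
    known_rois = set(conn.connected.columns)
    for region, rois in rois_of.items():
        if not rois & known_rois:
            raise MappingError(
                f"region {region!r} maps to no ROI present in the connectome"
            )

    bound = conn.connected
    tract_rois = {
        t: set(bound.columns[bound.loc[t].to_numpy()]) for t in bound.index
    }
    unknown_ad = set(ad_tracts) - set(bound.index)
    ad_present = set(ad_tracts) & set(bound.index)
    if unknown_ad and not ad_present:
        ad_present = set()  # no AD tracts in this connectome; class never used

    rows = []
    for a, b in itertools.combinations(regions, 2):
        klass = NOT_BOUND
        for tract, rois in tract_rois.items():
            if rois & rois_of[a] and rois & rois_of[b]:
                if tract in ad_present:
                    klass = AD_TRACT_BOUND
                    break
                klass = TRACT_BOUND
        rows.append((a, b, klass))
    pairs = pd.DataFrame(rows, columns=["region_a", "region_b", "klass"])
    counts = pairs.klass.value_counts().to_dict()
    for k in (NOT_BOUND, TRACT_BOUND, AD_TRACT_BOUND):
        counts.setdefault(k, 0)
    return RegionPairClasses(pairs=pairs, counts=counts)
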