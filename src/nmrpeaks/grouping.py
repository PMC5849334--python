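"""Grouping detected peaks across samples into features.

A feature is a group of peaks with at most one peak per sample.  Peaks are
first split into contiguous index segments (gaps wider than the group span
cannot belong to one feature), then hierarchically clustered on the Gower
distance over the chosen peak variables, and the dendrogram is cut top-down
into clusters that satisfy the span and one-per-sample constraints.  Extra
same-sample peaks inside an otherwise good cluster are deleted (nearest to
the group median wins) and can be re-adopted later by peak filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .cwt_peaks import PEAK_COLUMNS


@dataclass
class GroupingParams:
    variables: tuple[str, ...] = ("ppm",)
    linkage: str = "average"  # or "complete"
    max_group_span: float = 10.0  # measurement points
    min_samples: int = 1
    max_duplicate_frac: float = 0.1

    def __post_init__(self) -> None:
        if "ppm" not in self.variables:
            raise ValueError("'ppm' must always be a grouping variable")
        if self.linkage not in {"average", "complete"}:
            raise ValueError("linkage must be 'average' or 'complete'")


@dataclass
class FeatureGroup:
    """A cluster of peaks, at most one per sample."""

    feature_id: int
    members: pd.DataFrame
    deleted: pd.DataFrame
    center_index: int = field(init=False)
    center_ppm: float = field(init=False)
    mean_scale: float = field(init=False)

    def __post_init__(self) -> None:
        # duplicates are tolerated here so enforce_single_peak can take a
        # violating group as input; build_feature_matrix re-checks
        if len(self.members) == 0:
            raise ValueError("a feature group needs at least one member")
        self.center_index = int(round(float(self.members["peak_index"].median())))
        self.center_ppm = float(self.members["ppm"].median())
        self.mean_scale = float(self.members["scale"].mean())

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return int(self.members["peak_index"].max() - self.members["peak_index"].min())


@dataclass
class GroupingResult:
    """Accepted groups plus the peaks dropped by the min_samples filter."""

    groups: list[FeatureGroup]
    dropped: pd.DataFrame

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)

    def __getitem__(self, i):
        return self.groups[i]


def gower_distance(points: pd.DataFrame) -> np.ndarray:
    """Pairwise Gower distance: mean over variables of range-normalised
    absolute differences.  Constant variables contribute 0 (but still count
    in the mean); the result is symmetric with zero diagonal in [0, 1]."""
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, v = x.shape
    d = np.zeros((n, n))
    for j in range(v):
        col = x[:, j]
        rng = col.max() - col.min()
        if rng > 0:
            d += np.abs(col[:, None] - col[None, :]) / rng
    return d / v


def enforce_single_peak(group: FeatureGroup) -> FeatureGroup:
    """Delete extra same-sample peaks: keep the one nearest the group median
    index; ties broken by larger peak_value, then lower index."""
    m = group.members
    if not m["sample_id"].duplicated().any():
        return group
    median = float(m["peak_index"].median())
    m = m.assign(
        _dist=(m["peak_index"] - median).abs(),
        _negval=-m["peak_value"].astype(float),
    ).sort_values(["_dist", "_negval", "peak_index"], kind="stable")
    keep = m.drop_duplicates("sample_id", keep="first")
    drop = m.loc[~m.index.isin(keep.index)]
    keep = keep.drop(columns=["_dist", "_negval"]).sort_values("peak_index")
    drop = drop.drop(columns=["_dist", "_negval"]).sort_values("peak_index")
    deleted = pd.concat([group.deleted, drop], ignore_index=True)
    return FeatureGroup(group.feature_id, keep.reset_index(drop=True), deleted)


def _cut_cluster(
    peaks: pd.DataFrame, idxs: list[int], node, params: GroupingParams, out: list
) -> None:
    sub = peaks.iloc[idxs]
    span = float(sub["peak_index"].max() - sub["peak_index"].min())
    n_samples = sub["sample_id"].nunique()
    n_dup = len(sub) - n_samples
    dup_ok = n_dup == 0 or (n_dup / max(n_samples, 1)) <= params.max_duplicate_frac
    if (span <= params.max_group_span and dup_ok) or node is None or node.is_leaf():
        out.append(sub)
        return
    left, right = node.get_left(), node.get_right()
    li = set(left.pre_order())
    left_idxs = [i for i in idxs if i in li]
    right_idxs = [i for i in idxs if i not in li]
    _cut_cluster(peaks, left_idxs, left, params, out)
    _cut_cluster(peaks, right_idxs, right, params, out)


def _cluster_segment(seg: pd.DataFrame, params: GroupingParams) -> list[pd.DataFrame]:
    if len(seg) == 1:
        return [seg]
    d = gower_distance(seg[list(params.variables)])
    z = hierarchy.linkage(squareform(d, checks=False), method=params.linkage)
    tree = hierarchy.to_tree(z)
    out: list[pd.DataFrame] = []
    _cut_cluster(seg, list(range(len(seg))), tree, params, out)
    return out


def group_peaks(peaks: pd.DataFrame, params: GroupingParams | None = None) -> GroupingResult:
    """Partition a peak table into FeatureGroups.

    Deterministic given params: peaks are pre-sorted by (peak_index,
    sample_id, peak_value) so input order is irrelevant.
    """
    params = params or GroupingParams()
    if len(peaks) == 0:
        raise ValueError("no peaks to group")
    peaks = (
        peaks.sort_values(["peak_index", "sample_id", "peak_value"], kind="stable")
        .reset_index(drop=True)
    )
    # divide step: segments separated by index gaps > max_group_span
    gaps = peaks["peak_index"].diff().fillna(0)
    seg_id = (gaps > params.max_group_span).cumsum()
    clusters: list[pd.DataFrame] = []
    for _, seg in peaks.groupby(seg_id):
        clusters.extend(_cluster_segment(seg, params))
    clusters.sort(key=lambda c: float(c["peak_index"].median()))
    groups, dropped = [], []
    empty_del = peaks.iloc[0:0]
    fid = 0
    for c in clusters:
        g = enforce_single_peak(
            FeatureGroup(fid, c.reset_index(drop=True), empty_del.copy())
        )
        if g.n_members < params.min_samples:
            dropped.append(pd.concat([g.members, g.deleted], ignore_index=True))
            continue
        g.feature_id = fid
        groups.append(g)
        fid += 1
    dropped_df = (
        pd.concat(dropped, ignore_index=True) if dropped else peaks.iloc[0:0].copy()
    )
    return GroupingResult(groups=groups, dropped=dropped_df)


# -- (de)serialisation helpers -------------------------------------------


def groups_to_frame(groups: list[FeatureGroup]) -> pd.DataFrame:
    """Flatten groups into one table: peak columns + feature_id + deleted flag."""
    parts = []
    for g in groups:
        parts.append(g.members.assign(feature_id=g.feature_id, deleted=False))
        if len(g.deleted):
            parts.append(g.deleted.assign(feature_id=g.feature_id, deleted=True))
    if not parts:
        return pd.DataFrame(columns=PEAK_COLUMNS + ["feature_id", "deleted"])
    return pd.concat(parts, ignore_index=True)[PEAK_COLUMNS + ["feature_id", "deleted"]]


def groups_from_frame(df: pd.DataFrame) -> list[FeatureGroup]:
    groups = []
    for fid, sub in df.groupby("feature_id", sort=True):
        members = sub.loc[~sub["deleted"].astype(bool), PEAK_COLUMNS].reset_index(drop=True)
        deleted = sub.loc[sub["deleted"].astype(bool), PEAK_COLUMNS].reset_index(drop=True)
        groups.append(FeatureGroup(int(fid), members, deleted))
    return groups


def groups_summary(groups: list[FeatureGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [g.feature_id for g in groups],
            "center_index": [g.center_index for g in groups],
            "center_ppm": [g.center_ppm for g in groups],
            "n_members": [g.n_members for g in groups],
            "n_deleted": [len(g.deleted) for g in groups],
        }
    )
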