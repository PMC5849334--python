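"""Silhouette-based quality control of the peak grouping.

When between-sample shifts exceed the gap between adjacent resonances the
grouper can split or interleave groups; low silhouette values flag this,
and flagged groups are pooled with their nearest neighbours and regrouped.
Distances are on ppm only, matching the grouping default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grouping import FeatureGroup, GroupingParams, group_peaks


class SilhouetteError(ValueError):
    pass


def silhouette_values(groups: list[FeatureGroup]) -> pd.DataFrame:
    """Per-peak silhouette s(i) = (b - a) / max(a, b) on |ppm| distances.

    a(i): mean distance to own-group peers (0 for singletons); b(i): smallest
    mean distance to another group, whose id is reported as ``neighbor``.
    Returns columns: feature_id, sample_id, peak_index, ppm, silhouette,
    neighbor.
    """
    if len(groups) < 2:
        raise SilhouetteError("silhouette needs at least 2 groups")
    labels = np.concatenate([[g.feature_id] * g.n_members for g in groups])
    ppm = np.concatenate([g.members["ppm"].to_numpy(float) for g in groups])
    rows = pd.concat(
        [g.members[["sample_id", "peak_index", "ppm"]] for g in groups],
        ignore_index=True,
    )
    dist = np.abs(ppm[:, None] - ppm[None, :])
    uniq = np.array([g.feature_id for g in groups])
    sizes = np.array([g.n_members for g in groups])
    # mean distance from every peak to every group
    group_mean = np.stack([dist[:, labels == u].mean(axis=1) for u in uniq], axis=1)
    own_col = np.array([np.where(uniq == l)[0][0] for l in labels])
    n_own = sizes[own_col]
    a = np.where(n_own > 1, group_mean[np.arange(len(labels)), own_col] * n_own / np.maximum(n_own - 1, 1), 0.0)
    other = group_mean.copy()
    other[np.arange(len(labels)), own_col] = np.inf
    b = other.min(axis=1)
    neighbor = uniq[other.argmin(axis=1)]
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / denom, 0.0)
    return rows.assign(feature_id=labels, silhouette=s, neighbor=neighbor)[
        ["feature_id", "sample_id", "peak_index", "ppm", "silhouette", "neighbor"]
    ]


def group_silhouettes(sil: pd.DataFrame) -> pd.Series:
    """Mean silhouette per group, indexed by feature_id."""
    return sil.groupby("feature_id")["silhouette"].mean()


def regroup_flagged(
    groups: list[FeatureGroup],
    threshold: float = 0.6,
    params: GroupingParams | None = None,
) -> list[FeatureGroup]:
    """Pool every group with mean silhouette < threshold together with the
    neighbour group(s) its members' b(i) point to, re-run the grouper on the
    pooled peaks (deleted peaks included as candidates), and renumber."""
    params = params or GroupingParams()
    sil = silhouette_values(groups)
    means = group_silhouettes(sil)
    flagged = set(means.index[means < threshold])
    if not flagged:
        return groups

    # union-find pooling of flagged groups with their neighbours
    parent = {g.feature_id: g.feature_id for g in groups}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for fid in flagged:
        for nb in sil.loc[sil["feature_id"] == fid, "neighbor"].unique():
            union(fid, nb)

    by_id = {g.feature_id: g for g in groups}
    pools: dict[int, list[int]] = {}
    for g in groups:
        pools.setdefault(find(g.feature_id), []).append(g.feature_id)

    out_groups: list[FeatureGroup] = []
    for root, fids in pools.items():
        if not any(f in flagged for f in fids):
            out_groups.extend(by_id[f] for f in fids)
            continue
        pooled = pd.concat(
            [by_id[f].members for f in fids] + [by_id[f].deleted for f in fids],
            ignore_index=True,
        )
        out_groups.extend(group_peaks(pooled, params).groups)
    out_groups.sort(key=lambda g: g.center_index)
    return [
        FeatureGroup(i, g.members, g.deleted) for i, g in enumerate(out_groups)
    ]
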