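"""Metabolite-identification support.

Peaks originating from one metabolite rise and fall together across
samples, so significant features are clustered on their Pearson
correlation (hierarchical, complete linkage on 1 - r); a cluster whose
minimum pairwise r is high (e.g. > 0.75) very likely belongs to a single
compound.  The ppm values of one cluster can then be submitted to the HMDB
1D 1H spectrum search; only the query URL is built here, no network call is
made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from urllib.parse import urlencode

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .features import FeatureMatrix

HMDB_NMR_SEARCH = "https://hmdb.ca/spectra/nmr_one_d/search"
DEFAULT_TOLERANCE = 0.02


@dataclass
class CorrelationClusters:
    assignments: pd.DataFrame  # feature_id, cluster, center_ppm
    min_correlation: dict[int, float]  # cluster -> min pairwise r (1.0 singleton)


def correlation_cluster(
    m: FeatureMatrix, feature_subset=None, k: int = 2
) -> CorrelationClusters:
    """Cluster feature columns on Pearson correlation into k groups.

    Zero-variance features are excluded with a warning.  Cluster labels are
    canonical (numbered by ascending minimum center_ppm), so they do not
    depend on feature input order.
    """
    meta = m.feature_meta.reset_index(drop=True)
    if feature_subset is not None:
        subset = list(feature_subset)
        sel = meta["feature_id"].isin(subset).to_numpy()
    else:
        sel = np.ones(len(meta), dtype=bool)
    cols = np.where(sel)[0]
    if m.values.shape[0] < 3:
        raise ValueError("correlation clustering needs at least 3 samples")
    var = np.std(m.values[:, cols], axis=0)
    if np.any(var == 0):
        warnings.warn(f"excluding {int((var == 0).sum())} zero-variance features")
        cols = cols[var > 0]
    if len(cols) == 0:
        raise ValueError("no usable features to cluster")
    if not 1 <= k <= len(cols):
        raise ValueError(f"k must be in [1, {len(cols)}]")
    # deterministic internal order
    order = np.argsort(meta.loc[cols, "feature_id"].to_numpy(), kind="stable")
    cols = cols[order]
    r = np.corrcoef(m.values[:, cols], rowvar=False)
    if r.ndim == 0:  # single feature
        labels = np.array([1])
    else:
        d = np.clip(1.0 - r, 0.0, None)
        np.fill_diagonal(d, 0.0)
        z = hierarchy.linkage(squareform(d, checks=False), method="complete")
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    out = pd.DataFrame(
        {
            "feature_id": meta.loc[cols, "feature_id"].to_numpy(),
            "cluster": labels,
            "center_ppm": meta.loc[cols, "center_ppm"].to_numpy(),
        }
    )
    # canonical numbering by ascending minimum ppm within cluster
    key = out.groupby("cluster")["center_ppm"].min().sort_values()
    remap = {old: new + 1 for new, old in enumerate(key.index)}
    out["cluster"] = out["cluster"].map(remap)
    out = out.sort_values(["cluster", "feature_id"]).reset_index(drop=True)
    min_r: dict[int, float] = {}
    for c, sub in out.groupby("cluster"):
        idx = [int(np.where(meta.loc[cols, "feature_id"].to_numpy() == f)[0][0]) for f in sub["feature_id"]]
        if len(idx) == 1:
            min_r[int(c)] = 1.0  # by convention
        else:
            block = np.asarray(r)[np.ix_(idx, idx)]
            min_r[int(c)] = float(block[np.triu_indices(len(idx), 1)].min())
    return CorrelationClusters(assignments=out, min_correlation=min_r)


def hmdb_query_url(ppm_list, tolerance: float = DEFAULT_TOLERANCE) -> str:
    """Deterministic HMDB 1H spectrum search URL for a list of ppm values.

    Values are sorted and printed with 4 decimals so permutations of the
    input produce byte-identical URLs.
    """
    ppm = sorted(float(v) for v in ppm_list)
    if not ppm:
        raise ValueError("empty ppm list")
    params = [
        ("type", "experimental"),
        ("peaks", " ".join(f"{v:.4f}" for v in ppm)),
        ("cs_tolerance", f"{tolerance:g}"),
    ]
    return f"{HMDB_NMR_SEARCH}?{urlencode(params)}"
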