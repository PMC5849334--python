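"""Targeted re-detection of peaks missed in the first pass (peak filling).

For every (feature, missing sample) cell the raw spectrum of that sample is
searched in a short window (512 or 1024 measurement points) centred on the
group centre, with wavelet scales narrowed around the group's mean scale and
*no* intensity or SNR threshold — only the distance rule filters: a candidate
is accepted iff it lies within ``max_dist`` (default 10) measurement points
of the group centre.  Peaks deleted during grouping are offered as ordinary
candidates so a peak removed from one group can be adopted by another.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cwt_peaks import PEAK_COLUMNS, cwt_transform, estimate_noise, find_ridges
from .grouping import FeatureGroup
from .spectra_io import SpectraSet

log = logging.getLogger(__name__)

REPORT_COLUMNS = ["feature_id", "sample_id", "filled_index", "distance", "accepted"]


@dataclass
class FillResult:
    groups: list[FeatureGroup]
    report: pd.DataFrame


def _fill_scales(mean_scale: float) -> tuple[int, ...]:
    lo = max(1, math.ceil(mean_scale / 2))
    hi = max(lo, int(round(2 * mean_scale)))
    return tuple(range(lo, hi + 1))


def _window_candidates(
    intensity: np.ndarray, center: int, window: int, scales: tuple[int, ...]
) -> list[dict]:
    p = intensity.size
    if window > p:
        log.warning("fill window %d longer than spectrum (%d points); truncating", window, p)
        window = p
    lo = max(0, min(center - window // 2, p - window))
    seg = intensity[lo : lo + window]
    scales = tuple(s for s in scales if 2 * s <= window) or (1,)
    coefs = cwt_transform(seg, scales)
    ridges = find_ridges(
        coefs, scales, ridge_gap_max=3, ridge_length_min=max(1, len(scales) // 4)
    )
    out = []
    for r in ridges:
        col = r.max_col
        noise = estimate_noise(coefs[0], col)
        out.append(
            {
                "peak_index": lo + col,
                "peak_value": float(r.max_value),
                "peak_height": float(seg[col]),
                "snr": float(r.max_value / noise) if noise > 0 else float("inf"),
                "scale": int(scales[r.max_scale_idx]),
            }
        )
    return out


def fill_peaks(
    groups: list[FeatureGroup],
    spectra: SpectraSet,
    window: int | None = None,
    max_dist: int = 10,
) -> FillResult:
    """Fill missing (feature, sample) cells; returns new groups + report.

    ``window`` is 512 or 1024 points; by default 512, switching to 1024 for
    groups whose mean scale exceeds 32 so wide peaks stay inside the window.
    Fills are computed against the *pre-fill* group centres, so the result
    does not depend on feature processing order.
    """
    if window is not None and window not in (512, 1024):
        raise ValueError("window must be 512 or 1024 measurement points")
    all_ids = list(spectra.sample_ids)
    row_of = {sid: i for i, sid in enumerate(all_ids)}
    # global pool of deleted peaks, candidates for re-adoption
    deleted_pool = (
        pd.concat([g.deleted for g in groups], ignore_index=True)
        if any(len(g.deleted) for g in groups)
        else None
    )
    report_rows = []
    additions: dict[int, list[dict]] = {}
    for g in groups:
        missing = [s for s in all_ids if s not in set(g.members["sample_id"])]
        if not missing:
            continue
        w = window or (1024 if g.mean_scale > 32 else 512)
        scales = _fill_scales(g.mean_scale)
        for sid in missing:
            cands = _window_candidates(
                spectra.intensities[row_of[sid]], g.center_index, w, scales
            )
            if deleted_pool is not None:
                for _, row in deleted_pool[deleted_pool["sample_id"] == sid].iterrows():
                    cands.append(
                        {
                            "peak_index": int(row["peak_index"]),
                            "peak_value": float(row["peak_value"]),
                            "peak_height": float(row["peak_height"]),
                            "snr": float(row["snr"]),
                            "scale": int(row["scale"]),
                        }
                    )
            if not cands:
                report_rows.append((g.feature_id, sid, -1, np.nan, False))
                continue
            best = min(cands, key=lambda c: abs(c["peak_index"] - g.center_index))
            dist = abs(best["peak_index"] - g.center_index)
            accepted = dist <= max_dist
            report_rows.append(
                (g.feature_id, sid, best["peak_index"], int(dist), accepted)
            )
            if accepted:
                additions.setdefault(g.feature_id, []).append(
                    {
                        "sample_id": sid,
                        "peak_index": best["peak_index"],
                        "ppm": float(spectra.ppm[best["peak_index"]]),
                        "peak_value": best["peak_value"],
                        "peak_height": best["peak_height"],
                        "snr": best["snr"],
                        "scale": best["scale"],
                        "filled": True,
                    }
                )
    new_groups = []
    for g in groups:
        add = additions.get(g.feature_id)
        if add:
            members = pd.concat(
                [g.members, pd.DataFrame(add)[PEAK_COLUMNS]], ignore_index=True
            ).sort_values("peak_index", kind="stable").reset_index(drop=True)
            new_groups.append(FeatureGroup(g.feature_id, members, g.deleted.copy()))
        else:
            new_groups.append(g)
    report = pd.DataFrame(report_rows, columns=REPORT_COLUMNS)
    return FillResult(groups=new_groups, report=report)
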