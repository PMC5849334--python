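"""Single-command pipeline: detect -> group -> silhouette regroup -> fill
-> featurize -> differential analysis -> correlation clustering.

Every stage writes its CSV into the output directory and the run ends with
a manifest (parameters, seed, stage row counts) so a run can be audited and
reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .cwt_peaks import CWTParams, detect_peaks
from .diff_analysis import differential_analysis
from .features import build_feature_matrix, impute, pqn_normalize, scale_features
from .filling import fill_peaks
from .grouping import GroupingParams, group_peaks, groups_summary, groups_to_frame
from .identification import correlation_cluster, hmdb_query_url
from .silhouette import regroup_flagged, silhouette_values
from .spectra_io import read_response, read_spectra

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "spectra": "spectra.csv",
    "response": None,  # file or null
    "detect": {
        "scales": None,  # null -> package default scale set
        "baseline_threshold": 1000.0,
        "snr_threshold": 3.0,
        "use_height": False,
    },
    "group": {"variables": ["ppm"], "linkage": "average", "max_group_span": 10, "min_samples": 1},
    "silhouette": {"threshold": 0.6, "regroup": True},
    "fill": {"window": None, "max_dist": 10},
    "featurize": {"impute": "zeros", "pqn": False, "scale": "pareto_sqrt", "center": True},
    "diff": {"adjust": "BH", "alpha": 0.05},
    "identify": {"k": None, "tolerance": 0.02},  # k null -> number of significant features capped at 5
    "seed": 1,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _merged(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | None, outdir) -> Path:
    """Run the whole workflow; returns the output directory."""
    cfg = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg, "stages": {}}

    def record(stage: str, n_rows: int) -> None:
        manifest["stages"][stage] = {"rows": int(n_rows)}
        log.info("stage %s: %d rows", stage, n_rows)

    def finish(status: str) -> Path:
        manifest["status"] = status
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return outdir

    try:
        spectra = read_spectra(cfg["spectra"])
        if cfg["response"]:
            spectra = spectra.with_response(read_response(cfg["response"]))
        record("read", spectra.n_samples)
    except Exception as exc:
        raise PipelineError("read", exc) from exc

    try:
        d = cfg["detect"]
        params = CWTParams(
            **({"scales": tuple(d["scales"])} if d["scales"] else {}),
            baseline_threshold=float(d["baseline_threshold"]),
            snr_threshold=float(d["snr_threshold"]),
            use_height=bool(d["use_height"]),
        )
        peaks = detect_peaks(spectra, params)
        peaks.to_csv(outdir / "peaks.csv", index=False)
        record("detect", len(peaks))
        if len(peaks) == 0:
            log.error("no peaks detected; nothing to featurize — stopping")
            return finish("no-peaks")
    except Exception as exc:
        raise PipelineError("detect", exc) from exc

    try:
        g = cfg["group"]
        gp = GroupingParams(
            variables=tuple(g["variables"]),
            linkage=g["linkage"],
            max_group_span=float(g["max_group_span"]),
            min_samples=int(g["min_samples"]),
        )
        groups = group_peaks(peaks, gp).groups
        record("group", len(groups))
    except Exception as exc:
        raise PipelineError("group", exc) from exc

    try:
        s = cfg["silhouette"]
        if len(groups) >= 2:
            sil = silhouette_values(groups)
            sil.to_csv(outdir / "silhouette.csv", index=False)
            if s["regroup"]:
                groups = regroup_flagged(groups, threshold=float(s["threshold"]), params=gp)
        record("silhouette", len(groups))
    except Exception as exc:
        raise PipelineError("silhouette", exc) from exc

    try:
        f = cfg["fill"]
        fill = fill_peaks(groups, spectra, window=f["window"], max_dist=int(f["max_dist"]))
        groups = fill.groups
        fill.report.to_csv(outdir / "fill_report.csv", index=False)
        groups_to_frame(groups).to_csv(outdir / "grouped_peaks.csv", index=False)
        groups_summary(groups).to_csv(outdir / "groups.csv", index=False)
        record("fill", len(fill.report))
    except Exception as exc:
        raise PipelineError("fill", exc) from exc

    try:
        ft = cfg["featurize"]
        fm = build_feature_matrix(groups, sample_ids=list(spectra.sample_ids))
        fm = impute(fm, ft["impute"])
        if ft["pqn"]:
            fm = pqn_normalize(fm)
        if ft["scale"]:
            fm = scale_features(fm, ft["scale"], center=bool(ft["center"]))
        fm.to_frame().to_csv(outdir / "features.csv")
        fm.feature_meta.to_csv(outdir / "feature_meta.csv", index=False)
        record("featurize", fm.values.shape[1])
    except Exception as exc:
        raise PipelineError("featurize", exc) from exc

    if spectra.response is None:
        log.info("no response vector; stopping after featurize")
        return finish("no-response")

    try:
        dd = cfg["diff"]
        res = differential_analysis(fm, spectra.response, adjust=dd["adjust"], alpha=float(dd["alpha"]))
        res.to_csv(outdir / "diff_results.csv", index=False)
        record("diff", len(res))
    except Exception as exc:
        raise PipelineError("diff", exc) from exc

    try:
        ident = cfg["identify"]
        sig = res.loc[res["significant"], "feature_id"].tolist()
        if len(sig) >= 2:
            k = ident["k"] or min(5, len(sig))
            clusters = correlation_cluster(fm, feature_subset=sig, k=int(k))
            clusters.assignments.to_csv(outdir / "clusters.csv", index=False)
            urls = [
                hmdb_query_url(sub["center_ppm"], tolerance=float(ident["tolerance"]))
                for _, sub in clusters.assignments.groupby("cluster")
            ]
            (outdir / "hmdb_queries.txt").write_text("\n".join(urls) + "\n")
            record("identify", len(clusters.assignments))
        else:
            record("identify", 0)
    except Exception as exc:
        raise PipelineError("identify", exc) from exc

    return finish("ok")
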