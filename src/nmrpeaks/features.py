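"""The samples x features matrix and its transformations.

Missing cells (features without a peak in a sample) are held as NaN behind
an explicit mask, never silently zero.  Every transformation is recorded in
an append-only provenance list; ``replay`` applies a provenance to a raw
matrix and reproduces the transformed one bit-for-bit.

Scaling notes: per feature j with values y_{i,j}, sample standard deviation
sigma_j (n-1 denominator), "unit" divides the centred column by sigma_j;
``pareto_sqrt`` (conventional Pareto) divides by sqrt(sigma_j), damping
large signals while keeping data structure roughly intact; ``pareto_printed``
divides by sigma_j without implying centring, kept because some workflows
define Pareto that way.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grouping import FeatureGroup

log = logging.getLogger(__name__)


class FeatureMatrixError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    values: np.ndarray  # N x K, NaN at masked cells
    missing_mask: np.ndarray  # N x K bool
    sample_ids: list[str]
    feature_meta: pd.DataFrame  # feature_id, center_index, center_ppm, mean_scale
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, k = self.values.shape
        if n < 1 or k < 1:
            raise FeatureMatrixError("feature matrix must be at least 1x1")
        if self.missing_mask.shape != (n, k):
            raise FeatureMatrixError("mask shape mismatch")
        if len(self.sample_ids) != n or len(self.feature_meta) != k:
            raise FeatureMatrixError("label lengths do not match matrix shape")

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            self.missing_mask.copy(),
            list(self.sample_ids),
            self.feature_meta.copy(),
            copy.deepcopy(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_meta["feature_id"].to_numpy(),
        )


def build_feature_matrix(
    groups: list[FeatureGroup], sample_ids: list[str] | None = None
) -> FeatureMatrix:
    """Cell (i, j) = peak value of sample i's member in feature j, NaN where
    the sample has no peak.  Columns ordered by group centre index."""
    groups = sorted(groups, key=lambda g: (g.center_index, g.feature_id))
    if sample_ids is None:
        sample_ids = sorted({s for g in groups for s in g.members["sample_id"]})
    row = {s: i for i, s in enumerate(sample_ids)}
    n, k = len(sample_ids), len(groups)
    values = np.full((n, k), np.nan)
    for j, g in enumerate(groups):
        if g.members["sample_id"].duplicated().any():
            raise FeatureMatrixError(
                f"feature {g.feature_id} holds duplicate samples"
            )
        for sid, val in zip(g.members["sample_id"], g.members["peak_value"]):
            values[row[sid], j] = val
    meta = pd.DataFrame(
        {
            "feature_id": [g.feature_id for g in groups],
            "center_index": [g.center_index for g in groups],
            "center_ppm": [g.center_ppm for g in groups],
            "mean_scale": [g.mean_scale for g in groups],
        }
    )
    return FeatureMatrix(values, np.isnan(values), list(sample_ids), meta)


def impute(m: FeatureMatrix, method: str = "zeros") -> FeatureMatrix:
    """Replace masked cells (default: with 0, meaning "no peak present")."""
    if method != "zeros":
        raise FeatureMatrixError(
            f"unknown imputation method {method!r}; only 'zeros' is supported"
        )
    out = m.copy()
    out.values[out.missing_mask] = 0.0
    out.missing_mask[:] = False
    out.provenance.append({"op": "impute", "method": method})
    return out


def pqn_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Probabilistic quotient normalisation.

    The reference is the feature-wise median row; each row is divided by
    the median of its quotients to the reference over features where the
    reference is positive.  The quotient step is iterated to a fixed point
    (every median quotient 1, to 1e-14) and the global scale is anchored so
    the mean row total is preserved — this per-row normalisation replaces
    an initial row-sum normalisation and makes the operation exactly
    idempotent.  For pure dilution the first quotient pass already lands on
    the fixed point.  The combined per-sample dilution factor is recorded
    in the provenance entry.
    """
    if m.n_missing:
        raise FeatureMatrixError("impute before PQN")
    if m.values.shape[0] < 2:
        raise FeatureMatrixError("PQN needs at least 2 samples")
    out = m.copy()
    sums = out.values.sum(axis=1)
    for i, s in enumerate(sums):
        if s == 0:
            raise FeatureMatrixError(f"all-zero row for sample {out.sample_ids[i]!r}")
    x = out.values.copy()
    factors = np.ones(x.shape[0])
    for _ in range(200):
        ref = np.median(x, axis=0)
        ok = ref > 0
        if not ok.any():
            raise FeatureMatrixError("reference row has no positive entries")
        med_q = np.median(x[:, ok] / ref[ok], axis=1)
        x = x / med_q[:, None]
        factors *= med_q
        if np.max(np.abs(med_q - 1.0)) < 1e-14:
            break
    scale = x.sum(axis=1).mean() / sums.mean()
    x /= scale
    factors *= scale
    out.values = x
    out.provenance.append({"op": "pqn", "factors": factors.tolist()})
    return out


def scale_features(
    m: FeatureMatrix, method: str = "pareto_sqrt", center: bool = True
) -> FeatureMatrix:
    """Column scaling: 'center', 'unit', 'pareto_sqrt' or 'pareto_printed'.

    'unit' always centres before dividing by sigma_j; the Pareto variants
    centre only when ``center`` is true.  Columns with sigma_j = 0 are left
    unscaled with a warning.  Column statistics are computed over observed
    cells only; masked cells stay masked (so impute-then-scale and
    scale-then-impute genuinely differ, the latter amounting to mean
    imputation for centred scalings).
    """
    if method not in {"center", "unit", "pareto_sqrt", "pareto_printed"}:
        raise FeatureMatrixError(f"unknown scaling method {method!r}")
    out = m.copy()
    x = out.values
    # column stats over observed cells; masked cells stay NaN behind the mask,
    # which is why impute-then-scale differs from scale-then-impute
    if method in ("center", "unit") or center:
        x = x - np.nanmean(x, axis=0, keepdims=True)
    if method != "center":
        with np.errstate(invalid="ignore"):
            sd = (
                np.nanstd(out.values, axis=0, ddof=1)
                if x.shape[0] > 1
                else np.zeros(x.shape[1])
            )
        sd = np.nan_to_num(sd, nan=0.0)
        zero = sd == 0
        if zero.any():
            log.warning("%d zero-variance columns left unscaled", int(zero.sum()))
        denom = np.ones_like(sd)
        if method == "unit" or method == "pareto_printed":
            denom[~zero] = sd[~zero]
        else:  # pareto_sqrt
            denom[~zero] = np.sqrt(sd[~zero])
        x = x / denom
    out.values = x
    out.provenance.append({"op": "scale", "method": method, "center": bool(center)})
    return out


def replay(raw: FeatureMatrix, provenance: list[dict]) -> FeatureMatrix:
    """Re-apply a recorded provenance to a raw matrix."""
    m = raw
    for step in provenance:
        op = step["op"]
        if op == "impute":
            m = impute(m, step["method"])
        elif op == "pqn":
            m = pqn_normalize(m)
        elif op == "scale":
            m = scale_features(m, step["method"], step["center"])
        else:
            raise FeatureMatrixError(f"unknown provenance op {op!r}")
    return m
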