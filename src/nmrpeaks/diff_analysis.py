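"""Per-feature linear-model differential analysis.

Each feature's peak values y_j are regressed on the response x (class codes
or a numeric covariate) by ordinary least squares with an intercept, and the
slope beta_j is tested against 0 with a two-tailed t-test (N - 2 df).  With
a binary 0/1 response this is exactly the pooled-variance two-sample
t-test.  Raw p-values are corrected for multiple testing, by
Benjamini-Hochberg (default) or Bonferroni.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

METHODS = {"BH", "bonferroni", "none"}


class DiffAnalysisError(ValueError):
    pass


def adjust_pvalues(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment, order-preserving.

    'bonferroni': min(1, K*p); 'BH': step-up with monotonicity enforcement;
    'none': unchanged.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DiffAnalysisError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    k = p.size
    if method == "bonferroni":
        return np.minimum(1.0, p * k)
    if method == "BH":
        order = np.argsort(p, kind="stable")
        adj = np.empty(k)
        running = 1.0
        for rank in range(k, 0, -1):
            i = order[rank - 1]
            # p * (k/rank), factor >= 1 exactly, so p_adj >= p holds in floats
            running = min(running, p[i] * (k / rank))
            adj[i] = running
        return adj
    raise DiffAnalysisError(f"unknown adjustment method {method!r}")


def differential_analysis(
    m: FeatureMatrix,
    response: np.ndarray,
    adjust: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS slope test of every feature against the response.

    Returns one row per feature: feature_id, center_ppm, beta, se, t, p,
    p_adj, significant (p_adj < alpha), in matrix column order.
    """
    if adjust not in METHODS:
        raise DiffAnalysisError(f"unknown adjustment method {adjust!r}")
    if m.n_missing:
        raise DiffAnalysisError("impute the feature matrix before testing")
    x = np.asarray(response, dtype=float)
    if x.size != m.values.shape[0]:
        raise DiffAnalysisError("response length does not match samples")
    if not np.all(np.isfinite(x)):
        raise DiffAnalysisError("response must be finite")
    if np.ptp(x) == 0:
        raise DiffAnalysisError("response is constant; no slope is estimable")
    if x.size < 3:
        raise DiffAnalysisError("need at least 3 samples (N - 2 residual df)")

    k = m.values.shape[1]
    beta = np.empty(k)
    se = np.empty(k)
    tval = np.empty(k)
    pval = np.empty(k)
    for j in range(k):
        res = stats.linregress(x, m.values[:, j])
        beta[j] = res.slope
        se[j] = res.stderr
        with np.errstate(divide="ignore", invalid="ignore"):
            tval[j] = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope or 1)
        pval[j] = res.pvalue if np.isfinite(res.pvalue) else 0.0
    # constant column -> slope 0, stderr 0: define t = 0, p = 1
    const = np.std(m.values, axis=0) == 0
    tval[const] = 0.0
    pval[const] = 1.0
    beta[const] = 0.0
    padj = adjust_pvalues(pval, "none" if adjust == "none" else adjust)
    return pd.DataFrame(
        {
            "feature_id": m.feature_meta["feature_id"].to_numpy(),
            "center_ppm": m.feature_meta["center_ppm"].to_numpy(),
            "beta": beta,
            "se": se,
            "t": tval,
            "p": pval,
            "p_adj": padj,
            "significant": padj < alpha,
        }
    )
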