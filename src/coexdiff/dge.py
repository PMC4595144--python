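"""Per-probe case-control differential expression by logistic regression.

Each probe is tested by a logistic regression of case status on that
probe's (standardized) expression plus adjustment covariates, with a Wald
z test on the expression coefficient. Multiple testing is controlled by
Benjamini-Hochberg FDR; a candidate-gene lookup applies Bonferroni over
the tested probes only. The two-stage procedure carries discovery hits
(FDR < alpha) into an independent replication set and re-applies BH within
the carried-forward set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "logistic_de",
    "bh_fdr",
    "two_stage_replication",
    "candidate_gene_lookup",
]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _fit_one(y: np.ndarray, design: np.ndarray) -> tuple[float, float, float, bool]:
    """Logistic fit via IRLS; returns (beta, se, p) for design column 1 and a
    convergence flag. Non-converged / separated fits report p = 1."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, design, family=sm.families.Binomial())
            res = model.fit(maxiter=50, tol=1e-8)
        beta, se = res.params[1], res.bse[1]
        if not np.isfinite(beta) or not np.isfinite(se) or se > 1e4 or not res.converged:
            return np.nan, np.nan, 1.0, False
        return beta, se, float(res.pvalues[1]), True
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return np.nan, np.nan, 1.0, False


def logistic_de(expr: pd.DataFrame, status, covariates: pd.DataFrame | None = None,
                ) -> pd.DataFrame:
    """Wald tests for case-control expression differences, probe by probe.

    Parameters
    ----------
    expr : probes x samples expression (residualized/normalized).
    status : binary case labels aligned to `expr` columns.
    covariates : optional samples x k numeric frame (e.g. surrogate
        variables) entered into every fit.

    Returns a frame indexed by probe with beta (per expression SD), se, p,
    p_fdr and a `converged` flag; separated or non-converged probes carry
    p = 1 and converged = False.
    """
    y = np.asarray(status, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in `status`")
    n = expr.shape[1]
    cov = None
    if covariates is not None:
        cov = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) \
            else np.asarray(covariates, float)
        if cov.shape[1] + 2 >= n:
            raise ValueError("too many covariates for the sample count")
    x = expr.to_numpy(float)
    rows = []
    for i in range(x.shape[0]):
        xi = x[i]
        sd = xi.std()
        xi = (xi - xi.mean()) / sd if sd > 0 else np.zeros(n)
        cols = [np.ones(n), xi]
        if cov is not None:
            cols.append(cov)
        design = np.column_stack(cols)
        if sd == 0:
            rows.append((np.nan, np.nan, 1.0, False))
        else:
            rows.append(_fit_one(y, design))
    out = pd.DataFrame(rows, index=expr.index, columns=["beta", "se", "p", "converged"])
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out[["beta", "se", "p", "p_fdr", "converged"]]


def two_stage_replication(discovery: pd.DataFrame, replication_expr: pd.DataFrame,
                          status, covariates: pd.DataFrame | None = None,
                          alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Replicate discovery hits in an independent set.

    Discovery probes with p_fdr < `alpha_fdr` are refit in the replication
    data; BH is re-applied within that selected subset and probes passing
    again are returned (empty frame if the discovery stage selected
    nothing).
    """
    if not 0 < alpha_fdr <= 1:
        raise ValueError("alpha_fdr must be in (0, 1]")
    if replication_expr.shape[1] == 0:
        raise ValueError("replication set is empty")
    selected = discovery.index[discovery["p_fdr"] < alpha_fdr]
    selected = [p for p in selected if p in replication_expr.index]
    if not selected:
        return discovery.iloc[0:0].copy()
    rep = logistic_de(replication_expr.loc[selected], status, covariates)
    rep["p_fdr"] = bh_fdr(rep["p"].to_numpy())
    return rep[rep["p_fdr"] < alpha_fdr]


def candidate_gene_lookup(de: pd.DataFrame, genes, probe_to_gene: pd.Series,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni lookup of a prior candidate-gene list.

    Restricts to probes mapping to the listed gene symbols and flags those
    with raw p below ``alpha / n_tested_probes``. Returns probe, gene, p,
    threshold and pass flag (empty frame with a warning when nothing maps).
    """
    if len(probe_to_gene) == 0:
        raise ValueError("probe_to_gene mapping is empty")
    genes = set(genes)
    hits = [p for p in de.index if probe_to_gene.get(p) in genes]
    if not hits:
        warnings.warn("no probe maps to any candidate gene", UserWarning)
        return pd.DataFrame(columns=["gene", "p", "threshold", "significant"])
    threshold = alpha / len(hits)
    sub = de.loc[hits]
    return pd.DataFrame({
        "gene": [probe_to_gene[p] for p in hits],
        "p": sub["p"].to_numpy(),
        "threshold": threshold,
        "significant": sub["p"].to_numpy() < threshold,
    }, index=pd.Index(hits, name="probe_id"))
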