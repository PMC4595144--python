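"""Surrogate-variable estimation and covariate residualization.

Unmodelled heterogeneity (batches, cell-composition drift, technical
background) is captured by surrogate variables: after protecting the
primary case/control contrast, the leading singular vectors of the
residual expression matrix span the dominant unmodelled structure.
Downstream stages consume expression residualized against either these
surrogate variables or a set of known risk-factor covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["SurrogateVariableAnalysis", "estimate_surrogate_variables", "residualize"]


def _ols_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each row of `y` (features x samples) on `design`
    (samples x p), via one pseudoinverse."""
    pinv = np.linalg.pinv(design)
    beta = y @ pinv.T  # features x p
    return y - beta @ design.T


class SurrogateVariableAnalysis(BaseEstimator, TransformerMixin):
    """Two-step surrogate variable analysis.

    Step 1 removes the protected primary variable from every probe by
    ordinary least squares; step 2 takes the leading left singular vectors
    of the sample-space residual matrix as surrogate variables. With
    ``n_sv="auto"``, the number of components is chosen by parallel
    analysis: a component is kept while its variance share exceeds the 95th
    percentile of the matching component's share over column-permuted
    residual matrices.

    Parameters
    ----------
    n_sv : int or "auto"
        Number of surrogate variables, or automatic parallel-analysis choice.
    n_permutations : int
        Permutations for parallel analysis (default 20).
    quantile : float
        Null quantile a component must exceed to be retained (default 0.95).
    random_state : int or None
        Seed for the permutation step.

    Attributes
    ----------
    surrogate_variables_ : ndarray, samples x n_sv_, orthonormal columns
    n_sv_ : int
    """

    def __init__(self, n_sv: int | str = "auto", n_permutations: int = 20,
                 quantile: float = 0.95, random_state: int | None = None):
        self.n_sv = n_sv
        self.n_permutations = n_permutations
        self.quantile = quantile
        self.random_state = random_state

    def fit(self, X, y=None):
        """Estimate surrogate variables from X (samples x probes).

        `y` is the protected primary variable (e.g. case status); it is
        regressed out per probe before the SVD so the surrogate variables
        cannot absorb the disease contrast.
        """
        X = np.asarray(X, float)
        n_samples, _ = X.shape
        if n_samples < 10:
            raise ValueError("need at least 10 samples for surrogate variable analysis")
        design = np.ones((n_samples, 1))
        if y is not None:
            design = np.column_stack([design, np.asarray(y, float)])
        resid = _ols_residuals(X.T, design).T  # samples x probes
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        var_share = s**2 / (s**2).sum()

        if self.n_sv == "auto":
            k = self._parallel_analysis(resid, var_share)
        else:
            k = int(self.n_sv)
            if k >= n_samples:
                raise ValueError(f"n_sv={k} must be < n_samples={n_samples}")
        self.n_sv_ = k
        self.surrogate_variables_ = u[:, :k]
        self.singular_values_ = s[:k]
        return self

    def _parallel_analysis(self, resid: np.ndarray, var_share: np.ndarray) -> int:
        rng = np.random.default_rng(self.random_state)
        n_comp = len(var_share)
        null_shares = np.empty((self.n_permutations, n_comp))
        for b in range(self.n_permutations):
            perm = resid.copy()
            for j in range(perm.shape[1]):
                rng.shuffle(perm[:, j])
            s_null = np.linalg.svd(perm, compute_uv=False)
            null_shares[b] = s_null**2 / (s_null**2).sum()
        cutoff = np.quantile(null_shares, self.quantile, axis=0)
        k = 0
        while k < n_comp and var_share[k] > cutoff[k]:
            k += 1
        return k

    def transform(self, X):
        """Residualize X (samples x probes) against the surrogate variables."""
        check_is_fitted(self, "surrogate_variables_")
        X = np.asarray(X, float)
        design = np.column_stack([np.ones(X.shape[0]), self.surrogate_variables_])
        return _ols_residuals(X.T, design).T


def estimate_surrogate_variables(expr: pd.DataFrame, primary_variable,
                                 n_sv: int | str = "auto",
                                 random_state: int | None = None) -> pd.DataFrame:
    """Surrogate variables for a probes x samples expression frame.

    Thin wrapper over :class:`SurrogateVariableAnalysis`; returns a
    samples x k frame with orthonormal columns SV1..SVk.
    """
    sva = SurrogateVariableAnalysis(n_sv=n_sv, random_state=random_state)
    sva.fit(expr.to_numpy(float).T, np.asarray(primary_variable, float))
    return pd.DataFrame(
        sva.surrogate_variables_, index=expr.columns,
        columns=[f"SV{i + 1}" for i in range(sva.n_sv_)],
    )


def residualize(expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-probe OLS residuals of expression against intercept + covariates.

    `expr` is probes x samples; `covariates` is samples x p (numeric; an
    intercept column is added internally). Raises if the augmented design is
    rank deficient, naming the collinear columns.
    """
    cov = covariates.loc[expr.columns] if not covariates.index.equals(expr.columns) \
        else covariates
    design = np.column_stack([np.ones(expr.shape[1]), cov.to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase rank when added
        collinear = []
        base = np.ones((expr.shape[1], 1))
        for name in cov.columns:
            cand = np.column_stack([base, cov[name].to_numpy(float)])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(base):
                collinear.append(name)
        raise ValueError(
            "rank-deficient design; collinear column(s): "
            + (", ".join(collinear) if collinear else "(linear combination of columns)")
        )
    resid = _ols_residuals(expr.to_numpy(float), design)
    return pd.DataFrame(resid, index=expr.index, columns=expr.columns)
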