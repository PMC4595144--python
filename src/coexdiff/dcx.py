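"""Differential co-expression: dispersion statistic, permutation inference
and module preservation.

Case and control co-expression are compared through signed soft-powered
Spearman correlations c_g = sign(rho_g) * |rho_g|^beta computed per group.
The pairwise change d_ij = sqrt(0.5 * |c_case,ij - c_control,ij|) lies in
[0, 1]; modules of differentially co-expressed genes are branches of an
average-linkage dendrogram of 1 - d cut at a fixed height. A module's
dispersion statistic

    D_s = sqrt( mean_{i<j in module} d_ij^2 )

is tested against a null distribution obtained by shuffling case/control
labels (module membership fixed), with Bonferroni correction over tested
modules. Preservation of a module in an independent replication set is
summarised by a Z-summary combining density and connectivity statistics
against a random-gene-set null; Z-summary > 10 is strong preservation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network import ModuleAssignment, UNASSIGNED, modules_from_dissimilarity

__all__ = [
    "signed_power_correlation",
    "dc_difference",
    "extract_dc_modules",
    "dispersion_statistic",
    "permutation_test",
    "bonferroni_from_permutation_index",
    "preservation_zsummary",
    "dc_heatmap_export",
]


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)


def _spearman(x: np.ndarray) -> np.ndarray:
    """Spearman correlation of rows; constant rows correlate 0."""
    ranks = _rank_rows(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def signed_power_correlation(x: np.ndarray, beta: float) -> np.ndarray:
    """sign(rho) * |rho|^beta on the row-wise Spearman correlation of x."""
    corr = _spearman(x)
    return np.sign(corr) * np.abs(corr) ** beta


def dc_difference(expr_cases: pd.DataFrame, expr_controls: pd.DataFrame,
                  beta: float = 6.0) -> pd.DataFrame:
    """Pairwise differential co-expression d_ij in [0, 1].

    d_ij = sqrt(0.5 * |c_case,ij - c_control,ij|) with c the signed
    soft-powered Spearman correlation within each group; diagonal 0.
    """
    if not expr_cases.index.equals(expr_controls.index):
        raise ValueError("case and control matrices must share the same gene set")
    if expr_cases.shape[1] < 3 or expr_controls.shape[1] < 3:
        raise ValueError("need at least 3 samples per group")
    c1 = signed_power_correlation(expr_cases.to_numpy(float), beta)
    c0 = signed_power_correlation(expr_controls.to_numpy(float), beta)
    d = np.sqrt(0.5 * np.abs(c1 - c0))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr_cases.index, columns=expr_cases.index)


def extract_dc_modules(d: pd.DataFrame, cut_height: float = 0.96,
                       min_module_size: int = 30,
                       palette_seed: int | None = None) -> ModuleAssignment:
    """Modules of differentially co-expressed genes.

    Clustering dissimilarity is 1 - d, so strongly changing gene pairs
    (large d) sit on low branches and merge below the cut height. Labels
    are colour names, randomly ordered when `palette_seed` is given
    (deterministic under the seed).
    """
    dissim = pd.DataFrame(1.0 - d.to_numpy(float), index=d.index, columns=d.columns)
    return modules_from_dissimilarity(dissim, cut_height, min_module_size,
                                      palette_seed=palette_seed)


def dispersion_statistic(d: pd.DataFrame, module_genes) -> float:
    """Root-mean-square pairwise differential co-expression within a module."""
    genes = list(module_genes)
    if len(genes) < 2:
        raise ValueError("dispersion statistic needs a module of >= 2 genes")
    sub = d.loc[genes, genes].to_numpy(float)
    iu = np.triu_indices(len(genes), k=1)
    return float(np.sqrt((sub[iu] ** 2).mean()))


def _module_ds(x_cases: np.ndarray, x_controls: np.ndarray, beta: float) -> float:
    """D_s of one module directly from its per-group expression blocks."""
    c1 = signed_power_correlation(x_cases, beta)
    c0 = signed_power_correlation(x_controls, beta)
    iu = np.triu_indices(c1.shape[0], k=1)
    return float(np.sqrt((0.5 * np.abs(c1 - c0))[iu].mean()))


def bonferroni_from_permutation_index(perm_index: int, n_perm: int,
                                      n_modules: int) -> float:
    """Convert a permutation index to a Bonferroni-corrected empirical p.

    p_emp = perm_index / n_perm; p_bonf = min(1, n_modules * p_emp).
    """
    if n_perm <= 0 or n_modules <= 0 or perm_index < 0:
        raise ValueError("perm_index >= 0, n_perm > 0 and n_modules > 0 required")
    return min(1.0, n_modules * perm_index / n_perm)


def permutation_test(expr_cases: pd.DataFrame, expr_controls: pd.DataFrame,
                     modules: ModuleAssignment, n_perm: int = 10000,
                     beta: float = 6.0, seed: int | None = None,
                     method: str = "sample") -> pd.DataFrame:
    """Label-permutation test of each module's dispersion statistic.

    Case/control labels are shuffled (group sizes preserved) and every
    module's D_s recomputed on its own expression block; module membership
    stays fixed at the observed clustering. `method="exhaustive"`
    enumerates all label splits instead of sampling (small groups only).

    Returns a frame (module, n_genes, d_s, perm_index, p_emp, p_bonf) with
    perm_index the number of null D_s values >= the observed one and
    p_bonf = min(1, m * p_emp) over the m tested modules.
    """
    if method not in ("sample", "exhaustive"):
        raise ValueError("method must be 'sample' or 'exhaustive'")
    if method == "sample" and n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable null")
    mods = modules.modules()
    n1, n0 = expr_cases.shape[1], expr_controls.shape[1]
    combined = {
        name: np.hstack([
            expr_cases.loc[genes].to_numpy(float),
            expr_controls.loc[genes].to_numpy(float),
        ])
        for name, genes in mods.items()
    }
    observed = {name: _module_ds(x[:, :n1], x[:, n1:], beta)
                for name, x in combined.items()}

    if method == "exhaustive":
        n_splits = comb(n1 + n0, n1)
        if n_splits > 200000:
            raise ValueError("too many label splits for exhaustive enumeration")
        splits = [np.array(c) for c in combinations(range(n1 + n0), n1)]
        n_perm = n_splits
    else:
        rng = np.random.default_rng(seed)
        splits = [rng.permutation(n1 + n0)[:n1] for _ in range(n_perm)]

    perm_index = {name: 0 for name in mods}
    all_idx = np.arange(n1 + n0)
    for case_idx in splits:
        mask = np.zeros(n1 + n0, bool)
        mask[case_idx] = True
        ctrl_idx = all_idx[~mask]
        for name, x in combined.items():
            ds = _module_ds(x[:, case_idx], x[:, ctrl_idx], beta)
            if ds >= observed[name]:
                perm_index[name] += 1

    m = len(mods)
    rows = []
    for name, genes in mods.items():
        p_emp = perm_index[name] / n_perm
        rows.append({
            "module": name, "n_genes": len(genes), "d_s": observed[name],
            "perm_index": perm_index[name], "p_emp": p_emp,
            "p_bonf": bonferroni_from_permutation_index(perm_index[name], n_perm, m),
        })
    return pd.DataFrame(rows).set_index("module")


def _within_stats(net_disc: np.ndarray, net_repl: np.ndarray,
                  idx: np.ndarray) -> tuple[float, float]:
    """(density in replication, discovery-vs-replication connectivity corr)
    for the gene subset `idx` of two gene x gene weight matrices."""
    m = len(idx)
    sub_r = net_repl[np.ix_(idx, idx)].copy()
    sub_d = net_disc[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub_r, 0.0)
    np.fill_diagonal(sub_d, 0.0)
    density = sub_r.sum() / (m * (m - 1))
    k_d, k_r = sub_d.sum(axis=1), sub_r.sum(axis=1)
    if k_d.std() == 0 or k_r.std() == 0:
        connectivity = 0.0
    else:
        connectivity = float(np.corrcoef(k_d, k_r)[0, 1])
    return float(density), connectivity


def preservation_zsummary(net_discovery: pd.DataFrame, net_replication: pd.DataFrame,
                          module_genes, n_perm: int = 200,
                          seed: int | None = None) -> dict:
    """Z-summary preservation of a module between two networks.

    `net_discovery` and `net_replication` are gene x gene weight matrices
    of the same kind over a common gene universe (e.g. differential
    co-expression matrices of the discovery and replication sets). The
    density statistic is the module's mean within-module weight in the
    replication network; the connectivity statistic is the correlation of
    the genes' intramodular connectivity between the two networks. Each is
    standardised against `n_perm` random same-size gene sets, and
    z_summary is their mean; z_summary > 10 flags strong preservation.
    """
    genes = list(module_genes)
    universe = list(net_replication.index)
    if len(genes) > len(universe) / 2:
        raise ValueError("module size exceeds half the gene universe; "
                         "the random-set null would be degenerate")
    pos = {g: i for i, g in enumerate(universe)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"module gene(s) absent from the networks: {missing[:5]}")
    nd = net_discovery.loc[universe, universe].to_numpy(float)
    nr = net_replication.to_numpy(float)
    idx = np.array([pos[g] for g in genes])
    obs_density, obs_connectivity = _within_stats(nd, nr, idx)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, 2))
    for b in range(n_perm):
        ridx = rng.choice(len(universe), len(genes), replace=False)
        null[b] = _within_stats(nd, nr, ridx)
    sd = null.std(axis=0, ddof=1)
    sd[sd == 0] = np.finfo(float).eps
    z_density = (obs_density - null[:, 0].mean()) / sd[0]
    z_connectivity = (obs_connectivity - null[:, 1].mean()) / sd[1]
    z_summary = (z_density + z_connectivity) / 2.0
    return {
        "z_density": float(z_density),
        "z_connectivity": float(z_connectivity),
        "z_summary": float(z_summary),
        "preserved": bool(z_summary > 10),
    }


def dc_heatmap_export(expr_cases: pd.DataFrame, expr_controls: pd.DataFrame,
                      modules: ModuleAssignment, outdir: str | Path,
                      prefix: str = "dc_module") -> list[Path]:
    """Per-module correlation heatmaps: cases above, controls below the
    diagonal, genes ordered by clustering of the case correlations.

    Writes one PNG and one numeric TSV sidecar per module; returns the PNG
    paths. Rendering is best effort (a headless backend is forced).
    """
    import matplotlib
    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, genes in modules.modules().items():
        c1 = _spearman(expr_cases.loc[genes].to_numpy(float))
        c0 = _spearman(expr_controls.loc[genes].to_numpy(float))
        d = 1.0 - np.abs(c1)
        np.fill_diagonal(d, 0.0)
        order = leaves_list(linkage(squareform((d + d.T) / 2, checks=False),
                                    method="average"))
        c1, c0 = c1[np.ix_(order, order)], c0[np.ix_(order, order)]
        combined = np.tril(c0, k=-1) + np.triu(c1)
        ordered_genes = [genes[i] for i in order]
        pd.DataFrame(combined, index=ordered_genes, columns=ordered_genes).to_csv(
            outdir / f"{prefix}_{name}.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4.5))
        im = ax.imshow(combined, cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title(f"module {name}: cases (upper) vs controls (lower)")
        fig.colorbar(im, ax=ax, label="Spearman correlation")
        path = outdir / f"{prefix}_{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
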