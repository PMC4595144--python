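"""Weighted co-expression networks and module extraction.

Adjacency between genes is the absolute (or signed) Spearman rank
correlation raised to a soft-threshold power; modules are branches of an
average-linkage dendrogram cut at a fixed height, labelled by descending
size from the conventional colour palette. The co-differential
co-expression (CDC) test asks whether a module's mean differential-
expression signal exceeds what random same-size gene sets achieve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ModuleAssignment",
    "spearman_correlation",
    "build_adjacency",
    "extract_modules",
    "modules_from_dissimilarity",
    "cdc_test",
    "MODULE_PALETTE",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"

#: conventional module colour order, assigned by descending module size
MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "black", "red", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


@dataclass
class ModuleAssignment:
    """Partition of genes into named modules (plus 'unassigned')."""

    labels: pd.Series  # gene -> module label
    cut_height: float
    min_module_size: int
    linkage_matrix: np.ndarray | None = field(default=None, repr=False)

    def modules(self) -> dict[str, list[str]]:
        """Mapping of module label -> member genes, excluding 'unassigned'."""
        out: dict[str, list[str]] = {}
        for gene, lab in self.labels.items():
            if lab != UNASSIGNED:
                out.setdefault(lab, []).append(gene)
        return out

    def n_modules(self) -> int:
        return len(self.modules())


def spearman_correlation(expr: pd.DataFrame) -> np.ndarray:
    """Gene x gene Spearman correlation for a genes x samples frame.

    Ties receive midranks; constant genes get correlation 0 to every other
    gene (with a warning) and 1 on the diagonal.
    """
    x = expr.to_numpy(float)
    ranks = stats.rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{constant.sum()} constant gene(s); correlations set to 0",
                      UserWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def build_adjacency(expr: pd.DataFrame, beta: float = 6.0,
                    signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded Spearman adjacency: |rho|^beta (unsigned default).

    The signed variant keeps the correlation's sign: sign(rho)*|rho|^beta.
    """
    if beta < 1:
        raise ValueError("soft-threshold power beta must be >= 1")
    corr = spearman_correlation(expr)
    a = np.abs(corr) ** beta
    if signed:
        a = np.sign(corr) * a
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def modules_from_dissimilarity(dissim: pd.DataFrame, cut_height: float,
                               min_module_size: int,
                               palette_seed: int | None = None,
                               ) -> ModuleAssignment:
    """Average-linkage clustering of a gene x gene dissimilarity, static cut.

    Clusters merging below `cut_height` become modules; those smaller than
    `min_module_size` are relabelled 'unassigned'. Labels come from the
    colour palette by descending module size, or in seeded random palette
    order when `palette_seed` is given.
    """
    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must be in (0, 1]")
    genes = list(dissim.index)
    d = dissim.to_numpy(float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    cluster_ids = fcluster(z, t=cut_height, criterion="distance")

    sizes = pd.Series(cluster_ids).value_counts()
    big = [cid for cid, sz in sizes.items() if sz >= min_module_size]
    big.sort(key=lambda cid: (-sizes[cid], cid))
    palette = list(MODULE_PALETTE)
    palette += [f"module{i}" for i in range(len(palette) + 1, len(big) + 1)]
    if palette_seed is not None:
        rng = np.random.default_rng(palette_seed)
        names = list(rng.permutation(palette[:max(len(big), 1)]))[:len(big)]
    else:
        names = palette[:len(big)]
    name_of = {cid: names[i] for i, cid in enumerate(big)}
    labels = pd.Series(
        [name_of.get(cid, UNASSIGNED) for cid in cluster_ids],
        index=pd.Index(genes, name="gene"), name="module",
    )
    return ModuleAssignment(labels, cut_height, min_module_size, z)


def extract_modules(adjacency: pd.DataFrame, cut_height: float = 0.96,
                    min_module_size: int = 30) -> ModuleAssignment:
    """Modules from a co-expression adjacency via dissimilarity 1 - a."""
    a = adjacency.to_numpy(float)
    dissim = pd.DataFrame(1.0 - np.abs(a), index=adjacency.index,
                          columns=adjacency.columns)
    return modules_from_dissimilarity(dissim, cut_height, min_module_size)


def cdc_test(modules: ModuleAssignment, de_p: pd.Series, n_perm: int = 10000,
             seed: int | None = None) -> pd.DataFrame:
    """Co-differential co-expression test.

    Gene significance is -log10 of the differential-expression p-value; for
    each module the observed mean gene significance is compared to `n_perm`
    random same-size gene sets drawn from all module-assigned genes, giving
    an empirical p of (r + 1) / (n_perm + 1) with r the count of null means
    at or above the observed mean.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    mods = modules.modules()
    assigned = [g for gs in mods.values() for g in gs]
    missing = [g for g in assigned if g not in de_p.index]
    if missing:
        raise ValueError(f"no DE p-value for module gene(s): {missing[:5]} ...")
    gs_all = -np.log10(np.clip(de_p.loc[assigned].to_numpy(float), 1e-300, 1.0))
    rng = np.random.default_rng(seed)
    rows = []
    for name, genes in mods.items():
        m = len(genes)
        if m > len(assigned):
            raise ValueError("module larger than the assigned-gene universe")
        obs = -np.log10(np.clip(de_p.loc[genes].to_numpy(float), 1e-300, 1.0)).mean()
        null_means = np.empty(n_perm)
        for b in range(n_perm):
            null_means[b] = gs_all[rng.choice(len(gs_all), m, replace=False)].mean()
        r = int((null_means >= obs).sum())
        rows.append({"module": name, "n_genes": m, "mean_gene_significance": obs,
                     "p_perm": (r + 1) / (n_perm + 1)})
    return pd.DataFrame(rows).set_index("module")
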