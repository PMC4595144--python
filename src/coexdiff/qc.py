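"""Sample and probe quality control, normalization and set splitting.

The sample-level pipeline runs in a fixed order: lab quality (RIN, 260/280
purity) -> principal-component outliers -> reported-vs-expression sex
concordance -> expression duplicates. Probe filters (non-specific,
non-autosomal, retired) follow, then quantile normalization and log2.
Every exclusion carries a reason code so the report accounts for each
input sample and probe exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Exclusion",
    "QcReport",
    "filter_lab_quality",
    "detect_pc_outliers",
    "check_sex_concordance",
    "detect_duplicates",
    "filter_probes",
    "quantile_normalize_log2",
    "QuantileNormalizer",
    "split_discovery_replication",
    "compare_leukocyte_counts",
    "run_qc",
]

SAMPLE_REASONS = ("low_rin", "low_purity", "pc_outlier", "sex_mismatch", "duplicate")
PROBE_REASONS = ("nonspecific", "non_autosomal", "retired")
_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}
_SEX_MT = {"X", "Y", "MT", "chrX", "chrY", "chrM", "chrMT"}


@dataclass(frozen=True)
class Exclusion:
    id: str
    reason: str


@dataclass
class QcReport:
    """Bookkeeping of everything excluded and everything retained."""

    excluded_samples: list[Exclusion] = field(default_factory=list)
    excluded_probes: list[Exclusion] = field(default_factory=list)
    n_samples_retained: int = 0
    n_probes_retained: int = 0

    def to_dict(self) -> dict:
        return {
            "excluded_samples": [asdict(e) for e in self.excluded_samples],
            "excluded_probes": [asdict(e) for e in self.excluded_probes],
            "n_samples_retained": self.n_samples_retained,
            "n_probes_retained": self.n_probes_retained,
        }


def _check_matrix(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise ValueError("expression matrix has duplicate probe or sample ids")
    if not np.isfinite(expr.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")


def filter_lab_quality(metadata: pd.DataFrame, rin_min: float = 6.0,
                       purity_min: float = 1.8) -> list[Exclusion]:
    """Exclude samples with RIN below `rin_min` or 260/280 below `purity_min`.

    Thresholds are strict 'below': a sample exactly at the threshold is kept.
    """
    if rin_min <= 0 or purity_min <= 0:
        raise ValueError("quality thresholds must be positive")
    for col in ("rin", "ratio_260_280"):
        bad = metadata.index[metadata[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col} for sample(s): {list(bad)}")
    out = []
    for sid, row in metadata.iterrows():
        if row["rin"] < rin_min:
            out.append(Exclusion(sid, "low_rin"))
        elif row["ratio_260_280"] < purity_min:
            out.append(Exclusion(sid, "low_purity"))
    return out


def detect_pc_outliers(expr: pd.DataFrame, k_mad: float = 5.0) -> list[Exclusion]:
    """Flag samples whose PC1/PC2 score is a robust outlier.

    Principal components of the sample x probe matrix (probes centered) are
    taken from the SVD; a sample is flagged when its score on PC1 or PC2 is
    more than `k_mad` robust standard deviations (1.4826 * MAD) from the
    median. This is a deterministic surrogate for visual inspection of
    principal-component plots.
    """
    _check_matrix(expr)
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for PC outlier detection")
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    x = expr.to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)  # center per probe
    if not np.any(x):
        raise ValueError("constant expression matrix: no variance to decompose")
    # scores: samples x components
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    scores = u[:, :2] * s[:2]
    flagged: set[str] = set()
    for j in range(min(2, scores.shape[1])):
        col = scores[:, j]
        med = np.median(col)
        mad = stats.median_abs_deviation(col, scale="normal")
        if mad == 0:
            continue
        flagged.update(expr.columns[np.abs(col - med) > k_mad * mad])
    return [Exclusion(sid, "pc_outlier") for sid in expr.columns if sid in flagged]


def _two_means_split(values: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Deterministic 1-D 2-means; returns boolean 'upper cluster' mask."""
    lo, hi = values.min(), values.max()
    if lo == hi:
        return np.zeros(len(values), bool)
    c0, c1 = lo, hi
    for _ in range(n_iter):
        upper = np.abs(values - c1) < np.abs(values - c0)
        if upper.all() or (~upper).all():
            break
        n0, n1 = values[~upper].mean(), values[upper].mean()
        if (n0, n1) == (c0, c1):
            break
        c0, c1 = n0, n1
    threshold = (c0 + c1) / 2.0
    return values > threshold


def check_sex_concordance(expr: pd.DataFrame, annotation: pd.DataFrame,
                          metadata: pd.DataFrame,
                          min_discordant: int = 2) -> list[Exclusion]:
    """Exclude samples whose expression-predicted sex contradicts the record.

    Each sex-check probe's intensities are split into two clusters (1-D
    two-means, threshold at the midpoint of the cluster means); the cluster
    labels are oriented by majority agreement with reported sex. A sample is
    excluded when at least `min_discordant` probes predict the opposite of
    its reported sex.
    """
    sex_probes = annotation.index[annotation["is_sex_check_probe"]]
    sex_probes = [p for p in sex_probes if p in expr.index]
    if len(sex_probes) < min_discordant:
        raise ValueError(
            f"need at least {min_discordant} sex-check probes, found {len(sex_probes)}"
        )
    reported_f = (metadata.loc[expr.columns, "reported_sex"] == "F").to_numpy()
    discordant = np.zeros(expr.shape[1], int)
    for probe in sex_probes:
        upper = _two_means_split(expr.loc[probe].to_numpy(float))
        # orient: does the upper cluster align with reported F or M?
        agree_f = (upper == reported_f).mean()
        predicted_f = upper if agree_f >= 0.5 else ~upper
        discordant += predicted_f != reported_f
    return [
        Exclusion(sid, "sex_mismatch")
        for sid, d in zip(expr.columns, discordant)
        if d >= min_discordant
    ]


def detect_duplicates(expr: pd.DataFrame, r_min: float = 0.99) -> list[Exclusion]:
    """Exclude later members of sample pairs with Pearson r > `r_min`.

    Transitive groups of near-copies keep exactly one representative: the
    earliest column.
    """
    _check_matrix(expr)
    if not 0.0 < r_min < 1.0:
        raise ValueError("r_min must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(expr.to_numpy(float).T)
    n = expr.shape[1]
    excluded: list[Exclusion] = []
    dropped = np.zeros(n, bool)
    for j in range(n):
        if dropped[j]:
            continue
        for i in range(j):
            if not dropped[i] and corr[i, j] > r_min:
                dropped[j] = True
                excluded.append(Exclusion(expr.columns[j], "duplicate"))
                break
    return excluded


def filter_probes(annotation: pd.DataFrame) -> list[Exclusion]:
    """Exclude non-specific, non-autosomal (X/Y/MT) and retired probes.

    When several rules hit the same probe the recorded reason follows the
    priority nonspecific > non_autosomal > retired.
    """
    known = _AUTOSOMES | _SEX_MT
    unknown = set(annotation["chromosome"].astype(str)) - known
    if unknown:
        raise ValueError(f"unknown chromosome label(s): {sorted(unknown)}")
    out = []
    for pid, row in annotation.iterrows():
        if not row["is_specific"]:
            out.append(Exclusion(pid, "nonspecific"))
        elif str(row["chromosome"]) in _SEX_MT:
            out.append(Exclusion(pid, "non_autosomal"))
        elif row["is_retired"]:
            out.append(Exclusion(pid, "retired"))
    return out


def _rank_mean_normalize(x: np.ndarray) -> np.ndarray:
    """Map every column onto the per-rank mean of the sorted columns.

    Ties within a column receive the average of the rank means they span.
    """
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    rank_means = sorted_x.mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        # average rank means over tied values
        ranks = stats.rankdata(col, method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (rank_means[lo] + rank_means[hi]) / 2.0
    return out


def quantile_normalize_log2(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalize raw intensities across samples, then log2.

    After normalization every column holds the same multiset of values (the
    per-rank means); ids are preserved. Raw intensities must be strictly
    positive.
    """
    _check_matrix(expr)
    x = expr.to_numpy(float)
    normalized = _rank_mean_normalize(x)
    if (normalized <= 0).any():
        raise ValueError("non-positive intensity encountered before log2")
    return pd.DataFrame(np.log2(normalized), index=expr.index, columns=expr.columns)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style quantile normalization to a reference distribution.

    `fit` learns the per-rank mean distribution from a samples x probes
    matrix; `transform` maps each new row onto that distribution (by rank)
    and applies log2. `fit_transform` on the training matrix reproduces
    :func:`quantile_normalize_log2` (up to orientation).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        out = np.empty_like(X, dtype=float)
        for i in range(X.shape[0]):
            ranks = stats.rankdata(X[i], method="average") - 1.0
            lo = np.floor(ranks).astype(int)
            hi = np.ceil(ranks).astype(int)
            out[i] = (self.reference_[lo] + self.reference_[hi]) / 2.0
        if (out <= 0).any():
            raise ValueError("non-positive intensity encountered before log2")
        return np.log2(out)


def split_discovery_replication(metadata: pd.DataFrame, seed: int) -> pd.Series:
    """Randomly assign 2/3 discovery / 1/3 replication within case and control.

    The replication count per stratum is floor(n/3); the remainder goes to
    discovery. Returns a Series of {'discovery', 'replication'} labels.
    """
    labels = pd.Series("discovery", index=metadata.index, name="set_label")
    rng = np.random.default_rng(seed)
    for _, idx in metadata.groupby("is_case").groups.items():
        idx = list(idx)
        if len(idx) < 3:
            raise ValueError("each stratum needs at least 3 samples to split")
        n_rep = len(idx) // 3
        rep = rng.choice(len(idx), n_rep, replace=False)
        labels.loc[[idx[i] for i in rep]] = "replication"
    return labels


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum: tie-corrected normal approximation with
    continuity correction. Returns (W, two-sided p) with W the rank sum of
    the first group."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts ** 3 - counts).sum()) / ((n) * (n - 1))
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:
        return w, 1.0
    diff = w - mean_w
    # continuity correction shrinks |diff| by 0.5
    cc = np.sign(diff) * 0.5 if diff != 0 else 0.0
    z = (diff - cc) / np.sqrt(var_w)
    p = 2.0 * stats.norm.sf(abs(z))
    return w, min(p, 1.0)


def compare_leukocyte_counts(metadata: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon rank-sum test of each leukocyte differential, cases vs controls."""
    count_cols = [c for c in metadata.columns if c.startswith("count_")]
    if not count_cols:
        raise ValueError("no leukocyte count columns (count_*) in metadata")
    cases = metadata[metadata["is_case"]]
    controls = metadata[~metadata["is_case"]]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("each group needs at least 2 observations")
    rows = []
    for col in count_cols:
        w, p = _wilcoxon_rank_sum(cases[col].to_numpy(float),
                                  controls[col].to_numpy(float))
        rows.append({"cell_type": col.removeprefix("count_"), "rank_sum": w, "p": p})
    return pd.DataFrame(rows).set_index("cell_type")


def run_qc(expr_raw: pd.DataFrame, metadata: pd.DataFrame,
           annotation: pd.DataFrame, *, rin_min: float = 6.0,
           purity_min: float = 1.8, k_mad: float = 5.0,
           min_discordant: int = 2, r_dup: float = 0.99,
           ) -> tuple[pd.DataFrame, pd.DataFrame, QcReport]:
    """Full QC pipeline: sample filters in fixed order, probe filters, then
    quantile normalization + log2 on the retained submatrix.

    Sample-level statistics (PC outliers, sex check, duplicates) run on the
    log2 of the raw intensities, which stabilises variance without changing
    rank structure. Returns (normalized log2 expression, retained metadata,
    report).
    """
    _check_matrix(expr_raw)
    if (expr_raw.to_numpy() <= 0).any():
        raise ValueError("raw intensities must be strictly positive")
    report = QcReport()
    log2_expr = pd.DataFrame(np.log2(expr_raw.to_numpy(float)),
                             index=expr_raw.index, columns=expr_raw.columns)

    def drop(excl: list[Exclusion], current: pd.DataFrame) -> pd.DataFrame:
        already = {e.id for e in report.excluded_samples}
        fresh = [e for e in excl if e.id not in already]
        report.excluded_samples.extend(fresh)
        keep = [c for c in current.columns if c not in {e.id for e in fresh}]
        return current[keep]

    cur = log2_expr
    cur = drop(filter_lab_quality(metadata, rin_min, purity_min), cur)
    # PC outliers are scored on autosomal probes only: with few probes the
    # sex-chromosome shift would otherwise dominate a component and flag one
    # sex wholesale
    autosomal = annotation.index[
        annotation["chromosome"].astype(str).isin(_AUTOSOMES)]
    pc_input = cur.loc[cur.index.intersection(autosomal)]
    cur = drop(detect_pc_outliers(pc_input if len(pc_input) >= 3 else cur, k_mad), cur)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cur = drop(check_sex_concordance(cur, annotation, metadata, min_discordant), cur)
    cur = drop(detect_duplicates(cur, r_dup), cur)

    probe_excl = filter_probes(annotation.loc[cur.index])
    report.excluded_probes = probe_excl
    bad_probes = {e.id for e in probe_excl}
    keep_probes = [p for p in cur.index if p not in bad_probes]

    retained_raw = expr_raw.loc[keep_probes, cur.columns]
    normalized = quantile_normalize_log2(retained_raw)
    report.n_samples_retained = normalized.shape[1]
    report.n_probes_retained = normalized.shape[0]
    meta_kept = metadata.loc[normalized.columns]
    return normalized, meta_kept, report
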