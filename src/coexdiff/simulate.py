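"""Synthetic case-control expression data with planted, known structure.

Emulates an Illumina HumanHT-12-style whole-blood experiment: a probe x
sample intensity matrix (raw scale; log2 underneath), a sample metadata
table with phenotype and lab-QC fields, and a probe annotation table.
Ground truth for every planted feature (co-expression modules,
differentially (co-)expressed genes, duplicates, outliers, low-quality
samples) is returned alongside, so downstream stages can be scored against
what was actually planted.

Module structure uses a single-factor Gaussian model: for a module with
target within-group correlation r, each member probe is
``sqrt(r) * f + sqrt(1 - r) * eps`` with a shared per-sample factor f, so
the expected pairwise correlation equals r exactly. Loss of co-expression
in one group is planted by zeroing the loading in that group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlantedModule",
    "SimulationConfig",
    "SyntheticDataset",
    "generate_dataset",
]

#: leukocyte differential reference means (1e9 cells/L) and coefficient of
#: variation used for both groups (no planted group difference).
_LEUKOCYTE_MEANS = {
    "neutrophils": 4.0,
    "lymphocytes": 2.0,
    "monocytes": 0.5,
    "eosinophils": 0.15,
    "basophils": 0.05,
}

# Table-1-like covariate frequencies (cases, controls)
_COVARIATE_FREQS = {
    "female": (0.83, 0.40),
    "hypertension": (0.61, 0.28),
    "smoking_ever": (0.83, 0.78),
    "familial_ia": (0.04, 0.0),
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expression module with per-group target correlation."""

    size: int
    r_case: float
    r_control: float
    preserved_in_replication: bool = True

    def validate(self) -> None:
        if self.size < 3:
            raise ConfigurationError(f"PlantedModule.size must be >= 3, got {self.size}")
        for name, r in (("r_case", self.r_case), ("r_control", self.r_control)):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(
                    f"PlantedModule.{name} must be in [0, 1] for a single-factor "
                    f"module model, got {r}"
                )


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the emulated study: 119 cases and 118 controls recruited,
    34 135 autosomal probes surviving filtering, log2 intensities around a
    baseline of 7 with unit-variance biological/technical noise.
    """

    n_cases: int = 119
    n_controls: int = 118
    n_probes: int = 34135
    planted_modules: list[PlantedModule] = field(default_factory=list)
    n_de_genes: int = 0
    de_effect: float = 0.5
    n_batches: int = 1
    batch_sd: float = 0.0
    noise_sd: float = 1.0
    n_sex_probes: int = 8
    sex_effect: float = 6.0
    n_duplicates: int = 0
    n_outliers: int = 0
    n_low_rin: int = 0
    n_background_factors: int = 5
    background_r: float = 0.1
    baseline: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_cases", "n_controls", "n_probes", "n_de_genes", "n_batches",
            "n_sex_probes", "n_duplicates", "n_outliers", "n_low_rin",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_batches < 1:
            raise ConfigurationError(f"n_batches must be >= 1, got {self.n_batches}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.background_r < 1.0:
            raise ConfigurationError(
                f"background_r must be in [0, 1), got {self.background_r}")
        for m in self.planted_modules:
            m.validate()
        total = sum(m.size for m in self.planted_modules)
        if total + self.n_de_genes + self.n_sex_probes > self.n_probes:
            raise ConfigurationError(
                "n_probes too small: planted module sizes + n_de_genes + "
                f"n_sex_probes = {total + self.n_de_genes + self.n_sex_probes} "
                f"> n_probes = {self.n_probes}"
            )
        if self.n_outliers + self.n_low_rin > self.n_cases + self.n_controls:
            raise ConfigurationError("n_outliers + n_low_rin exceeds sample count")


@dataclass
class SyntheticDataset:
    """One generated dataset plus the ground truth of everything planted."""

    expression: pd.DataFrame  # probes x samples, raw intensity scale
    metadata: pd.DataFrame  # one row per sample
    annotation: pd.DataFrame  # one row per probe
    truth: dict  # probe id -> {"module": str | None, "is_de": bool}
    truth_samples: dict  # sample id -> QC flags

    def write(self, outdir: str | Path) -> None:
        """Write the three input tables (TSV) plus a JSON truth file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
        self.annotation.to_csv(outdir / "annotation.tsv", sep="\t")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"probes": self.truth, "samples": self.truth_samples}, fh, indent=1)


def _sample_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cases + cfg.n_controls
    is_case = np.r_[np.ones(cfg.n_cases, bool), np.zeros(cfg.n_controls, bool)]
    rows = {}
    rows["is_case"] = is_case
    rows["age"] = np.round(rng.normal(60, 10, n).clip(20, 90), 1)
    freq_f = np.where(is_case, *_COVARIATE_FREQS["female"])
    female = rng.random(n) < freq_f
    rows["reported_sex"] = np.where(female, "F", "M")
    for key in ("hypertension", "smoking_ever", "familial_ia"):
        p_case, p_ctrl = _COVARIATE_FREQS[key]
        rows[key] = rng.random(n) < np.where(is_case, p_case, p_ctrl)
    rows["rin"] = np.round(rng.uniform(7.0, 10.0, n), 1)
    rows["ratio_260_280"] = np.round(rng.normal(2.0, 0.05, n), 2)
    for cell, mean in _LEUKOCYTE_MEANS.items():
        rows[f"count_{cell}"] = np.round(rng.gamma(16.0, mean / 16.0, n), 3)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a synthetic dataset with the structure `config` plants.

    The expression matrix is returned on the raw intensity scale
    (2 ** log2-value) so the QC stage's quantile-normalise-then-log2 step
    applies as it would to scanner output. All planted effects (module
    factors, differential expression, sex shifts, batch offsets) are additive
    on the log2 scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    p = config.n_probes

    meta = _sample_metadata(config, rng)
    is_case = meta["is_case"].to_numpy()
    female = (meta["reported_sex"] == "F").to_numpy()

    probe_ids = [f"P{i + 1:06d}" for i in range(p)]
    # base: per-probe baseline + iid noise, log2 scale
    probe_means = config.baseline + rng.normal(0.0, 0.5, p)
    x = rng.normal(0.0, 1.0, (p, n))

    # planted co-expression modules occupy the leading probe rows
    truth = {pid: {"module": None, "is_de": False} for pid in probe_ids}
    # replication stratum: final third of each group's columns (used when a
    # module is planted as not preserved there)
    repl_mask = np.zeros(n, bool)
    for grp_mask in (is_case, ~is_case):
        idx = np.flatnonzero(grp_mask)
        n_rep = len(idx) - (2 * len(idx) + 2) // 3  # ~1/3, at least matches floor
        if n_rep > 0:
            repl_mask[idx[-n_rep:]] = True

    row = 0
    for mi, mod in enumerate(config.planted_modules):
        f = rng.normal(0.0, 1.0, n)  # shared factor, one value per sample
        load = np.where(is_case, np.sqrt(mod.r_case), np.sqrt(mod.r_control))
        resid = np.where(is_case, np.sqrt(1 - mod.r_case), np.sqrt(1 - mod.r_control))
        if not mod.preserved_in_replication:
            load = np.where(repl_mask, 0.0, load)
            resid = np.where(repl_mask, 1.0, resid)
        sl = slice(row, row + mod.size)
        x[sl] = load * f + resid * x[sl]
        for pid in probe_ids[sl]:
            truth[pid]["module"] = f"M{mi + 1}"
        row += mod.size

    # differentially expressed probes: next block, group-mean shift in cases
    de_rows = slice(row, row + config.n_de_genes)
    x[de_rows, is_case] += config.de_effect / config.noise_sd
    for pid in probe_ids[de_rows]:
        truth[pid]["is_de"] = True
    row += config.n_de_genes

    # background structure: sample-continuous latent factors (cell
    # composition, global technical drift) shared by both groups, carried by
    # the non-planted probes at per-probe variance fraction background_r.
    # This is what makes the leading principal components of real blood
    # arrays continuous rather than degenerate.
    if config.n_background_factors > 0 and config.background_r > 0:
        bg = rng.normal(0.0, 1.0, (config.n_background_factors, n))
        free = np.ones(p, bool)
        free[: row] = False  # planted module + DE probes keep exact variance
        if config.n_sex_probes:
            free[p - config.n_sex_probes:] = False
        f_idx = rng.integers(0, config.n_background_factors, p)
        sign = rng.choice([-1.0, 1.0], p)
        h = config.background_r
        x[free] = (np.sqrt(h) * sign[free, None] * bg[f_idx[free]]
                   + np.sqrt(1 - h) * x[free])

    # scale noise and add baselines
    x = x * config.noise_sd + probe_means[:, None]

    # sex-linked probes: final block, shifted in males
    sex_rows = slice(p - config.n_sex_probes, p) if config.n_sex_probes else slice(0, 0)
    x[sex_rows, :] += np.where(female, 0.0, config.sex_effect)

    # batch structure: per-probe, per-batch offsets
    batch = rng.integers(0, config.n_batches, n)
    if config.n_batches > 1 and config.batch_sd > 0:
        offsets = rng.normal(0.0, config.batch_sd, (p, config.n_batches))
        x += offsets[:, batch]
    meta["batch"] = batch

    sample_ids = list(meta.index)
    truth_samples = {
        sid: {"is_duplicate": False, "is_outlier": False, "is_low_quality": False,
              "is_replication_designate": bool(repl_mask[i])}
        for i, sid in enumerate(sample_ids)
    }

    # outliers: global mean shift, separates on PC1
    if config.n_outliers:
        out_idx = rng.choice(n, config.n_outliers, replace=False)
        x[:, out_idx] += 10.0 * config.noise_sd
        for i in out_idx:
            truth_samples[sample_ids[i]]["is_outlier"] = True

    # low-RIN samples (drawn among non-outliers)
    if config.n_low_rin:
        pool = [i for i in range(n) if not truth_samples[sample_ids[i]]["is_outlier"]]
        low_idx = rng.choice(pool, config.n_low_rin, replace=False)
        rin = meta["rin"].to_numpy(copy=True)
        rin[low_idx] = np.round(rng.uniform(4.0, 5.9, config.n_low_rin), 1)
        meta["rin"] = rin
        for i in low_idx:
            truth_samples[sample_ids[i]]["is_low_quality"] = True

    # duplicates: extra columns that are near-copies of existing clean samples
    # (a copy of a planted outlier / low-RIN sample would inherit that flaw
    # and be excluded for the wrong reason)
    if config.n_duplicates:
        clean = [i for i in range(n)
                 if not (truth_samples[sample_ids[i]]["is_outlier"]
                         or truth_samples[sample_ids[i]]["is_low_quality"])]
        src_idx = rng.choice(clean, config.n_duplicates, replace=False)
        dup_cols = x[:, src_idx] + rng.normal(0.0, 0.02 * config.noise_sd,
                                              (p, config.n_duplicates))
        x = np.hstack([x, dup_cols])
        for j, i in enumerate(src_idx):
            sid = f"S{n + j + 1:04d}"
            sample_ids.append(sid)
            meta.loc[sid] = meta.iloc[i]
            truth_samples[sid] = {
                "is_duplicate": True, "is_outlier": False,
                "is_low_quality": False, "is_replication_designate": False,
            }

    expression = pd.DataFrame(
        np.exp2(x), index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )

    chrom = rng.choice([str(c) for c in range(1, 23)], p)
    annotation = pd.DataFrame(
        {
            "chromosome": chrom,
            "is_specific": True,
            "is_retired": False,
            "gene_symbol": [f"GENE{i + 1:05d}" for i in range(p)],
            "is_sex_check_probe": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    if config.n_sex_probes:
        sex_ids = probe_ids[p - config.n_sex_probes:]
        annotation.loc[sex_ids, "chromosome"] = "X"
        annotation.loc[sex_ids, "is_sex_check_probe"] = True

    return SyntheticDataset(expression, meta, annotation, truth, truth_samples)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["planted_modules"] = [asdict(m) for m in config.planted_modules]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    mods = [PlantedModule(**m) if isinstance(m, dict) else m
            for m in d.pop("planted_modules", [])]
    try:
        return SimulationConfig(planted_modules=mods, **d)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
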