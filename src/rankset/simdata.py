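"""Synthetic count-data generator for the 2x2 glucose x drug design.

Generates negative-binomial count matrices for a four-group (LG, LGV,
HG, HGV) replicated design together with gene-set collections containing
null sets and sets carrying planted, coordinated log2-fold-change shifts
(e.g. induced under high glucose and reversed by the drug), plus the
exact ground truth, so every downstream stage of the pipeline can be
tested without any external data.

Counts follow the mean/dispersion convention of mainstream RNA-seq
differential-expression tools: mean ``lam``, variance ``lam + phi *
lam**2`` with per-gene dispersion ``phi = phi0 + a / lam``. Library-size
variation is applied through the negative-binomial mean (the family is
closed under mean scaling), not by post-hoc thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConfigError, CountMatrix
from .formats import GeneSetCollection

__all__ = [
    "SetSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_experiment",
    "true_contrast_table",
    "GROUPS",
    "CONTRASTS",
]

#: Canonical group ordering for the 2x2 design.
GROUPS = ("LG", "LGV", "HG", "HGV")

#: The two encoded contrasts, each (treatment, control).
CONTRASTS = {"HG-vs-LG": ("HG", "LG"), "HGV-vs-HG": ("HGV", "HG")}


@dataclass(frozen=True)
class SetSpec:
    """Specification of a block of planted (or null) gene sets.

    ``delta_glucose`` is the log2 fold change applied to HG and HGV group
    means; ``delta_vpa`` the additional log2 fold change applied to HGV
    relative to HG. ``delta_vpa_lg`` optionally gives LGV its own drug
    response relative to LG (independent of HGV by default, since the
    design does not force the two to be equal).
    """

    set_size: int
    n_sets: int
    delta_glucose: float = 0.0
    delta_vpa: float = 0.0
    delta_vpa_lg: float = 0.0

    @property
    def is_null(self) -> bool:
        return self.delta_glucose == 0.0 and self.delta_vpa == 0.0 and self.delta_vpa_lg == 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 10000
    n_reps: int = 3
    groups: tuple[str, ...] = GROUPS
    baseline_log2_mean_mu: float = 6.0
    baseline_log2_mean_sd: float = 2.0
    dispersion_asymptote: float = 0.05  # phi0
    dispersion_slope: float = 0.5  # a in phi = phi0 + a / lam
    libsize_cv: float = 0.1
    set_specs: tuple[SetSpec, ...] = ()
    frac_dropout_members: float = 0.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes: must be >= 2")
        if self.n_reps < 2:
            raise ConfigError("n_reps: must be >= 2")
        if len(self.groups) != len(set(self.groups)):
            raise ConfigError("groups: labels must be unique")
        if self.dispersion_asymptote < 0:
            raise ConfigError("dispersion_asymptote: must be >= 0")
        if self.dispersion_slope < 0:
            raise ConfigError("dispersion_slope: must be >= 0")
        if self.libsize_cv < 0:
            raise ConfigError("libsize_cv: must be >= 0")
        if not 0.0 <= self.frac_dropout_members <= 1.0:
            raise ConfigError("frac_dropout_members: must be in [0, 1]")
        total_members = 0
        for spec in self.set_specs:
            if spec.set_size < 2:
                raise ConfigError("set_specs: set_size must be >= 2")
            if spec.set_size >= self.n_genes:
                raise ConfigError("set_specs: set_size must be < n_genes")
            if spec.n_sets < 1:
                raise ConfigError("set_specs: n_sets must be >= 1")
            for name in ("delta_glucose", "delta_vpa", "delta_vpa_lg"):
                if not np.isfinite(getattr(spec, name)):
                    raise ConfigError(f"set_specs: {name} must be finite")
            total_members += spec.set_size * spec.n_sets
        if not self.allow_overlap and total_members > self.n_genes:
            raise ConfigError(
                "set_specs: total disjoint membership exceeds n_genes "
                f"({total_members} > {self.n_genes})"
            )


@dataclass
class GroundTruth:
    """Planted per-gene log2 fold changes and per-set labels.

    ``table`` is indexed by gene identifier with columns ``lfc_glucose``
    (true HG-vs-LG log2FC) and ``lfc_vpa`` (true HGV-vs-HG log2FC);
    genes in no planted set carry zeros. ``set_info`` records, per set,
    its size, planted deltas and null status.
    """

    table: pd.DataFrame
    set_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def true_log2fc(self, contrast: str) -> pd.Series:
        return true_contrast_table(self, contrast)["log2fc"]


def true_contrast_table(truth: GroundTruth, contrast: str) -> pd.DataFrame:
    """Per-gene true log2 fold change for one of the encoded contrasts."""
    columns = {"HG-vs-LG": "lfc_glucose", "HGV-vs-HG": "lfc_vpa"}
    if contrast not in columns:
        raise ConfigError(
            f"contrast: unknown label {contrast!r}; expected one of {sorted(columns)}"
        )
    out = truth.table[[columns[contrast]]].rename(columns={columns[contrast]: "log2fc"})
    return out.reset_index()


def _group_log2_effects(spec: SetSpec) -> dict[str, float]:
    return {
        "LG": 0.0,
        "LGV": spec.delta_vpa_lg,
        "HG": spec.delta_glucose,
        "HGV": spec.delta_glucose + spec.delta_vpa,
    }


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, GeneSetCollection, GroundTruth]:
    """Draw one synthetic experiment.

    Returns the count matrix (genes x samples with design), the gene-set
    collection described by ``config.set_specs``, and the exact ground
    truth. Identical config (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_reps = config.n_genes, config.n_reps
    groups = list(config.groups)
    gene_ids = pd.Index([f"G{i:06d}" for i in range(1, n_genes + 1)], name="gene_id")
    sample_ids = [f"{g}_{r}" for g in groups for r in range(1, n_reps + 1)]
    design = pd.Series(
        [g for g in groups for _ in range(n_reps)],
        index=pd.Index(sample_ids, name="sample"),
        name="group",
    )

    baseline = np.exp2(
        rng.normal(config.baseline_log2_mean_mu, config.baseline_log2_mean_sd, size=n_genes)
    )
    phi = config.dispersion_asymptote + config.dispersion_slope / baseline

    # per-gene, per-group log2 effect matrix
    effects = pd.DataFrame(0.0, index=gene_ids, columns=groups)
    lfc_glucose = np.zeros(n_genes)
    lfc_vpa = np.zeros(n_genes)

    sets = GeneSetCollection()
    set_rows = []
    cursor = 0
    set_counter = 0
    for spec in config.set_specs:
        for _ in range(spec.n_sets):
            set_counter += 1
            name = f"SET{set_counter:04d}"
            if config.allow_overlap:
                idx = np.sort(rng.choice(n_genes, size=spec.set_size, replace=False))
            else:
                idx = np.arange(cursor, cursor + spec.set_size)
                cursor += spec.set_size
            members = gene_ids[idx]
            sets.add(name, "simulated", members)
            n_drop = int(np.floor(config.frac_dropout_members * spec.set_size))
            if n_drop > 0:
                dropped = rng.choice(idx, size=n_drop, replace=False)
            else:
                dropped = np.empty(0, dtype=int)
            affected = np.setdiff1d(idx, dropped)
            if not spec.is_null:
                eff = _group_log2_effects(spec)
                for g in groups:
                    effects.iloc[affected, effects.columns.get_loc(g)] += eff.get(g, 0.0)
                lfc_glucose[affected] += spec.delta_glucose
                lfc_vpa[affected] += spec.delta_vpa
            set_rows.append(
                {
                    "set_name": name,
                    "size": spec.set_size,
                    "n_affected": len(affected) if not spec.is_null else 0,
                    "delta_glucose": spec.delta_glucose,
                    "delta_vpa": spec.delta_vpa,
                    "delta_vpa_lg": spec.delta_vpa_lg,
                    "is_null": spec.is_null,
                }
            )

    # library-size factors: log-normal, mean 1, coefficient of variation as configured
    if config.libsize_cv > 0:
        sigma2 = np.log1p(config.libsize_cv**2)
        lib_factors = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(sample_ids))
    else:
        lib_factors = np.ones(len(sample_ids))

    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        group = design.loc[sample]
        mu = baseline * np.exp2(effects[group].to_numpy()) * lib_factors[j]
        counts[:, j] = _nb_draw(rng, mu, phi)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), design)
    truth = GroundTruth(
        table=pd.DataFrame(
            {"lfc_glucose": lfc_glucose, "lfc_vpa": lfc_vpa}, index=gene_ids
        ),
        set_info=pd.DataFrame(set_rows),
    )
    return cm, sets, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative-binomial draw with mean ``mu``, variance ``mu + phi mu^2``.

    Genes with ``phi == 0`` fall back to Poisson (the NB limit).
    """
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / phi[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out
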