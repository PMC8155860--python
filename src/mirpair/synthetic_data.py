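"""Seeded generator for paired miRNome/transcriptome datasets with planted signal.

The generator emulates a small paired-tissue design: a handful of control and
lesion samples profiled on both a miRNA and an mRNA platform, on log2 scale.
A chosen subset of features is differentially expressed between groups, and a
chosen subset of DE mRNAs is anti-coupled to a DE miRNA: across every sample
the target's expression is its baseline minus ``coupling_strength`` times the
regulator's expression, plus Gaussian noise, so pooled-sample Pearson
correlation of a planted pair is negative (exactly -1 when ``noise_sd`` is 0).

Alongside the expression matrices the generator emits synthetic
target-prediction databases (each planted pair listed with probability
``db_coverage`` per database, plus random decoy pairs) and a GMT gene-set
collection in which at least one set is enriched for planted targets, with a
designated structure-gene subset recorded for composition scoring.

Defaults mirror the emulated study design: 3 control vs 4 lesion samples,
75 DE miRNAs, 562 DE mRNAs, and three prediction databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionDataset,
    GeneSetCollection,
    PredictionDB,
    read_expression_tsv,
    read_group_labels,
    write_expression_tsv,
    write_gene_list,
    write_gmt,
    write_group_labels,
    write_prediction_db,
)

logger = logging.getLogger("mirpair")

# log2-scale baseline model: per-feature mean ~ Normal(BASELINE_MEAN, BASELINE_SD),
# chosen to resemble processed array/NGS intensities.
BASELINE_MEAN = 6.0
BASELINE_SD = 2.0


class ConfigError(ValueError):
    """A SimulationConfig violating one of its bounds."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-omics simulation (log2 scale throughout)."""

    n_control: int = 3
    n_lesion: int = 4
    n_mirna: int = 200
    n_mrna: int = 1500
    n_de_mirna: int = 75
    n_de_mrna: int = 562
    fc_range: tuple[float, float] = (4.0, 16.0)
    n_planted_pairs: int = 330
    coupling_strength: float = 1.0
    noise_sd: float = 0.2
    db_count: int = 3
    db_coverage: float = 0.7
    decoy_rate: float = 1000.0
    n_gene_sets: int = 25
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_control": self.n_control,
            "n_lesion": self.n_lesion,
            "n_mirna": self.n_mirna,
            "n_mrna": self.n_mrna,
            "n_de_mirna": self.n_de_mirna,
            "n_de_mrna": self.n_de_mrna,
            "n_planted_pairs": self.n_planted_pairs,
            "db_count": self.db_count,
            "n_gene_sets": self.n_gene_sets,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.n_de_mirna > self.n_mirna:
            raise ConfigError(f"n_de_mirna ({self.n_de_mirna}) exceeds n_mirna ({self.n_mirna})")
        if self.n_de_mrna > self.n_mrna:
            raise ConfigError(f"n_de_mrna ({self.n_de_mrna}) exceeds n_mrna ({self.n_mrna})")
        if self.n_planted_pairs > self.n_de_mirna * self.n_de_mrna:
            raise ConfigError(
                f"n_planted_pairs ({self.n_planted_pairs}) exceeds "
                f"n_de_mirna * n_de_mrna ({self.n_de_mirna * self.n_de_mrna})"
            )
        if self.n_planted_pairs > self.n_de_mrna:
            # each target mRNA is coupled to a single regulator
            raise ConfigError(
                f"n_planted_pairs ({self.n_planted_pairs}) exceeds n_de_mrna "
                f"({self.n_de_mrna}); each planted target couples to one miRNA"
            )
        if not 0.0 <= self.db_coverage <= 1.0:
            raise ConfigError(f"db_coverage must be in [0, 1], got {self.db_coverage}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.decoy_rate < 0:
            raise ConfigError(f"decoy_rate must be >= 0, got {self.decoy_rate}")
        lo, hi = self.fc_range
        if not (0 < lo <= hi):
            raise ConfigError(f"fc_range must satisfy 0 < low <= high, got {self.fc_range}")


@dataclass
class GroundTruth:
    """Planted signal of one simulated dataset.

    ``de_mirnas`` / ``de_mrnas`` map planted-DE feature ids to their true
    log2 fold change (lesion minus control); ``planted_pairs`` maps each
    planted (mirna_id, mrna_id) coupling to its coupling strength.
    ``structure_genes`` is the designated cell-structure subset of the mRNA
    universe used by the composition scoring downstream.
    """

    de_mirnas: dict[str, float]
    de_mrnas: dict[str, float]
    planted_pairs: dict[tuple[str, str], float]
    structure_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mi, mr in self.planted_pairs:
            if mi not in self.de_mirnas or mr not in self.de_mrnas:
                raise ValueError(f"planted pair ({mi}, {mr}) references a non-DE feature")


def _feature_ids(prefix: str, n: int, width: int) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionDataset, GroundTruth, list[PredictionDB], GeneSetCollection]:
    """Simulate one paired dataset with planted DE features and anti-couplings.

    Returns the dataset, its ground truth, the synthetic prediction databases
    and a gene-set collection. Identical config (including seed) gives
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = config.n_control + config.n_lesion
    samples = [f"ctrl{i + 1}" for i in range(config.n_control)] + [
        f"les{i + 1}" for i in range(config.n_lesion)
    ]
    groups = pd.Series(
        ["control"] * config.n_control + ["lesion"] * config.n_lesion,
        index=samples,
        name="group",
    )
    lesion_mask = (groups == "lesion").to_numpy()

    mirna_ids = _feature_ids("mir", config.n_mirna, 4)
    mrna_ids = _feature_ids("gene", config.n_mrna, 6)

    # --- planted DE assignment -------------------------------------------
    de_mirna_idx = rng.choice(config.n_mirna, size=config.n_de_mirna, replace=False)
    de_mrna_idx = rng.choice(config.n_mrna, size=config.n_de_mrna, replace=False)
    lo, hi = config.fc_range
    lfc_mirna = np.log2(rng.uniform(lo, hi, size=config.n_de_mirna)) * rng.choice(
        [-1.0, 1.0], size=config.n_de_mirna
    )
    lfc_mrna = np.log2(rng.uniform(lo, hi, size=config.n_de_mrna)) * rng.choice(
        [-1.0, 1.0], size=config.n_de_mrna
    )

    # couplings: distinct target mRNAs, each paired to a random DE miRNA
    target_pos = rng.choice(config.n_de_mrna, size=config.n_planted_pairs, replace=False)
    regulator_pos = rng.integers(0, config.n_de_mirna, size=config.n_planted_pairs)

    # --- miRNA matrix -----------------------------------------------------
    lesion_cols = lesion_mask.nonzero()[0]
    base_mi = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_mirna)
    mi = base_mi[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_mirna, n_samples))
    mi[np.ix_(de_mirna_idx, lesion_cols)] += lfc_mirna[:, None]

    # --- mRNA matrix ------------------------------------------------------
    base_mr = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_mrna)
    mr = base_mr[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_mrna, n_samples))
    mr[np.ix_(de_mrna_idx, lesion_cols)] += lfc_mrna[:, None]
    # anti-coupling overrides the target's own expression in every sample
    coupling_noise = rng.normal(0.0, config.noise_sd, size=(config.n_planted_pairs, n_samples))
    tgt_rows = de_mrna_idx[target_pos]
    reg_rows = de_mirna_idx[regulator_pos]
    # baseline offset keeps the target near its own baseline level on average
    offset = base_mr[tgt_rows] + config.coupling_strength * base_mi[reg_rows]
    mr[tgt_rows] = offset[:, None] - config.coupling_strength * mi[reg_rows] + coupling_noise

    mirna = pd.DataFrame(mi, index=pd.Index(mirna_ids, name="feature_id"), columns=samples)
    mrna = pd.DataFrame(mr, index=pd.Index(mrna_ids, name="feature_id"), columns=samples)
    dataset = ExpressionDataset(mirna, mrna, groups)

    # true log2fc of a coupled target is induced by its regulator's shift
    de_mrna_lfc = dict(zip((mrna_ids[i] for i in de_mrna_idx), lfc_mrna))
    for t, r in zip(target_pos, regulator_pos):
        de_mrna_lfc[mrna_ids[de_mrna_idx[t]]] = -config.coupling_strength * lfc_mirna[r]

    planted_pairs = {
        (mirna_ids[r], mrna_ids[t]): config.coupling_strength
        for r, t in zip(reg_rows, tgt_rows)
    }
    truth = GroundTruth(
        de_mirnas=dict(zip((mirna_ids[i] for i in de_mirna_idx), lfc_mirna)),
        de_mrnas=de_mrna_lfc,
        planted_pairs=planted_pairs,
        structure_genes=[],
    )

    databases = _generate_databases(config, rng, truth)
    collection, structure_genes = _generate_gene_sets(config, rng, truth, mrna_ids)
    truth.structure_genes = structure_genes

    logger.info(
        "simulated dataset: %d miRNAs x %d samples, %d mRNAs, %d planted pairs, seed=%d",
        config.n_mirna, n_samples, config.n_mrna, config.n_planted_pairs, config.seed,
    )
    return dataset, truth, databases, collection


def _generate_databases(
    config: SimulationConfig, rng: np.random.Generator, truth: GroundTruth
) -> list[PredictionDB]:
    """Each database lists a planted pair with probability db_coverage plus decoys.

    Decoys are uniform draws from the non-planted (DE miRNA x DE mRNA) pairs.
    """
    de_mirnas = sorted(truth.de_mirnas)
    de_mrnas = sorted(truth.de_mrnas)
    planted = set(truth.planted_pairs)
    databases = []
    for d in range(config.db_count):
        keep = rng.random(len(planted)) < config.db_coverage
        pairs = {p for p, k in zip(sorted(planted), keep) if k}
        n_free = len(de_mirnas) * len(de_mrnas) - len(planted)
        n_decoys = min(rng.poisson(config.decoy_rate), n_free)
        while n_decoys > 0:
            mi = rng.choice(de_mirnas, size=n_decoys)
            mr = rng.choice(de_mrnas, size=n_decoys)
            new = {(a, b) for a, b in zip(mi, mr)} - planted - pairs
            pairs |= new
            n_decoys -= len(new)
            if len(pairs) - len(planted & pairs) >= n_free:
                break
        databases.append(PredictionDB(f"synthdb{d + 1}", frozenset(pairs)))
    return databases


def _generate_gene_sets(
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: GroundTruth,
    mrna_ids: list[str],
) -> tuple[GeneSetCollection, list[str]]:
    """Random gene sets over the mRNA universe, one enriched for planted targets.

    A tenth of the universe is designated "structure" genes; two sets are
    biased toward them so composition scores are non-trivial downstream.
    """
    universe = np.array(mrna_ids)
    n_structure = max(10, len(universe) // 10)
    structure = sorted(rng.choice(universe, size=n_structure, replace=False))
    structure_set = set(structure)
    targets = sorted({mr for _, mr in truth.planted_pairs})

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}

    # one set stacked with planted targets -> reliably enriched downstream
    n_t = min(40, len(targets))
    chosen = list(rng.choice(targets, size=n_t, replace=False))
    padding = rng.choice(universe, size=20, replace=False)
    sets["planted_target_set"] = sorted(set(chosen) | set(padding))
    descriptions["planted_target_set"] = "synthetic set enriched for planted miRNA targets"

    # two structure-heavy sets
    for i in (1, 2):
        n_struct = 30
        picked = set(rng.choice(structure, size=min(n_struct, len(structure)), replace=False))
        picked |= set(rng.choice(universe, size=10, replace=False))
        name = f"structure_set{i}"
        sets[name] = sorted(picked)
        descriptions[name] = "synthetic set biased toward structure genes"

    for i in range(len(sets) + 1, config.n_gene_sets + 1):
        size = int(rng.integers(30, 80))
        name = f"random_set{i:02d}"
        sets[name] = sorted(rng.choice(universe, size=size, replace=False))
        descriptions[name] = "synthetic random gene set"

    return GeneSetCollection(sets, descriptions), list(structure)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: ExpressionDataset,
    path: str | Path,
    truth: GroundTruth | None = None,
    databases: list[PredictionDB] | None = None,
    collection: GeneSetCollection | None = None,
) -> None:
    """Write a dataset (and optionally its companions) under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(dataset.mirna, path / "mirna_expression.tsv")
    write_expression_tsv(dataset.mrna, path / "mrna_expression.tsv")
    write_group_labels(dataset.groups, path / "sample_groups.tsv")
    if truth is not None:
        pd.DataFrame(
            [(mi, mr, s) for (mi, mr), s in sorted(truth.planted_pairs.items())],
            columns=["mirna_id", "mrna_id", "coupling_strength"],
        ).to_csv(path / "planted_pairs.tsv", sep="\t", index=False)
        write_gene_list(truth.structure_genes, path / "structure_genes.txt")
    for db in databases or []:
        write_prediction_db(db, path / f"{db.name}.tsv")
    if collection is not None:
        write_gmt(collection, path / "gene_sets.gmt")


def read_dataset(path: str | Path) -> ExpressionDataset:
    """Read back the three core TSVs written by :func:`write_dataset`."""
    path = Path(path)
    return ExpressionDataset(
        mirna=read_expression_tsv(path / "mirna_expression.tsv"),
        mrna=read_expression_tsv(path / "mrna_expression.tsv"),
        groups=read_group_labels(path / "sample_groups.tsv"),
    )


def scaled_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A small configuration for quick tests: same design, fewer features."""
    base = dict(
        n_mirna=30, n_mrna=120, n_de_mirna=10, n_de_mrna=40,
        n_planted_pairs=20, decoy_rate=30.0, n_gene_sets=8, seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)
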