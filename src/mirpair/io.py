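"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular formats are TSV. An expression matrix file has a ``feature_id``
first column followed by one column per sample; miRNA and mRNA matrices for
the same study must carry identical, identically ordered sample columns.
Group labels are a two-column TSV (``sample_id``, ``group``) with groups in
{control, lesion}. Target-prediction databases are two-column TSVs
(``mirna_id``, ``mrna_id``). Gene sets use GMT (set name, description, then
member genes, tab-separated); the structure-gene list is one symbol per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("mirpair")

GROUPS = ("control", "lesion")


class ParseError(ValueError):
    """A malformed input file (ragged rows, duplicates, label/sample mismatch)."""


@dataclass
class ExpressionDataset:
    """Matched miRNA and mRNA expression matrices plus sample group labels.

    Both matrices are log2-scale, features x samples, indexed by feature id;
    ``groups`` maps each sample id to ``control`` or ``lesion``.
    """

    mirna: pd.DataFrame
    mrna: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if list(self.mirna.columns) != list(self.mrna.columns):
            raise ParseError(
                "sample mismatch: miRNA matrix columns "
                f"{list(self.mirna.columns)} != mRNA matrix columns "
                f"{list(self.mrna.columns)}"
            )
        missing = [s for s in self.mirna.columns if s not in self.groups.index]
        if missing:
            raise ParseError(f"sample mismatch: no group label for samples {missing}")
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise ParseError(f"unknown group labels {bad}; expected {GROUPS}")

    @property
    def samples(self) -> list[str]:
        return list(self.mirna.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]


@dataclass
class PredictionDB:
    """One target-prediction database: a named set of (mirna_id, mrna_id) pairs."""

    name: str
    pairs: frozenset[tuple[str, str]]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


@dataclass
class GeneSetCollection:
    """GMT-style gene-set collection: set id -> (description, member genes)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# expression matrices and labels
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "feature_id":
            raise ParseError(f"{path.name}: first column must be 'feature_id', got {header[:1]}")
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            if len(line.rstrip("\n").split("\t")) != ncol:
                raise ParseError(f"{path.name}: ragged row at line {lineno} (expected {ncol} columns)")
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"{path.name}: duplicate feature ids {dup}")
    if df.isna().any().any():
        raise ParseError(f"{path.name}: missing values present")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")


def read_group_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample_id", "group"]:
        raise ParseError(f"label file columns must be ['sample_id', 'group'], got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample ids in label file")
    return df.set_index("sample_id")["group"]


def write_group_labels(groups: pd.Series, path: str | Path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# prediction databases
# ---------------------------------------------------------------------------

def read_prediction_db(path: str | Path, name: str | None = None) -> PredictionDB:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["mirna_id", "mrna_id"]:
        raise ParseError(
            f"{path.name}: prediction DB columns must be ['mirna_id', 'mrna_id'], got {list(df.columns)}"
        )
    return PredictionDB(name or path.stem, frozenset(map(tuple, df.itertuples(index=False))))


def write_prediction_db(db: PredictionDB, path: str | Path) -> None:
    pd.DataFrame(sorted(db.pairs), columns=["mirna_id", "mrna_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT) and structure-gene lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"GMT line {lineno}: need set name, description and >=1 gene")
            name, desc, *genes = parts
            if name in sets:
                raise ParseError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
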