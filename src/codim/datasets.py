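"""In-memory containers and TSV I/O for expression compendia.

Matrices are pandas DataFrames, genes as rows and treatment profiles as
columns, everywhere in the package. Gene and profile identifiers are opaque
strings. Each dataset optionally carries an untreated (control) matrix on
the same gene space, a present-call matrix, and per-profile metadata
(drug, batch, dose, time, replicate, control flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


#: profile metadata columns understood by the pipeline (all optional except drug)
META_COLUMNS = ("drug", "batch", "dose", "time", "replicate", "control", "cell_line")


@dataclass
class ExpressionDataset:
    """Genes x treatment-profiles expression matrix with metadata.

    Parameters
    ----------
    values : DataFrame
        Expression matrix, rows indexed by gene (or probe) id, columns by
        profile id. Scale recorded in ``scale`` ("raw" or "zscore").
    profile_meta : DataFrame
        Indexed by profile id; any subset of ``META_COLUMNS``.
    gene_meta : DataFrame, optional
        Indexed by row id; a ``gene`` column maps probes to genes before
        probe collapse.
    untreated : DataFrame, optional
        Control/untreated expression on the same gene space (its own
        profile columns).
    present : DataFrame, optional
        0/1 present-call matrix aligned with ``values``.
    """

    values: pd.DataFrame
    profile_meta: pd.DataFrame | None = None
    gene_meta: pd.DataFrame | None = None
    untreated: pd.DataFrame | None = None
    present: pd.DataFrame | None = None
    scale: str = "zscore"
    dataset_id: str = "dataset"
    kind: str = "cellline"  # or "liver"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate profile ids")
        if self.profile_meta is None:
            self.profile_meta = pd.DataFrame(index=self.values.columns)
        missing = self.values.columns.difference(self.profile_meta.index)
        if len(missing):
            raise ValidationError(f"profiles lacking metadata: {list(missing)[:5]}")
        self.profile_meta = self.profile_meta.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def profiles(self) -> pd.Index:
        return self.values.columns

    def drug_of_profile(self) -> pd.Series:
        """Profile id -> drug id (identity when no drug column present)."""
        if "drug" in self.profile_meta.columns:
            return self.profile_meta["drug"]
        return pd.Series(self.profiles, index=self.profiles)

    @property
    def drugs(self) -> list[str]:
        return sorted(set(self.drug_of_profile()))

    def subset_profiles(self, profiles) -> "ExpressionDataset":
        profiles = [p for p in profiles if p in self.values.columns]
        return ExpressionDataset(
            values=self.values[profiles].copy(),
            profile_meta=self.profile_meta.loc[profiles].copy(),
            gene_meta=None if self.gene_meta is None else self.gene_meta.copy(),
            untreated=None if self.untreated is None else self.untreated.copy(),
            present=None if self.present is None else self.present[profiles].copy(),
            scale=self.scale,
            dataset_id=self.dataset_id,
            kind=self.kind,
        )

    def to_dir(self, path) -> Path:
        """Write the dataset as plain TSV files under ``path``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        _write_tsv(self.values, path / "values.tsv", index_label="gene")
        _write_tsv(self.profile_meta, path / "profiles.tsv", index_label="profile")
        if self.gene_meta is not None:
            _write_tsv(self.gene_meta, path / "genes.tsv", index_label="row")
        if self.untreated is not None:
            _write_tsv(self.untreated, path / "untreated.tsv", index_label="gene")
        if self.present is not None:
            _write_tsv(self.present, path / "present.tsv", index_label="gene")
        (path / "scale.txt").write_text(f"{self.scale}\t{self.dataset_id}\t{self.kind}\n")
        return path

    @classmethod
    def from_dir(cls, path) -> "ExpressionDataset":
        path = Path(path)
        scale, dataset_id, kind = (
            (path / "scale.txt").read_text().strip().split("\t")
            if (path / "scale.txt").exists()
            else ("zscore", path.name, "cellline")
        )
        return cls(
            values=read_matrix_tsv(path / "values.tsv"),
            profile_meta=pd.read_csv(path / "profiles.tsv", sep="\t", index_col=0),
            gene_meta=(
                pd.read_csv(path / "genes.tsv", sep="\t", index_col=0)
                if (path / "genes.tsv").exists()
                else None
            ),
            untreated=(
                read_matrix_tsv(path / "untreated.tsv")
                if (path / "untreated.tsv").exists()
                else None
            ),
            present=(
                read_matrix_tsv(path / "present.tsv")
                if (path / "present.tsv").exists()
                else None
            ),
            scale=scale,
            dataset_id=dataset_id,
            kind=kind,
        )


@dataclass(frozen=True)
class OrthologyMap:
    """One-to-one gene correspondence between two namespaces (e.g. human/rat).

    ``pairs`` is a DataFrame with columns ``gene_a`` (reference) and
    ``gene_b`` (other species); no gene may appear twice on either side.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene_a", "gene_b"):
            if col not in self.pairs.columns:
                raise ValidationError(f"orthology table lacks column {col!r}")
            if self.pairs[col].duplicated().any():
                raise ValidationError(f"orthology map not one-to-one in {col!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    def b_to_a(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))

    def a_to_b(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    @classmethod
    def identity(cls, genes) -> "OrthologyMap":
        genes = list(genes)
        return cls(pd.DataFrame({"gene_a": genes, "gene_b": genes}))

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t")
        df.columns = ["gene_a", "gene_b"] + list(df.columns[2:])
        return cls(df[["gene_a", "gene_b"]])


def _write_tsv(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a genes x profiles TSV matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path, index_label="gene")
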