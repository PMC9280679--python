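"""Readers and writers for the pipeline's tabular and gene-set formats.

Formats are deliberately plain: expression matrices are TSV (genes as
rows, samples as columns), sample metadata is CSV/TSV with ``sample_id``
and ``group`` columns, gene sets are GMT. Expression values are stored on
the LINEAR scale; log transformation happens inside the statistical
operations, so fold changes stay simple ratios of group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three patient groups, in presentation order.
GROUPS = ("presurgical", "SIRS", "sepsis")


class FormatError(ValueError):
    """A file violated the expected format or an input invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized intensities (linear scale).

    ``data`` is a pandas DataFrame indexed by gene id with sample ids as
    columns. All values must be finite and strictly positive; gene and
    sample ids must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.columns[
                [not np.issubdtype(t, np.number) for t in df.dtypes]
            ].tolist()
            raise FormatError(f"non-numeric values in columns {bad[:5]}")
        finite = np.isfinite(values)
        if not finite.all():
            g, s = np.argwhere(~finite)[0]
            raise FormatError(
                f"missing or non-finite value for gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        if (values <= 0).any():
            g, s = np.argwhere(values <= 0)[0]
            raise FormatError(
                f"non-positive intensity {values[g, s]!r} for gene "
                f"{df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)])


@dataclass
class GeneSet:
    name: str
    class_label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets with a free-text class label each (GMT field 2)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise FormatError(f"duplicate gene-set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: no expression rows")
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() | df[col].isna()
            if bad.any():
                gene = df.index[np.argmax(bad.to_numpy())]
                raise FormatError(
                    f"{path}: missing or non-numeric value for gene "
                    f"{gene!r}, sample {col!r}"
                ) from None
        raise
    if df.isna().to_numpy().any():
        gene, col = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value for gene {df.index[gene]!r}, "
            f"sample {df.columns[col]!r}"
        )
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path) -> pd.Series:
    """Read sample metadata (``sample_id``, ``group``) as a Series.

    Returned Series maps sample id -> group; groups are restricted to
    ``presurgical``, ``SIRS`` and ``sepsis``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "group"}
    if df.empty or not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expected non-empty table with columns {sorted(required)}"
        )
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        offending = df.loc[bad, "group"].unique().tolist()
        raise FormatError(
            f"{path}: unknown group label(s) {offending}; allowed: {list(GROUPS)}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups[:5]}")
    return pd.Series(
        df["group"].to_numpy(), index=df["sample_id"].to_numpy(), name="group"
    )


def write_sample_table(samples: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": samples.index, "group": samples.to_numpy()}).to_csv(
        path, index=False
    )


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name <TAB> class/description <TAB> member genes..."""
    coll = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, class and >=1 member"
                )
            name, class_label, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            coll.add(GeneSet(name, class_label, frozenset(members)))
    if len(coll) == 0:
        raise FormatError(f"{path}: no gene sets found")
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.class_label}\t{members}\n")


def read_gene_list(path, name: str, class_label: str = "") -> GeneSetCollection:
    """Read a one-symbol-per-line list (e.g. a lysosomal gene catalogue)
    into a single-set collection."""
    with open(path, "r", encoding="utf-8") as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    dupes = pd.Index(genes).duplicated()
    if dupes.any():
        raise FormatError(
            f"{path}: duplicate gene(s) {pd.Index(genes)[dupes].tolist()[:5]}"
        )
    coll = GeneSetCollection()
    coll.add(GeneSet(name, class_label, frozenset(genes)))
    return coll


def check_samples_match(expr: ExpressionMatrix, samples: pd.Series) -> pd.Series:
    """Align a sample table to an expression matrix.

    Every expression sample must carry exactly one group label, and every
    group present must have at least two samples.
    """
    missing = [s for s in expr.sample_ids if s not in samples.index]
    if missing:
        raise FormatError(f"samples without group assignment: {missing[:10]}")
    aligned = samples.loc[expr.sample_ids]
    counts = aligned.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise FormatError(
            f"groups with fewer than 2 samples: {small.index.tolist()}"
        )
    return aligned
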