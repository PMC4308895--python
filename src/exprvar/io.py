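"""Readers and writers for the package's external text formats.

All tabular formats are plain tab-separated text:

* expression matrix — header row of sample ids, first column gene ids,
  log2-scale values (RMA-style normalized intensities are assumed; no
  normalization is performed here);
* sample groups — two columns ``sample_id<TAB>group``, exactly two groups;
* probe map — two columns ``probe_id<TAB>gene_id``;
* gene sets — GMT dialect (set name, description, tab-separated members).

Expression matrices are represented as :class:`pandas.DataFrame` with genes
in rows and samples in columns; sample groups as :class:`pandas.Series`
indexed by sample id. Missing values are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "GeneSetCollection",
    "validate_expression_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_groups",
    "write_sample_groups",
    "validate_sample_groups",
    "read_probe_map",
    "map_probes_to_genes",
    "read_gene_sets",
    "write_gene_sets",
]


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. pathways loaded from a GMT file."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions


def validate_expression_matrix(m: pd.DataFrame, source: str = "matrix") -> pd.DataFrame:
    """Check the expression-matrix invariants and return the frame unchanged.

    Requires unique gene and sample ids, at least 1 gene and 2 samples, and
    all-finite float values.
    """
    if m.shape[0] < 1 or m.shape[1] < 2:
        raise ValidationError(
            f"{source}: need at least 1 gene and 2 samples, got shape {m.shape}"
        )
    if m.index.duplicated().any():
        dupes = m.index[m.index.duplicated()].unique().tolist()
        raise ValidationError(f"{source}: duplicate gene ids: {dupes[:5]}")
    if m.columns.duplicated().any():
        dupes = m.columns[m.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{source}: duplicate sample ids: {dupes[:5]}")
    values = m.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{source}: matrix contains non-numeric values")
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{source}: non-finite value at gene {m.index[i]!r}, "
            f"sample {m.columns[j]!r}"
        )
    return m


def read_expression_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a gene×sample expression matrix from delimited text.

    First row is the sample header; first column holds gene ids. Any cell
    that does not parse as a finite number (including ``NA``) raises
    :class:`ParseError` naming the offending gene and sample.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                      keep_default_na=False, na_values=[])
    raw.index = raw.index.astype(str)
    parsed = {}
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            cell = raw.loc[gene, col]
            raise ParseError(
                f"{path}: cannot parse value {cell!r} at gene {gene!r}, "
                f"sample {col!r}"
            )
        parsed[col] = vals.astype(float)
    m = pd.DataFrame(parsed, index=raw.index)
    return validate_expression_matrix(m, source=str(path))


def write_expression_matrix(m: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a matrix in the dialect :func:`read_expression_matrix` reads."""
    m.to_csv(path, sep=delimiter, index_label="gene_id")


def read_sample_groups(path) -> pd.Series:
    """Read a two-column ``sample_id<TAB>group`` file into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    s = pd.Series(df[1].to_numpy(), index=pd.Index(df[0], name="sample_id"),
                  name="group")
    if s.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids in group file")
    return s


def write_sample_groups(groups: pd.Series, path) -> None:
    groups.to_csv(path, sep="\t", header=False)


def validate_sample_groups(groups: pd.Series, matrix: pd.DataFrame | None = None,
                           min_per_group: int = 2) -> tuple[str, str]:
    """Check the two-group invariant; return the (A, B) labels sorted.

    Every labeled sample must exist in ``matrix`` when one is given, and
    each group must have at least ``min_per_group`` samples (variance tests
    need 3).
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"expected exactly 2 group labels, got {labels}")
    counts = groups.value_counts()
    if (counts < min_per_group).any():
        raise ValidationError(
            f"each group needs >= {min_per_group} samples, got {counts.to_dict()}"
        )
    if matrix is not None:
        missing = groups.index.difference(matrix.columns)
        if len(missing) > 0:
            raise ValidationError(
                f"labeled samples absent from matrix: {missing.tolist()[:5]}"
            )
    return labels[0], labels[1]


def read_probe_map(path) -> pd.Series:
    """Read a two-column ``probe_id<TAB>gene_id`` map (many probes per gene)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    s = pd.Series(df[1].to_numpy(), index=pd.Index(df[0], name="probe_id"),
                  name="gene_id")
    if s.index.duplicated().any():
        dupes = s.index[s.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: probes mapped more than once: {dupes[:5]}")
    return s


def map_probes_to_genes(m: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level by averaging probe rows.

    Probes absent from the map are dropped. Each gene's row is the
    arithmetic mean of its probes' rows.
    """
    mapped = m.index.intersection(probe_map.index)
    if len(mapped) == 0:
        raise ValidationError("no probe in the matrix appears in the probe map")
    sub = m.loc[mapped]
    genes = probe_map.loc[mapped]
    out = sub.groupby(genes.to_numpy()).mean()
    out.index.name = m.index.name
    return out.sort_index()


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: per line a set name, a description, then members."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member, got {len(fields)} fields"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    """Write a GMT file; members sorted for deterministic output."""
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
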