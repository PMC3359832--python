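"""Readers and writers for the tool's file formats.

Formats handled here:

* expression matrices — plain TSV (first column gene ids, header row of
  sample ids) or GCT 1.2;
* pathway collections — standard GMT (name, description, members);
* reference banks — a two-file dialect of our own: ``instances.tsv``
  (instance_id, compound, dose, cell_line) plus ``ranks.tsv``, a
  genes x instances matrix where each column is a permutation of 1..N
  with 1 = most up-regulated.

The original bank this emulates was distributed in a platform-specific
format that the tool does not consume directly; the rank-matrix dialect
keeps only what the scoring needs (a total ordering per instance).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    PathwayCollection,
    ReferenceBank,
    ReferenceInstance,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_reference_bank",
    "write_reference_bank",
    "merge_replicate_instances",
    "read_pair_map",
    "write_pair_map",
]


class ParseError(ValueError):
    pass


def _frame_to_matrix(df: pd.DataFrame, source: str) -> ExpressionMatrix:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = df.index[coerced.isna() & ~df[col].isna()][0]
            raise ParseError(
                f"{source}: non-numeric value at gene {bad!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        logger.warning(
            "%s: %d duplicated gene id(s) (%s...) collapsed by mean",
            source,
            len(dup),
            dup[0],
        )
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(data=df)


def read_expression_matrix(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV or GCT 1.2.

    ``format`` is ``"tsv"`` or ``"gct"``; when omitted it is inferred from
    the file suffix. Duplicate gene rows are collapsed by their mean with a
    logged warning.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"{path}: cannot parse TSV header/body: {exc}") from exc
        if df.shape[1] == 0:
            raise ParseError(f"{path}: line 1: header row defines no samples")
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ParseError(f"{path}: line 1: expected '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2 or not all(d.isdigit() for d in dims[:2]):
                raise ParseError(f"{path}: line 2: malformed dimensions line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        if df.shape[1] and df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
        if df.shape != (n_rows, n_cols):
            raise ParseError(
                f"{path}: dimensions line says {n_rows}x{n_cols}, "
                f"found {df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown expression format: {format!r}")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return _frame_to_matrix(df, str(path))


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_pair_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a patient pairing table (patient_id, pre_sample, post_sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "pre_sample", "post_sample"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: needs columns {sorted(required)}")
    return {
        r.patient_id: (r.pre_sample, r.post_sample) for r in df.itertuples(index=False)
    }


def write_pair_map(pair_map: dict[str, tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(
        [(p, pre, post) for p, (pre, post) in pair_map.items()],
        columns=["patient_id", "pre_sample", "post_sample"],
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT pathway collection, preserving file order.

    Each line is ``name<TAB>description<TAB>gene[<TAB>gene...]``. Genes
    repeated within a line are deduplicated; a repeated pathway name is an
    error.
    """
    collection = PathwayCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and "
                    f"at least one gene; got {len(fields)} field(s)"
                )
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            try:
                collection.add(name, genes, description)
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return collection


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            desc = pathways.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


_BANK_META = "instances.tsv"
_BANK_RANKS = "ranks.tsv"


def read_reference_bank(path: str | Path) -> ReferenceBank:
    """Read a reference bank from a directory with instances.tsv + ranks.tsv.

    ``ranks.tsv`` holds one column per instance; each column must be a
    permutation of 1..N over the gene rows (1 = most up-regulated).
    """
    path = Path(path)
    meta_path, ranks_path = path / _BANK_META, path / _BANK_RANKS
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    required = {"instance_id", "compound", "dose", "cell_line"}
    if not required.issubset(meta.columns):
        raise ParseError(f"{meta_path}: needs columns {sorted(required)}")
    ranks = pd.read_csv(ranks_path, sep="\t", index_col=0)
    ranks.index = ranks.index.astype(str)
    n = ranks.shape[0]
    expected = np.arange(1, n + 1)
    genes = ranks.index.to_numpy()

    missing = set(meta["instance_id"]) - set(ranks.columns)
    if missing:
        raise ValidationError(
            f"metadata rows without a rank column: {sorted(missing)}"
        )
    extra = set(ranks.columns) - set(meta["instance_id"])
    if extra:
        raise ValidationError(f"rank columns without metadata: {sorted(extra)}")

    instances = []
    for row in meta.itertuples(index=False):
        col = ranks[row.instance_id].to_numpy()
        if not np.array_equal(np.sort(col), expected):
            raise ValidationError(
                f"instance {row.instance_id!r}: rank column is not a "
                f"permutation of 1..{n}"
            )
        order = genes[np.argsort(col, kind="stable")]
        instances.append(
            ReferenceInstance(
                instance_id=row.instance_id,
                compound=row.compound,
                dose=row.dose,
                cell_line=row.cell_line,
                order=order,
            )
        )
    return ReferenceBank(instances)


def write_reference_bank(bank: ReferenceBank, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bank.metadata().to_csv(path / _BANK_META, sep="\t", index=False)
    ranks = pd.DataFrame(
        bank.rank_matrix(), index=bank.gene_universe, columns=bank.instance_ids
    )
    ranks.index.name = "gene"
    ranks.to_csv(path / _BANK_RANKS, sep="\t")


def merge_replicate_instances(
    bank: ReferenceBank, key: tuple[str, ...] = ("compound", "dose", "cell_line")
) -> ReferenceBank:
    """Collapse instances sharing the metadata ``key`` into one profile each.

    Replicates are merged in rank space: each gene gets the mean of its
    per-replicate ranks and the merged profile is the re-ranking of those
    means, ties broken by gene id. Rank-space merging avoids any dependence
    on the (already discarded) intensity scale.
    """
    allowed = {"compound", "dose", "cell_line"}
    if not set(key) <= allowed:
        raise ValueError(f"key must be a subset of {sorted(allowed)}")
    groups: dict[tuple, list[ReferenceInstance]] = {}
    for inst in bank:
        k = tuple(getattr(inst, f) for f in key)
        groups.setdefault(k, []).append(inst)

    genes = np.array(bank.gene_universe)
    gene_pos = {g: i for i, g in enumerate(genes)}
    merged = []
    for members in groups.values():
        members = sorted(members, key=lambda i: i.instance_id)
        mean_rank = np.zeros(len(genes))
        for inst in members:
            for r, g in enumerate(inst.order, start=1):
                mean_rank[gene_pos[g]] += r
        mean_rank /= len(members)
        # lexsort: last key is primary -> mean rank ascending, then gene id
        order = genes[np.lexsort((genes, mean_rank))]
        rep = members[0]
        merged.append(
            ReferenceInstance(
                instance_id=rep.instance_id,
                compound=rep.compound,
                dose=rep.dose,
                cell_line=rep.cell_line,
                order=order,
            )
        )
    merged.sort(key=lambda i: i.instance_id)
    return ReferenceBank(merged)
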