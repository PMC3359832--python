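"""Core in-memory containers shared across the pipeline.

The pipeline moves four kinds of objects around:

* :class:`ExpressionMatrix` — genes x samples log2 intensities with
  pre/post sample pairing per patient.
* :class:`PathwayCollection` — an ordered set of named gene sets.
* :class:`ReferenceBank` — a bank of drug-perturbation instances, each a
  total ranking of a shared gene universe from most up- to most
  down-regulated.
* :class:`TagSignature` / :class:`DifferentialRanking` — the query side:
  the per-patient differential ranking and the thresholded up/down tag
  gene lists derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PathwayCollection",
    "ReferenceInstance",
    "ReferenceBank",
    "DifferentialRanking",
    "TagSignature",
]


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (typically log2) intensities.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with one column per sample.
    pair_map
        Mapping ``patient_id -> (pre_sample_id, post_sample_id)``.
    """

    data: pd.DataFrame
    pair_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if cols.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        for patient, pair in self.pair_map.items():
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValidationError(
                    f"patient {patient!r}: pair must be two distinct samples"
                )
            for s in pair:
                if s not in cols:
                    raise ValidationError(
                        f"patient {patient!r} references unknown sample {s!r}"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def check_finite(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values")

    def copy_with(self, data: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, pair_map=dict(self.pair_map))


class PathwayCollection:
    """Ordered mapping of pathway name -> gene set (exact, case-sensitive)."""

    def __init__(
        self,
        pathways: dict[str, frozenset[str]] | None = None,
        descriptions: dict[str, str] | None = None,
    ) -> None:
        self._pathways: dict[str, frozenset[str]] = {}
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for name, genes in (pathways or {}).items():
            self.add(name, genes, self.descriptions.get(name, ""))

    def add(self, name: str, genes, description: str = "") -> None:
        if name in self._pathways:
            raise ValidationError(f"duplicate pathway name: {name!r}")
        genes = frozenset(genes)
        if not genes:
            raise ValidationError(f"pathway {name!r} has an empty gene set")
        self._pathways[name] = genes
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._pathways[name]

    def __contains__(self, name: str) -> bool:
        return name in self._pathways

    def __iter__(self):
        return iter(self._pathways)

    def __len__(self) -> int:
        return len(self._pathways)

    def items(self):
        return self._pathways.items()

    def names(self) -> list[str]:
        return list(self._pathways)

    def subset(self, names) -> "PathwayCollection":
        """Sub-collection restricted to ``names``, original order preserved."""
        keep = set(names)
        return PathwayCollection(
            {n: g for n, g in self._pathways.items() if n in keep},
            {n: d for n, d in self.descriptions.items() if n in keep},
        )


@dataclass
class ReferenceInstance:
    """One perturbation profile: compound x dose (x cell line).

    ``order`` lists every gene of the bank universe exactly once, from the
    most up-regulated (position 1) to the most down-regulated (position N).
    """

    instance_id: str
    compound: str
    dose: str
    cell_line: str
    order: np.ndarray  # gene ids, most up-regulated first

    def rank_of(self) -> dict[str, int]:
        """Mapping gene id -> 1-based rank in this instance's profile."""
        return {g: i + 1 for i, g in enumerate(self.order)}


class ReferenceBank:
    """A collection of reference instances over one shared gene universe."""

    def __init__(self, instances: list[ReferenceInstance]) -> None:
        if not instances:
            raise ValidationError("reference bank has no instances")
        ids = [inst.instance_id for inst in instances]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate instance identifiers in bank")
        universe = frozenset(instances[0].order)
        for inst in instances:
            if len(inst.order) != len(set(inst.order)):
                raise ValidationError(
                    f"instance {inst.instance_id!r}: profile repeats a gene"
                )
            if frozenset(inst.order) != universe:
                raise ValidationError(
                    f"instance {inst.instance_id!r}: profile is not a "
                    "permutation of the bank gene universe"
                )
        self.instances = list(instances)
        self.gene_universe: list[str] = sorted(universe)
        self._rank_matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    @property
    def instance_ids(self) -> list[str]:
        return [inst.instance_id for inst in self.instances]

    def rank_matrix(self) -> np.ndarray:
        """Ranks (1 = most up-regulated) as a genes x instances array.

        Rows follow :attr:`gene_universe` (lexicographic) order.
        """
        if self._rank_matrix is None:
            gene_pos = {g: i for i, g in enumerate(self.gene_universe)}
            mat = np.empty((len(self.gene_universe), len(self.instances)), dtype=np.int64)
            for k, inst in enumerate(self.instances):
                for r, g in enumerate(inst.order, start=1):
                    mat[gene_pos[g], k] = r
            self._rank_matrix = mat
        return self._rank_matrix

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "instance_id": [i.instance_id for i in self.instances],
                "compound": [i.compound for i in self.instances],
                "dose": [i.dose for i in self.instances],
                "cell_line": [i.cell_line for i in self.instances],
            }
        )


@dataclass
class DifferentialRanking:
    """Genes ordered from most up- to most down-regulated with log2 fold changes.

    Order is strict: descending log2FC, ties broken by gene id.
    """

    genes: np.ndarray  # ordered gene ids
    log2fc: np.ndarray  # matching log2 fold changes, descending

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.log2fc):
            raise ValidationError("genes and log2fc lengths differ")

    def __len__(self) -> int:
        return len(self.genes)

    def rank_of(self) -> dict[str, int]:
        return {g: i + 1 for i, g in enumerate(self.genes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "log2fc": self.log2fc,
                "rank": np.arange(1, len(self.genes) + 1),
            }
        )


@dataclass
class TagSignature:
    """Up- and down-regulated tag gene lists from a fold-change threshold.

    Both lists are ordered by decreasing |log2FC|. ``fold_threshold`` is on
    the linear scale (2.0 means |log2FC| >= 1).
    """

    up_genes: list[str]
    down_genes: list[str]
    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValidationError(f"genes in both tag lists: {sorted(overlap)[:5]}")

    @property
    def n_tags(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    def is_empty(self) -> bool:
        return self.n_tags == 0
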