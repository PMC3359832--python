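"""Signed Kolmogorov-Smirnov connectivity scoring.

The connectivity statistic asks whether a group of t tag genes clusters
near the top or the bottom of a reference ranking of N genes. With V(j)
the 1-based position of the j-th tag gene (positions sorted increasing),

    p = max_j [ j/t - V(j)/N ]        (excess above uniform -> top-loaded)
    n = max_j [ V(j)/N - (j-1)/t ]    (excess below uniform -> bottom-loaded)

and the signed statistic is p when p > n and -n when n > p. On the rare
tie p = n the positive branch is kept, which preserves the closed-form
value of top-extreme configurations for every group size.
Tag genes at the very top give 1 - t/N; at the very bottom,
-(N - t + 1)/N. A positive score against a reference instance means the
instance mimics the query perturbation; negative means it reverses it.

Per-pathway scoring restricts the instance ranking to the pathway's genes
(order preserved, positions renumbered 1..N) before computing the
statistic, so scores are comparable across pathways of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ReferenceInstance, TagSignature

__all__ = [
    "ks_statistic",
    "ConnectivityCell",
    "pathway_connectivity",
    "connectivity_significance",
    "PermutationNullCache",
]


def ks_statistic(positions, n_total: int) -> float:
    """Signed KS statistic of one tag group against a ranked list.

    Parameters
    ----------
    positions
        Strictly increasing 1-based positions of the t tag genes within
        the ranked list.
    n_total
        Length N of the ranked list.
    """
    v = np.asarray(positions, dtype=float)
    t = v.size
    if t == 0:
        raise ValueError("ks_statistic undefined for an empty tag group")
    if v.min() < 1 or v.max() > n_total:
        raise ValueError("positions must lie in [1, n_total]")
    if t > 1 and (np.diff(v) <= 0).any():
        raise ValueError("positions must be strictly increasing")
    j = np.arange(1, t + 1, dtype=float)
    p = np.max(j / t - v / n_total)
    n = np.max(v / n_total - (j - 1) / t)
    # exact p/n gaps are multiples of 1/(tN); the tolerance only absorbs
    # float rounding of true ties, which must take the positive branch
    return float(p) if p >= n - 1e-12 else float(-n)


def _ks_rows(v_sorted: np.ndarray, n_total: int) -> np.ndarray:
    """Vectorized signed KS over rows of sorted position matrices."""
    m, t = v_sorted.shape
    j = np.arange(1, t + 1, dtype=float)
    v = v_sorted.astype(float)
    p = (j / t - v / n_total).max(axis=1)
    n = (v / n_total - (j - 1) / t).max(axis=1)
    return np.where(p >= n - 1e-12, p, -n)


@dataclass
class ConnectivityCell:
    """Connectivity of one reference instance within one pathway."""

    instance_id: str
    pathway: str
    ks_up: float | None
    ks_down: float | None
    score: float
    n_list: int  # pathway-restricted list length N
    t_up: int
    t_down: int
    p_value: float | None = None


def _combine(ks_up: float | None, ks_down: float | None, halve: bool) -> float:
    """Classic two-list combination: zero when both lists load the same
    end of the ranking, otherwise their (optionally halved) difference."""
    if ks_up is None and ks_down is None:
        raise ValueError("both tag groups empty")
    if ks_up is None:
        return -ks_down
    if ks_down is None:
        return ks_up
    if ks_up * ks_down > 0:
        return 0.0
    score = ks_up - ks_down
    return score / 2 if halve else score


def _tag_positions(
    restricted_rank: dict[str, int], tags: list[str]
) -> np.ndarray:
    pos = sorted(restricted_rank[g] for g in tags if g in restricted_rank)
    return np.asarray(pos, dtype=np.int64)


def pathway_connectivity(
    sig: TagSignature,
    inst: ReferenceInstance,
    pathway_genes,
    pathway_name: str = "",
    mode: str = "combined",
    halve: bool = True,
) -> ConnectivityCell | None:
    """Score one instance against one tag signature within one pathway.

    The instance ranking is filtered to ``pathway_genes`` (order kept,
    positions renumbered 1..N). In ``combined`` mode the up- and down-tag
    groups are scored separately and combined (same sign -> 0, else the
    halved difference, so the score stays in [-1, 1]); a missing group
    contributes nothing and the remaining group's statistic is used alone,
    the down group with flipped sign. ``single_set`` mode scores the union
    of both groups as one list. Returns None when no tag gene falls in the
    pathway-restricted list.
    """
    pw = set(pathway_genes)
    restricted = [g for g in inst.order if g in pw]
    n = len(restricted)
    if n == 0:
        return None
    rank = {g: i + 1 for i, g in enumerate(restricted)}

    if mode == "single_set":
        v = _tag_positions(rank, sig.up_genes + sig.down_genes)
        if v.size == 0:
            return None
        score = ks_statistic(v, n)
        return ConnectivityCell(
            instance_id=inst.instance_id,
            pathway=pathway_name,
            ks_up=None,
            ks_down=None,
            score=score,
            n_list=n,
            t_up=v.size,
            t_down=0,
        )
    if mode != "combined":
        raise ValueError(f"unknown mode {mode!r}")

    v_up = _tag_positions(rank, sig.up_genes)
    v_dn = _tag_positions(rank, sig.down_genes)
    if v_up.size == 0 and v_dn.size == 0:
        return None
    ks_up = ks_statistic(v_up, n) if v_up.size else None
    ks_dn = ks_statistic(v_dn, n) if v_dn.size else None
    score = _combine(ks_up, ks_dn, halve)
    return ConnectivityCell(
        instance_id=inst.instance_id,
        pathway=pathway_name,
        ks_up=ks_up,
        ks_down=ks_dn,
        score=score,
        n_list=n,
        t_up=int(v_up.size),
        t_down=int(v_dn.size),
    )


class PermutationNullCache:
    """Null score distributions for permuted tag positions.

    Null scores depend only on the list length N and the tag group sizes,
    so they are computed once per (N, t_up, t_down, mode) and reused across
    cells. Each configuration gets its own generator derived from the base
    seed and the configuration itself, making p-values independent of the
    order in which cells are scored.
    """

    def __init__(self, seed: int, n_perm: int = 1000, halve: bool = True) -> None:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        self.seed = int(seed)
        self.n_perm = int(n_perm)
        self.halve = halve
        self._cache: dict[tuple, np.ndarray] = {}

    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *key])

    def single_group(self, n: int, t: int) -> np.ndarray:
        """|KS| null for one tag group of size t in a list of length N."""
        key = ("single", n, t)
        if key not in self._cache:
            rng = self._rng(1, n, t)
            u = rng.random((self.n_perm, n))
            pos = np.argpartition(u, t - 1, axis=1)[:, :t] + 1 if t < n else (
                np.tile(np.arange(1, n + 1), (self.n_perm, 1))
            )
            pos = np.sort(pos, axis=1)
            self._cache[key] = np.abs(_ks_rows(pos, n))
        return self._cache[key]

    def combined(self, n: int, t_up: int, t_down: int) -> np.ndarray:
        """|score| null for disjoint up/down groups of fixed sizes."""
        if t_up == 0 or t_down == 0:
            t = max(t_up, t_down)
            return self.single_group(n, t)
        key = ("combined", n, t_up, t_down)
        if key not in self._cache:
            rng = self._rng(2, n, t_up, t_down)
            u = rng.random((self.n_perm, n))
            perm = np.argsort(u, axis=1) + 1
            v_up = np.sort(perm[:, :t_up], axis=1)
            v_dn = np.sort(perm[:, t_up : t_up + t_down], axis=1)
            ks_up = _ks_rows(v_up, n)
            ks_dn = _ks_rows(v_dn, n)
            score = ks_up - ks_dn
            if self.halve:
                score = score / 2
            score[ks_up * ks_dn > 0] = 0.0
            self._cache[key] = np.abs(score)
        return self._cache[key]

    def p_value(self, cell: ConnectivityCell, mode: str = "combined") -> float:
        """Two-sided permutation p-value for one scored cell."""
        if mode == "combined":
            null = self.combined(cell.n_list, cell.t_up, cell.t_down)
        else:
            null = self.single_group(cell.n_list, cell.t_up + cell.t_down)
        hits = int(np.sum(null >= abs(cell.score) - 1e-12))
        return (1 + hits) / (self.n_perm + 1)


def connectivity_significance(
    cells: list[ConnectivityCell],
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "combined",
    halve: bool = True,
) -> list[ConnectivityCell]:
    """Attach permutation p-values to scored cells (in place, returned).

    The null permutes tag-gene positions uniformly within each cell's
    pathway-restricted list, preserving the tag group sizes; p uses the
    +1 correction so it is never exactly zero.
    """
    cache = PermutationNullCache(seed=seed, n_perm=n_perm, halve=halve)
    for cell in cells:
        cell.p_value = cache.p_value(cell, mode=mode)
    return cells
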