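import numpy as np
import pytest

from pbsc.containers import DifferentialRanking, PathwayCollection, TagSignature
from pbsc.enrichment import (
    hypergeometric_enrichment,
    ks_permutation_enrichment,
    select_pathways,
)


def ranking_of(genes, fcs=None):
    genes = np.asarray(genes, dtype=object)
    fcs = np.asarray(fcs if fcs is not None else np.linspace(3, -3, len(genes)))
    return DifferentialRanking(genes=genes, log2fc=fcs)


class TestHypergeometric:
    universe = [f"g{i}" for i in range(10)]

    def test_perfect_overlap_probability(self):
        # universe 10, DE 5, pathway 5, overlap 5 -> p = 1 / C(10,5) = 1/252
        sig = TagSignature(up_genes=self.universe[:3], down_genes=self.universe[3:5])
        pw = PathwayCollection({"pw": frozenset(self.universe[:5])})
        (res,) = hypergeometric_enrichment(sig, pw, self.universe)
        assert res.p_value == pytest.approx(1 / 252)
        assert res.n_de_in_pathway == 5

    def test_zero_overlap_p_is_one(self):
        sig = TagSignature(up_genes=self.universe[:5], down_genes=[])
        pw = PathwayCollection({"pw": frozenset(self.universe[5:])})
        (res,) = hypergeometric_enrichment(sig, pw, self.universe)
        assert res.p_value == pytest.approx(1.0)

    def test_pathway_disjoint_from_universe_skipped(self):
        sig = TagSignature(up_genes=self.universe[:2], down_genes=[])
        pw = PathwayCollection({"pw": frozenset({"zz1", "zz2"})})
        assert hypergeometric_enrichment(sig, pw, self.universe) == []

    def test_empty_de_set_warns_and_p_one(self, caplog):
        sig = TagSignature(up_genes=[], down_genes=[])
        pw = PathwayCollection({"pw": frozenset(self.universe[:4])})
        with caplog.at_level("WARNING"):
            (res,) = hypergeometric_enrichment(sig, pw, self.universe)
        assert res.p_value == 1.0


class TestKsPermutation:
    def test_top_loaded_pathway_minimal_p(self):
        genes = [f"g{i:03d}" for i in range(100)]
        r = ranking_of(genes)
        pw = PathwayCollection({"pw": frozenset(genes[:10])})
        (res,) = ks_permutation_enrichment(r, pw, n_perm=200, seed=0)
        assert res.statistic == pytest.approx(1 - 10 / 100)
        assert res.p_value == pytest.approx(1 / 201)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:03d}" for i in range(80)]
        pw = PathwayCollection({"pw": frozenset(rng.choice(genes, 12, replace=False))})
        r = ranking_of(list(rng.permutation(genes)))
        a = ks_permutation_enrichment(r, pw, n_perm=150, seed=5)
        b = ks_permutation_enrichment(r, pw, n_perm=150, seed=5)
        assert a[0].p_value == b[0].p_value

    def test_invariant_to_relabeling_outside_pathway(self):
        genes = [f"g{i:03d}" for i in range(60)]
        member = set(genes[10:20])
        r1 = ranking_of(genes)
        relabeled = [g if g in member else f"x_{g}" for g in genes]
        r2 = ranking_of(relabeled)
        pw = PathwayCollection({"pw": frozenset(member)})
        a = ks_permutation_enrichment(r1, pw, n_perm=200, seed=3)
        b = ks_permutation_enrichment(r2, pw, n_perm=200, seed=3)
        assert a[0].statistic == b[0].statistic
        assert a[0].p_value == b[0].p_value

    def test_unmeasured_pathway_skipped(self):
        r = ranking_of(["g1", "g2"])
        pw = PathwayCollection({"pw": frozenset({"zz"})})
        assert ks_permutation_enrichment(r, pw, n_perm=100, seed=0) == []


class TestSelectPathways:
    def make(self, pvals):
        pw = PathwayCollection(
            {f"pw{i}": frozenset({f"g{i}"}) for i in range(len(pvals))}
        )
        sig = TagSignature(up_genes=[], down_genes=[])
        from pbsc.enrichment import EnrichmentResult

        res = [
            EnrichmentResult(f"pw{i}", "test", 0.0, p, 1, 0)
            for i, p in enumerate(pvals)
        ]
        return res, pw

    def test_strict_inequality(self):
        res, pw = self.make([0.01, 0.05, 0.2])
        sel = select_pathways(res, pw, alpha=0.05)
        assert sel.names() == ["pw0"]

    def test_empty_input(self):
        assert len(select_pathways([], PathwayCollection(), alpha=0.05)) == 0

    def test_alpha_one_selects_all(self):
        res, pw = self.make([0.3, 1.0, 0.9])
        assert len(select_pathways(res, pw, alpha=1.0)) == 3

    def test_alpha_zero_selects_none(self):
        res, pw = self.make([0.001, 0.5])
        assert len(select_pathways(res, pw, alpha=0.0)) == 0

    def test_monotone_in_alpha_and_subset(self):
        res, pw = self.make([0.01, 0.03, 0.04, 0.2, 0.6])
        tight = set(select_pathways(res, pw, alpha=0.02).names())
        loose = set(select_pathways(res, pw, alpha=0.3).names())
        assert tight <= loose <= set(pw.names())

    def test_order_preserved(self):
        res, pw = self.make([0.01, 0.5, 0.02])
        assert select_pathways(res, pw, alpha=0.05).names() == ["pw0", "pw2"]

    def test_fdr_gate_more_conservative(self):
        res, pw = self.make([0.01, 0.02, 0.03, 0.04, 0.9])
        raw = select_pathways(res, pw, alpha=0.05)
        adj = select_pathways(res, pw, alpha=0.05, fdr=True)
        assert set(adj.names()) <= set(raw.names())


def test_null_type_one_error_hypergeometric_small():
    """Sanity-scale calibration: null DE draws reject near or below alpha."""
    rng = np.random.default_rng(21)
    genes = np.array([f"g{i:04d}" for i in range(1000)])
    pw = PathwayCollection(
        {
            f"pw{i}": frozenset(rng.choice(genes, int(rng.integers(50, 150)), replace=False))
            for i in range(100)
        }
    )
    hits = total = 0
    for _ in range(5):
        de = rng.choice(genes, 200, replace=False)
        sig = TagSignature(up_genes=list(de[:100]), down_genes=list(de[100:]))
        for res in hypergeometric_enrichment(sig, pw, genes):
            hits += res.p_value < 0.05
            total += 1
    assert hits / total < 0.09  # never anti-conservative
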