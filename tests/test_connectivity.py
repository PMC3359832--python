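"""The signed KS statistic and per-pathway scoring, checked against a
literal brute-force oracle and its closed-form extremes."""

import numpy as np
import pytest

from conftest import make_instance
from pbsc.connectivity import (
    PermutationNullCache,
    connectivity_significance,
    ks_statistic,
    pathway_connectivity,
)
from pbsc.containers import TagSignature


def ks_oracle(positions, n_total):
    """Direct double-loop transcription of the statistic's definition
    (ties keep the positive branch)."""
    t = len(positions)
    p = max(
        (j + 1) / t - positions[j] / n_total for j in range(t)
    )
    n = max(
        positions[j] / n_total - j / t for j in range(t)
    )
    return p if p >= n - 1e-12 else -n


class TestKsStatistic:
    def test_top_loaded_closed_form(self):
        assert ks_statistic([1, 2, 3], 10) == pytest.approx(1 - 3 / 10)

    def test_bottom_loaded_closed_form(self):
        assert ks_statistic([8, 9, 10], 10) == pytest.approx(-(10 - 3 + 1) / 10)

    def test_worked_example(self):
        # N=10, t=3, V=(1,2,8): p = max(.2333, .4667, .2) wins over n
        assert ks_statistic([1, 2, 8], 10) == pytest.approx(0.46666666666666)

    def test_matches_oracle_on_random_cases(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            n = int(rng.integers(2, 51))
            t = int(rng.integers(1, n + 1))
            v = np.sort(rng.choice(np.arange(1, n + 1), size=t, replace=False))
            assert ks_statistic(v, n) == pytest.approx(ks_oracle(list(v), n), abs=0)

    def test_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            t = int(rng.integers(1, n + 1))
            v = np.sort(rng.choice(np.arange(1, n + 1), size=t, replace=False))
            assert -1 <= ks_statistic(v, n) <= 1

    @pytest.mark.parametrize(
        "positions, n",
        [([], 5), ([0, 1], 5), ([1, 6], 5), ([2, 2], 5), ([3, 1], 5)],
    )
    def test_invalid_inputs(self, positions, n):
        with pytest.raises(ValueError):
            ks_statistic(positions, n)


class TestPathwayConnectivity:
    pathway = {"a", "b", "c", "d", "e", "f"}

    def test_mimicry_positive(self):
        inst = make_instance("i", ["a", "b", "c", "d", "e", "f", "x"])
        sig = TagSignature(up_genes=["a", "b"], down_genes=["e", "f"])
        cell = pathway_connectivity(sig, inst, self.pathway, "pw")
        assert cell.ks_up > 0 and cell.ks_down < 0
        assert cell.score > 0.5

    def test_same_sign_groups_score_zero(self):
        inst = make_instance("i", ["a", "b", "c", "d", "e", "f"])
        sig = TagSignature(up_genes=["a"], down_genes=["b"])
        cell = pathway_connectivity(sig, inst, self.pathway, "pw")
        assert cell.score == 0.0

    def test_single_group_uses_flipped_down_sign(self):
        inst = make_instance("i", ["a", "b", "c", "d", "e", "f"])
        sig = TagSignature(up_genes=[], down_genes=["a", "b"])  # down at top
        cell = pathway_connectivity(sig, inst, self.pathway, "pw")
        assert cell.score == pytest.approx(-cell.ks_down)
        assert cell.score < 0  # down-tags at the top mean reversal... of reversal

    def test_no_tags_in_pathway_skipped(self):
        inst = make_instance("i", ["a", "b"])
        sig = TagSignature(up_genes=["zz"], down_genes=[])
        assert pathway_connectivity(sig, inst, {"a", "b"}, "pw") is None

    def test_reversed_instance_negates_score(self):
        """Reversing the ranking maps (p, n) -> (n - 1/N, p + 1/N), so the
        combined score negates exactly whenever neither group's branch
        margin |p - n| falls within 2/N of the flip boundary."""

        def margins(sig_genes, order):
            pos = sorted(order.index(g) + 1 for g in sig_genes)
            t, n = len(pos), len(order)
            j = np.arange(1, t + 1)
            v = np.asarray(pos, float)
            return abs((j / t - v / n).max() - (v / n - (j - 1) / t).max())

        rng = np.random.default_rng(77)
        genes = [f"g{i}" for i in range(30)]
        checked = 0
        for _ in range(60):
            order = list(rng.permutation(genes))
            up = list(rng.choice(genes, 4, replace=False))
            down = [g for g in rng.choice(genes, 8, replace=False) if g not in up][:3]
            if min(margins(up, order), margins(down, order)) <= 2 / len(genes):
                continue
            sig = TagSignature(up_genes=up, down_genes=down)
            fwd = pathway_connectivity(sig, make_instance("f", order), set(genes), "pw")
            rev = pathway_connectivity(
                sig, make_instance("r", order[::-1]), set(genes), "pw"
            )
            if fwd.score != 0 and abs(fwd.score) > 1 / len(genes):
                assert rev.score == pytest.approx(-fwd.score, abs=1e-12)
                checked += 1
        assert checked >= 10

    def test_halving_keeps_score_in_unit_interval(self):
        inst = make_instance("i", ["a", "b", "c", "d", "e", "f"])
        sig = TagSignature(up_genes=["a"], down_genes=["f"])
        halved = pathway_connectivity(sig, inst, self.pathway, "pw", halve=True)
        full = pathway_connectivity(sig, inst, self.pathway, "pw", halve=False)
        assert full.score == pytest.approx(2 * halved.score)
        assert -1 <= halved.score <= 1

    def test_single_set_mode(self):
        inst = make_instance("i", ["a", "b", "c", "d", "e", "f"])
        sig = TagSignature(up_genes=["a"], down_genes=["b"])
        cell = pathway_connectivity(sig, inst, self.pathway, "pw", mode="single_set")
        assert cell.score == pytest.approx(ks_statistic([1, 2], 6))


class TestSignificance:
    def test_extreme_configuration_gets_minimal_p(self):
        genes = [f"g{i:02d}" for i in range(20)]
        inst = make_instance("i", genes)
        sig = TagSignature(up_genes=genes[:3], down_genes=genes[-3:])
        cell = pathway_connectivity(sig, inst, set(genes), "pw")
        connectivity_significance([cell], n_perm=200, seed=1)
        assert cell.p_value == pytest.approx(1 / 201)

    def test_same_seed_identical_p(self):
        genes = [f"g{i:02d}" for i in range(15)]
        inst = make_instance("i", genes)
        sig = TagSignature(up_genes=[genes[4], genes[9]], down_genes=[genes[2]])
        p = []
        for _ in range(2):
            cell = pathway_connectivity(sig, inst, set(genes), "pw")
            connectivity_significance([cell], n_perm=200, seed=42)
            p.append(cell.p_value)
        assert p[0] == p[1]

    def test_random_tags_give_roughly_uniform_p(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:02d}" for i in range(40)]
        cache = PermutationNullCache(seed=3, n_perm=500)
        pvals = []
        for _ in range(300):
            order = list(rng.permutation(genes))
            inst = make_instance("i", order)
            up = list(rng.choice(genes, 5, replace=False))
            down = [g for g in genes if g not in up][:5]
            cell = pathway_connectivity(
                TagSignature(up_genes=up, down_genes=down), inst, set(genes), "pw"
            )
            pvals.append(cache.p_value(cell))
        assert abs(np.mean(np.array(pvals) < 0.25) - 0.25) < 0.08
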