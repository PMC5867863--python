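import numpy as np
import pandas as pd
import pytest

from lncweanflow.cis import (
    CisPair,
    call_cis_targets,
    cis_table,
    degree_summaries,
    edge_list,
    find_candidate_pairs,
    pearson_test,
    span_distance,
)
from lncweanflow.simulate import SimulationConfig, simulate_cis_expression

from .conftest import make_annotation, make_tx, random_exon_chain
from .oracles import pairs_brute_force


class TestCandidatePairs:
    def test_boundary_distance_inclusive(self):
        lnc = make_annotation(make_tx("l1", [(1_000, 2_000)], gene_id="L1"))
        mrna = make_annotation(make_tx("m1", [(52_000, 53_000)], gene_id="M1"))
        pairs = find_candidate_pairs(lnc, mrna, window=50_000)
        assert pairs == [("L1", "M1", 50_000)]

    def test_one_past_boundary_excluded(self):
        lnc = make_annotation(make_tx("l1", [(1_000, 2_000)], gene_id="L1"))
        mrna = make_annotation(make_tx("m1", [(52_001, 53_000)], gene_id="M1"))
        assert find_candidate_pairs(lnc, mrna, window=50_000) == []

    def test_different_chromosome_excluded(self):
        lnc = make_annotation(make_tx("l1", [(1_000, 2_000)], gene_id="L1"))
        mrna = make_annotation(make_tx("m1", [(1_000, 2_000)], chrom="chr2", gene_id="M1"))
        assert find_candidate_pairs(lnc, mrna) == []

    def test_overlap_has_distance_zero(self):
        lnc = make_annotation(make_tx("l1", [(1_000, 2_000)], gene_id="L1"))
        mrna = make_annotation(make_tx("m1", [(1_500, 2_500)], gene_id="M1"))
        assert find_candidate_pairs(lnc, mrna) == [("L1", "M1", 0)]

    def test_random_annotations_match_brute_force(self, rng):
        for _ in range(25):
            lncs, mrnas = [], []
            for i in range(15):
                chrom = f"chr{rng.integers(1, 3)}"
                lncs.append(make_tx(f"l{i}", [(e.start, e.end) for e in random_exon_chain(rng, chrom, 1_000, 200_000)], chrom=chrom, gene_id=f"L{i}"))
            for i in range(15):
                chrom = f"chr{rng.integers(1, 3)}"
                mrnas.append(make_tx(f"m{i}", [(e.start, e.end) for e in random_exon_chain(rng, chrom, 1_000, 200_000)], chrom=chrom, gene_id=f"M{i}"))
            window = int(rng.integers(1_000, 80_000))
            got = {
                (l, m): d
                for l, m, d in find_candidate_pairs(
                    make_annotation(*lncs), make_annotation(*mrnas), window
                )
            }
            expected = pairs_brute_force(
                {t.gene_id: (t.chrom, *t.span) for t in lncs},
                {t.gene_id: (t.chrom, *t.span) for t in mrnas},
                window,
            )
            assert got == expected

    def test_widening_window_never_removes_pairs(self, rng):
        lncs = [make_tx(f"l{i}", [(e.start, e.end) for e in random_exon_chain(rng, "chr1", 1_000, 300_000)], gene_id=f"L{i}") for i in range(10)]
        mrnas = [make_tx(f"m{i}", [(e.start, e.end) for e in random_exon_chain(rng, "chr1", 1_000, 300_000)], gene_id=f"M{i}") for i in range(10)]
        la, ma = make_annotation(*lncs), make_annotation(*mrnas)
        narrow = {(l, m) for l, m, _ in find_candidate_pairs(la, ma, 20_000)}
        wide = {(l, m) for l, m, _ in find_candidate_pairs(la, ma, 60_000)}
        assert narrow <= wide


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2, 3, 4])
        r, p = pearson_test(x, x)
        assert r == pytest.approx(1.0)

    def test_hand_computed_three_points(self):
        r, p = pearson_test([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.9820, abs=5e-5)

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r_xy, _ = pearson_test(x, y)
        r_yx, _ = pearson_test(y, x)
        r_aff, _ = pearson_test(3.0 * x + 7.0, y)
        assert r_yx == pytest.approx(r_xy)
        assert r_aff == pytest.approx(r_xy)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant_expression"):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_rejection_rate(self, rng):
        # two-sided t test on df=n-2 holds its level under independence
        n_reps, n = 2000, 32
        rejections = 0
        for _ in range(n_reps):
            _, p = pearson_test(rng.normal(size=n), rng.normal(size=n))
            rejections += p < 0.05
        assert 0.035 <= rejections / n_reps <= 0.065


class TestCallCisTargets:
    def _expr(self, rows, index):
        return pd.DataFrame(rows, index=index, columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_single_pair_bh_is_identity(self, rng):
        x = rng.normal(size=10)
        y = x + rng.normal(scale=0.1, size=10)
        lnc = self._expr([np.exp(x)], ["L1"])
        mrna = self._expr([np.exp(y)], ["M1"])
        res = call_cis_targets([("L1", "M1", 0)], lnc, mrna)
        assert len(res) == 1
        assert res[0].p_bh == pytest.approx(res[0].p)
        assert res[0].is_cis_target

    def test_missing_feature_dropped(self, rng):
        lnc = self._expr([rng.normal(size=8) ** 2], ["L1"])
        mrna = self._expr([rng.normal(size=8) ** 2], ["M1"])
        res = call_cis_targets([("L1", "M1", 0), ("L2", "M1", 5)], lnc, mrna)
        assert len(res) == 1

    def test_degree_summaries_conserve_edges(self, rng):
        pairs, lnc, mrna, planted = simulate_cis_expression(
            SimulationConfig(seed=3), n_planted=30, n_null=60, n_samples=24
        )
        res = call_cis_targets(pairs, lnc, mrna)
        n_sig = sum(c.is_cis_target for c in res)
        by_lnc, by_gene = degree_summaries(res)
        assert by_lnc.sum() == n_sig
        assert by_gene.sum() == n_sig
        assert len(edge_list(res)) == n_sig

    def test_planted_pairs_recovered(self):
        pairs, lnc, mrna, planted = simulate_cis_expression(
            SimulationConfig(seed=9), n_planted=40, n_null=400, n_samples=32
        )
        res = call_cis_targets(pairs, lnc, mrna)
        called = {(c.lncrna_id, c.mrna_gene_id) for c in res if c.is_cis_target}
        tp = len(called & planted)
        assert tp / len(planted) >= 0.9
        assert (len(called) - tp) / max(1, len(called)) <= 0.1

    def test_expr_scale_validated(self, rng):
        lnc = self._expr([rng.normal(size=8) ** 2], ["L1"])
        with pytest.raises(ValueError, match="expr_scale"):
            call_cis_targets([("L1", "L1", 0)], lnc, lnc, expr_scale="sqrt")

    def test_table_mirrors_results(self, rng):
        pairs, lnc, mrna, _ = simulate_cis_expression(
            SimulationConfig(seed=4), n_planted=5, n_null=10, n_samples=16
        )
        res = call_cis_targets(pairs, lnc, mrna)
        tab = cis_table(res)
        assert list(tab.columns) == [
            "lncrna_id", "mrna_gene_id", "distance_bp", "Cor", "p", "p.BH", "is_cis_target",
        ]
        assert len(tab) == len(res)


def test_span_distance_cases():
    assert span_distance((10, 20), (15, 30)) == 0
    assert span_distance((10, 20), (25, 30)) == 5
    assert span_distance((25, 30), (10, 20)) == 5
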