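import numpy as np
import pytest

from lncweanflow.annotation_io import Annotation
from lncweanflow.coding import GateThresholds
from lncweanflow.discovery import (
    FILTER_ORDER,
    POSITIONAL_CLASSES,
    candidate_table,
    characterize,
    discover,
    positional_classify,
    retained_annotation,
)
from lncweanflow.simulate import SimulationConfig, simulate_annotation

from .conftest import make_annotation, make_tx


def run_discover(synthetic, **kwargs):
    return discover(
        synthetic.assembled,
        synthetic.reference,
        synthetic.known_lnc,
        synthetic.sequences,
        blast=synthetic.blast_hits,
        **kwargs,
    )


@pytest.fixture(scope="module")
def cascade(synthetic_module):
    return run_discover(synthetic_module)


@pytest.fixture(scope="module")
def synthetic_module():
    return simulate_annotation(SimulationConfig(seed=11))


class TestCascade:
    def test_length_filter_is_strict(self):
        # a 200 bp intergenic transcript is removed, a 201 bp one kept
        ref = make_annotation(make_tx("r", [(100_000, 101_000)], gene_id="rg", biotype="protein_coding"))
        known = Annotation()
        short = make_tx("t200", [(1_000, 1_199)])
        keep = make_tx("t201", [(5_000, 5_200)])
        asm = make_annotation(short, keep)
        seqs = {"t200": "A" * 200, "t201": "ACGT" * 50 + "A"}
        cands = {c.transcript.transcript_id: c for c in discover(asm, ref, known, seqs)}
        assert cands["t200"].filter_trace[0] == ("length", "fail")
        assert not cands["t200"].retained
        assert cands["t201"].retained
        assert cands["t201"].known is False

    def test_filter_trace_matches_generator_manifest(self, cascade, synthetic_module):
        manifest = synthetic_module.manifest
        outcome = {}
        for c in cascade:
            tid = c.transcript.transcript_id
            if c.retained:
                outcome[tid] = "retained"
            else:
                name, verdict = next(
                    (n, v) for n, v in c.filter_trace if v.startswith("fail")
                )
                outcome[tid] = f"fail:{name}"
        assert outcome == manifest.expected_outcome

    def test_known_flags_match_manifest(self, cascade, synthetic_module):
        known_ids = set(synthetic_module.manifest.known_ids)
        for c in cascade:
            if c.retained:
                assert c.known == (c.transcript.transcript_id in known_ids)

    def test_cascade_order_faithful(self, cascade):
        for c in cascade:
            names = [n for n, _ in c.filter_trace]
            assert names == list(FILTER_ORDER)[: len(names)]
            seen_fail = False
            for _, verdict in c.filter_trace:
                if seen_fail:
                    assert verdict == "not_evaluated"
                if verdict.startswith("fail"):
                    seen_fail = True

    def test_known_novel_partition(self, cascade):
        kept = [c for c in cascade if c.retained]
        assert all(c.known in (True, False) for c in kept)
        assert all(c.positional_class in POSITIONAL_CLASSES for c in kept)

    def test_missing_sequence_fails_gate_with_reason(self, synthetic_module):
        seqs = dict(synthetic_module.sequences)
        survivor = synthetic_module.manifest.known_ids[0]
        del seqs[survivor]
        cands = discover(
            synthetic_module.assembled,
            synthetic_module.reference,
            synthetic_module.known_lnc,
            seqs,
            blast=synthetic_module.blast_hits,
        )
        c = next(x for x in cands if x.transcript.transcript_id == survivor)
        assert ("coding_gate", "fail:no_sequence") in c.filter_trace

    def test_survivors_monotone_in_thresholds(self, synthetic_module):
        base = sum(c.retained for c in run_discover(synthetic_module))
        stricter_len = sum(
            c.retained for c in run_discover(synthetic_module, min_length=700)
        )
        stricter_pep = sum(
            c.retained
            for c in run_discover(synthetic_module, thresholds=GateThresholds(peptide=40))
        )
        assert stricter_len <= base
        assert stricter_pep <= base


class TestPositionalClassify:
    def _pc_ref(self):
        return make_annotation(
            make_tx("m1", [(100_000, 100_500), (102_000, 102_500), (104_000, 104_500)],
                    "+", gene_id="G1", biotype="protein_coding")
        )

    def test_intergenic_beyond_1kb(self):
        ref = self._pc_ref()
        lnc = make_tx("l", [(105_502, 105_900)], "+")  # 1,001 bp past gene end
        assert positional_classify(lnc, ref) == "intergenic_same"

    def test_near_gene_within_1kb_downstream_of_plus_lnc(self):
        ref = self._pc_ref()
        lnc = make_tx("l", [(105_000, 105_400)], "+")  # 499 bp gap, gene upstream... lnc's left
        # gene lies on the lnc's upstream (left) side for a + lnc
        assert positional_classify(lnc, ref) == "intergenic_upstream_1kb"

    def test_divergent_head_to_head_is_bidirectional_promoter(self):
        ref = self._pc_ref()  # gene on + starting at 100,000
        lnc = make_tx("l", [(99_200, 99_600)], "-")  # 5' ends face, gap < 1 kb
        assert positional_classify(lnc, ref) == "bidirectional_promoter"

    def test_sense_intronic(self):
        ref = self._pc_ref()
        lnc = make_tx("l", [(100_700, 101_200)], "+")
        assert positional_classify(lnc, ref) == "sense_intronic"

    def test_antisense_intronic(self):
        ref = self._pc_ref()
        lnc = make_tx("l", [(100_700, 101_200)], "-")
        assert positional_classify(lnc, ref) == "antisense_intronic"

    def test_antisense_exonic(self):
        ref = self._pc_ref()
        lnc = make_tx("l", [(100_200, 100_800)], "-")
        assert positional_classify(lnc, ref) == "antisense_exonic"

    def test_containing_gene(self):
        ref = self._pc_ref()
        lnc = make_tx("l", [(99_000, 105_000)], "+")
        assert positional_classify(lnc, ref) == "containing_gene"

    def test_random_placements_against_rule_oracle(self, rng):
        # distance-based rules: a disjoint lncRNA >1 kb away lands in an
        # intergenic class whose orientation matches first principles
        ref = self._pc_ref()
        gene_span = (100_000, 104_500)
        for _ in range(300):
            strand = str(rng.choice(["+", "-"]))
            if rng.random() < 0.5:
                start = int(rng.integers(106_000, 150_000))
            else:
                start = int(rng.integers(10_000, 98_000))
            lnc = make_tx("l", [(start, start + 300)], strand)
            got = positional_classify(lnc, ref)
            s, e = lnc.span
            gap = max(gene_span[0] - e, s - gene_span[1], 0)
            if gap > 1_000:
                left_strand, right_strand = (strand, "+") if e < gene_span[0] else ("+", strand)
                if left_strand == right_strand:
                    expected = "intergenic_same"
                elif (left_strand, right_strand) == ("-", "+"):
                    expected = "intergenic_divergent"
                else:
                    expected = "intergenic_convergent"
                assert got == expected
            else:
                assert got in (
                    "intergenic_upstream_1kb",
                    "intergenic_downstream_1kb",
                    "bidirectional_promoter",
                )


class TestCharacterize:
    def test_single_transcript_bins(self, synthetic_module):
        cands = run_discover(synthetic_module)
        kept = [c for c in cands if c.retained]
        summaries = characterize(cands)
        assert summaries["length_bins"].sum() == len(kept)
        assert summaries["exons_per_transcript"].sum() == len(kept)
        assert summaries["per_chromosome"].sum() == len(kept)

    def test_empty_set_gives_empty_summary(self):
        summaries = characterize([])
        assert all(len(v) == 0 for v in summaries.values())

    def test_length_bin_edges(self):
        ref = make_annotation(make_tx("r", [(500_000, 500_100)], gene_id="rg", biotype="protein_coding"))
        lnc = make_tx("t1", [(1_000, 1_499)])  # 500 bp
        asm = make_annotation(lnc)
        cands = discover(asm, ref, Annotation(), {"t1": "ACGT" * 125})
        bins = characterize(cands)["length_bins"]
        assert bins["200-999"] == 1
        assert bins.drop("200-999").sum() == 0


class TestOutputs:
    def test_candidate_table_covers_all_inputs(self, cascade):
        tab = candidate_table(cascade)
        assert len(tab) == len(cascade)
        assert set(tab["retained"]) <= {True, False}

    def test_retained_annotation_round_trips(self, cascade, tmp_path):
        from lncweanflow.annotation_io import read_gtf, write_gtf

        ann = retained_annotation(cascade)
        write_gtf(ann, tmp_path / "kept.gtf")
        back = read_gtf(tmp_path / "kept.gtf")
        assert set(back.genes) == set(ann.genes)
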