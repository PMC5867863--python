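import math

import numpy as np
import pytest

from lncweanflow.coding import (
    ORF,
    CodingPotential,
    GateThresholds,
    LogisticCombiner,
    coding_gate,
    fickett_score,
    fickett_score_range,
    find_longest_orf,
    fit_logistic_combiner,
    gate_failures,
    hexamer_llr,
    read_blast_tab,
)
from lncweanflow.simulate import (
    SimulationConfig,
    hexamer_table_from_seqs,
    sample_hexamer_markov,
    training_corpus,
)

from .oracles import orf_brute_force


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq, expected_len",
        [
            ("ATGTAA", 1),
            ("ATGAAATAA", 2),
            ("CCCCCCCC", 0),  # no ATG
            ("", 0),
            ("ATGAAAAAA", 3),  # open-ended, counts to sequence end
        ],
    )
    def test_known_cases(self, seq, expected_len):
        assert find_longest_orf(seq).peptide_len == expected_len

    def test_matches_brute_force_on_random_sequences(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(rng.choice(bases, size=1000))
            got = find_longest_orf(seq, "+")
            exp_len, exp_start = orf_brute_force(seq)
            assert got.peptide_len == exp_len
            if exp_len:
                assert got.start_offset == exp_start

    def test_both_strands_takes_maximum(self):
        # ORF only on the reverse complement
        seq = "TTACATTTTTTTTT"[::-1].translate(str.maketrans("ACGT", "TGCA"))
        fwd = find_longest_orf(seq, "+")
        both = find_longest_orf(seq, "both")
        assert both.peptide_len >= fwd.peptide_len


class TestFickett:
    def test_poly_a_frozen_value(self):
        # hand evaluation of the lookup tables: every parameter falls in
        # its terminal bucket except A-content (1.0 -> first bucket)
        assert fickett_score("A" * 300) == pytest.approx(0.4144, abs=1e-10)

    def test_deterministic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        assert fickett_score(seq) == fickett_score(seq)

    def test_random_scores_within_table_bounds(self, rng):
        lo, hi = fickett_score_range()
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(200, 800))))
            assert lo <= fickett_score(seq) <= hi

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fickett_score("ACGTA")


class TestHexamerLlr:
    def test_identical_tables_score_zero(self, rng):
        table = np.full(4096, 1.0 / 4096)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert hexamer_llr(seq, table, table) == pytest.approx(0.0, abs=1e-12)

    def test_two_hexamer_toy_example(self):
        seq = "ACGTACG"  # hexamers ACGTAC, CGTACG
        coding = {"ACGTAC": 0.6, "CGTACG": 0.4}
        noncoding = {"ACGTAC": 0.3, "CGTACG": 0.7}
        eps = 1e-9
        expected = 0.5 * (
            math.log((0.6 + eps) / (0.3 + eps)) + math.log((0.4 + eps) / (0.7 + eps))
        )
        assert hexamer_llr(seq, coding, noncoding) == pytest.approx(expected, rel=1e-12)

    def test_short_sequence_scores_zero(self):
        table = np.full(4096, 1.0 / 4096)
        assert hexamer_llr("ACGTA", table, table) == 0.0

    def test_unnormalized_table_rejected(self):
        bad = np.full(4096, 1.0)
        good = np.full(4096, 1.0 / 4096)
        with pytest.raises(ValueError, match="normalized"):
            hexamer_llr("ACGTACGT", bad, good)

    def test_markov_samples_score_higher_under_own_table(self, rng):
        cfg = SimulationConfig(seed=7, train_corpus_per_class=60)
        corpus = training_corpus(cfg, rng)
        coding = hexamer_table_from_seqs(s for s, y in corpus if y == 1)
        noncoding = hexamer_table_from_seqs(s for s, y in corpus if y == 0)
        coding_scores, noncoding_scores = [], []
        for _ in range(100):
            coding_scores.append(
                hexamer_llr(sample_hexamer_markov(coding, 200, rng), coding, noncoding)
            )
            noncoding_scores.append(
                hexamer_llr(sample_hexamer_markov(noncoding, 200, rng), coding, noncoding)
            )
        assert np.mean(coding_scores) > np.mean(noncoding_scores)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestLogisticCombiner:
    def test_zero_coefficients_give_half(self):
        combiner = LogisticCombiner(np.zeros(5))
        assert combiner.score((5.0, 0.2, 0.7, -1.0)) == pytest.approx(0.5)

    def test_separable_toy_set_perfect_training_accuracy(self):
        rows = [((float(i), 0.0, 0.0, 0.0), int(i > 5)) for i in range(11) if i != 5]
        combiner = fit_logistic_combiner(rows)
        for feats, label in rows:
            assert (combiner.score(feats) > 0.5) == bool(label)

    def test_recovers_planted_coefficients_within_two_se(self):
        rng = np.random.default_rng(42)
        n = 2000
        beta = np.array([-0.1, 0.3, -0.5, 0.8, 0.2])  # intercept first
        X = rng.normal(size=(n, 4))
        p = _sigmoid(beta[0] + X @ beta[1:])
        y = rng.random(n) < p
        combiner = fit_logistic_combiner(list(zip(X, y.astype(int))))
        # asymptotic SEs from the Fisher information at the fit
        X1 = np.column_stack([np.ones(n), X])
        phat = _sigmoid(X1 @ combiner.coef)
        cov = np.linalg.inv(X1.T @ (X1 * (phat * (1 - phat))[:, None]))
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(combiner.coef - beta) <= 2 * se)

    def test_synthetic_corpus_held_out_accuracy(self):
        from lncweanflow.coding import score_transcript

        cfg = SimulationConfig(seed=13, train_corpus_per_class=500)
        rng = np.random.default_rng(13)
        corpus = training_corpus(cfg, rng)  # alternates noncoding/coding
        half = len(corpus) // 2
        train, test = corpus[:half], corpus[half:]
        coding = hexamer_table_from_seqs(s for s, y in train if y == 1)
        noncoding = hexamer_table_from_seqs(s for s, y in train if y == 0)
        zero = LogisticCombiner(np.zeros(5))

        def feats(seq):
            cp = score_transcript("t", seq, coding, noncoding, zero, "+")
            return (cp.orf.peptide_len, 3.0 * cp.orf.peptide_len / len(seq), cp.fickett, cp.hexamer_llr)

        combiner = fit_logistic_combiner([(feats(s), y) for s, y in train])
        correct = sum((combiner.score(feats(s)) > 0.5) == bool(y) for s, y in test)
        assert correct / len(test) >= 0.9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_combiner([((1.0, 0, 0, 0), 1), ((2.0, 0, 0, 0), 1)])


def _random_cp(rng, tid="t"):
    return CodingPotential(
        transcript_id=tid,
        orf=ORF(peptide_len=int(rng.integers(0, 200))),
        combined_prob=float(rng.random()),
        cnci_score=float(rng.normal()) if rng.random() < 0.7 else None,
        cpat_score=float(rng.random()) if rng.random() < 0.7 else None,
        min_evalue=float(10.0 ** rng.uniform(-20, 0)) if rng.random() < 0.7 else None,
    )


class TestCodingGate:
    def test_peptide_at_threshold_discarded(self):
        cp = CodingPotential("t", orf=ORF(peptide_len=100), combined_prob=0.1)
        assert coding_gate(cp) == "discard_coding"

    def test_combined_prob_just_below_threshold_retained(self):
        cp = CodingPotential("t", orf=ORF(peptide_len=10), combined_prob=0.49)
        assert coding_gate(cp) == "retain_noncoding"

    def test_external_cpat_governs_over_combined(self):
        cp = CodingPotential(
            "t", orf=ORF(peptide_len=10), combined_prob=0.9, cpat_score=0.1
        )
        assert coding_gate(cp) == "retain_noncoding"

    def test_thousand_random_records_match_conjunction_oracle(self, rng):
        th = GateThresholds()
        for i in range(1000):
            cp = _random_cp(rng, f"t{i}")
            discard = (
                (cp.cnci_score is not None and cp.cnci_score >= th.cnci)
                or (
                    cp.cpat_score >= th.cpat
                    if cp.cpat_score is not None
                    else cp.combined_prob >= th.cpat
                )
                or (cp.min_evalue is not None and cp.min_evalue < th.evalue)
                or cp.orf.peptide_len >= th.peptide
            )
            assert (coding_gate(cp) == "discard_coding") == discard

    def test_gate_monotone_in_coding_evidence(self, rng):
        # strengthening any evidence never flips discard -> retain
        for i in range(200):
            cp = _random_cp(rng, f"t{i}")
            if coding_gate(cp) == "retain_noncoding":
                continue
            stronger = CodingPotential(
                cp.transcript_id,
                orf=ORF(peptide_len=cp.orf.peptide_len + 50),
                combined_prob=min(1.0, cp.combined_prob + 0.3),
                cnci_score=None if cp.cnci_score is None else cp.cnci_score + 1,
                cpat_score=None if cp.cpat_score is None else min(1.0, cp.cpat_score + 0.3),
                min_evalue=None if cp.min_evalue is None else cp.min_evalue / 10,
            )
            assert coding_gate(stronger) == "discard_coding"


class TestBlastTab:
    def _row(self, qid, evalue):
        return "\t".join(
            [qid, "sp|P12345", "98.0", "100", "2", "0", "1", "100", "1", "100", str(evalue), "180"]
        )

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert read_blast_tab(p) == {}

    def test_minimum_evalue_per_query(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._row("t1", "1e-3") + "\n" + self._row("t1", "1e-7") + "\n")
        assert read_blast_tab(p) == {"t1": 1e-7}

    def test_non_numeric_evalue_reports_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._row("t1", "1e-3") + "\n" + self._row("t2", "oops") + "\n")
        with pytest.raises(ValueError, match="line 2"):
            read_blast_tab(p)

    def test_generator_hits_match_manifest(self, synthetic, tmp_path):
        p = tmp_path / "hits.tsv"
        rows = [self._row(t, e) for t, e in sorted(synthetic.blast_hits.items())]
        p.write_text("\n".join(rows) + "\n" if rows else "")
        assert read_blast_tab(p) == pytest.approx(synthetic.blast_hits)
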