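"""End-to-end orchestration: simulate, discover, normalize, DE, cis, enrich.

Every threshold defaults to the pipeline's canonical values (length
> 200 bp, CNCI < 0, CPAT < 0.5, e-value < 1e-5, peptide < 100 aa,
normalized count > 5 in >= 10% of libraries, BH FDR 0.05, 50 kb cis
window). A run writes per-stage tables under the output directory and
returns a machine-readable report with per-stage record counts and the
effective configuration; with a fixed seed, re-running reproduces
every output file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from lncweanflow import de as de_mod
from lncweanflow import simulate as sim
from lncweanflow.annotation_io import (
    Annotation,
    read_fasta,
    read_gtf,
    write_fasta,
    write_gtf,
)
from lncweanflow.cis import call_cis_targets, cis_table, degree_summaries, edge_list, find_candidate_pairs
from lncweanflow.coding import GateThresholds, fit_logistic_combiner, read_blast_tab, score_transcript
from lncweanflow.discovery import (
    candidate_table,
    characterize,
    discover,
    retained_annotation,
)
from lncweanflow.enrichment import enrichment_table, hypergeom_enrich, read_gmt, write_gmt
from lncweanflow.expression import CountMatrix, expression_filter, normalized_counts, size_factors
from lncweanflow.simulate import SimulationConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All inputs, outputs and thresholds of one pipeline run."""

    outdir: str = "lncweanflow_out"
    seed: int = 1
    simulate: bool = True
    # explicit inputs (used when simulate is False)
    assembled_gtf: str | None = None
    reference_gtf: str | None = None
    known_lnc_gtf: str | None = None
    fasta: str | None = None
    counts_tsv: str | None = None
    sample_sheet_tsv: str | None = None
    gmt: str | None = None
    blast_tab: str | None = None
    cnci_tsv: str | None = None
    cpat_tsv: str | None = None
    # thresholds (pipeline canon)
    min_length: int = 201
    cnci: float = 0.0
    cpat: float = 0.5
    evalue: float = 1e-5
    peptide: int = 100
    min_count: float = 5.0
    min_fraction: float = 0.10
    fdr: float = 0.05
    window: int = 50_000
    expr_scale: str = "log2p1"
    tissues: tuple = ("rumen", "ileum")
    n_background_genes: int = 400

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)

    def gate_thresholds(self) -> GateThresholds:
        return GateThresholds(self.cnci, self.cpat, self.evalue, self.peptide)


def _require(condition: bool, stage: str, message: str) -> None:
    if not condition:
        raise PipelineError(stage, message)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full cascade and return the JSON-serializable run report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    # outdir stays out of the report so identical runs in different
    # directories produce byte-identical reports
    report: dict = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "outdir"},
        "stages": {},
    }
    rng = np.random.default_rng(cfg.seed)
    sim_cfg = SimulationConfig(seed=cfg.seed)

    # ---- inputs -----------------------------------------------------------
    if cfg.simulate:
        synth = sim.simulate_annotation(sim_cfg, rng)
        reference, known_lnc, assembled = synth.reference, synth.known_lnc, synth.assembled
        seqs, blast = synth.sequences, synth.blast_hits
        write_gtf(reference, out / "reference.gtf")
        write_gtf(known_lnc, out / "known_lnc.gtf")
        write_gtf(assembled, out / "assembled.gtf")
        write_fasta(seqs, out / "assembled.fa")
        synth.manifest.to_json(out / "manifest.json")
        external = None
    else:
        for name in ("assembled_gtf", "reference_gtf", "known_lnc_gtf", "fasta"):
            _require(getattr(cfg, name) is not None, "inputs", f"{name} required")
            _require(Path(getattr(cfg, name)).exists(), "inputs", f"{getattr(cfg, name)} missing")
        assembled = read_gtf(cfg.assembled_gtf)
        reference = read_gtf(cfg.reference_gtf)
        known_lnc = read_gtf(cfg.known_lnc_gtf)
        seqs = read_fasta(cfg.fasta)
        blast = read_blast_tab(cfg.blast_tab) if cfg.blast_tab else {}
        external = {}
        if cfg.cnci_tsv:
            from lncweanflow.coding import read_score_table

            external["cnci"] = read_score_table(cfg.cnci_tsv, "cnci_score")
        if cfg.cpat_tsv:
            from lncweanflow.coding import read_score_table

            external["cpat"] = read_score_table(cfg.cpat_tsv, "cpat_score")
    report["stages"]["inputs"] = {
        "assembled_transcripts": assembled.n_transcripts(),
        "reference_genes": len(reference),
        "known_lnc_transcripts": known_lnc.n_transcripts(),
        "sequences": len(seqs),
    }

    # ---- coding model + discovery cascade ---------------------------------
    _require(len(seqs) > 0, "coding", "no transcript sequences available")
    corpus = sim.training_corpus(sim_cfg, rng)
    coding_table = sim.hexamer_table_from_seqs(s for s, y in corpus if y == 1)
    noncoding_table = sim.hexamer_table_from_seqs(s for s, y in corpus if y == 0)

    zero = _zero_combiner()

    def features(seq):
        cp = score_transcript("t", seq, coding_table, noncoding_table, zero, "+")
        return (cp.orf.peptide_len, 3.0 * cp.orf.peptide_len / len(seq), cp.fickett, cp.hexamer_llr)

    combiner = fit_logistic_combiner([(features(s), y) for s, y in corpus])

    candidates = discover(
        assembled,
        reference,
        known_lnc,
        seqs,
        external_scores=external,
        blast=blast,
        min_length=cfg.min_length,
        thresholds=cfg.gate_thresholds(),
        coding_table=coding_table,
        noncoding_table=noncoding_table,
        combiner=combiner,
    )
    candidate_table(candidates).to_csv(out / "lncrna_candidates.tsv", sep="\t", index=False)
    retained = retained_annotation(candidates)
    write_gtf(retained, out / "lncrna_retained.gtf")
    kept = [c for c in candidates if c.retained]
    summaries = characterize(candidates)
    report["stages"]["discovery"] = {
        "input_transcripts": len(candidates),
        "retained_lncrna": len(kept),
        "known": sum(bool(c.known) for c in kept),
        "novel": sum(not c.known for c in kept),
        "positional_classes": {k: int(v) for k, v in summaries["positional_classes"].items()},
        "length_bins": {k: int(v) for k, v in summaries["length_bins"].items()},
    }
    _require(len(kept) > 0, "discovery", "no lncRNA candidates survived the cascade")

    # ---- counts -----------------------------------------------------------
    mrna_gene_ids = sorted(
        g for g, gene in reference.genes.items() if gene.biotype == "protein_coding"
    )
    lnc_gene_ids = sorted(retained.genes)
    mrna_ann = reference.subset({"protein_coding"})
    planted_cis = [
        (lnc, gene)
        for lnc, gene, dist in find_candidate_pairs(retained, mrna_ann, cfg.window)
        if dist == 0
    ]
    report["stages"]["de"] = {}
    report["stages"]["cis"] = {}
    report["stages"]["enrichment"] = {}
    background = [f"BG{i + 1:06d}" for i in range(cfg.n_background_genes)]
    for tissue in cfg.tissues:
        if cfg.simulate:
            cm_all, counts_manifest = sim.simulate_counts(
                sim_cfg, mrna_gene_ids + background, lnc_gene_ids, tissue, rng, planted_cis
            )
            cm_all.to_tsv(out / f"counts_{tissue}.tsv", out / f"samples_{tissue}.tsv")
            with open(out / f"counts_manifest_{tissue}.json", "w") as fh:
                json.dump(dataclasses.asdict(counts_manifest), fh, indent=1, sort_keys=True)
        else:
            _require(cfg.counts_tsv is not None, "counts", "counts_tsv required")
            cm_full = CountMatrix.from_tsv(cfg.counts_tsv, cfg.sample_sheet_tsv)
            if tissue not in set(cm_full.sample_sheet["tissue"]):
                continue
            cm_all = cm_full.subset_tissue(tissue)

        sf = size_factors(cm_all)
        expressed = expression_filter(cm_all, sf, cfg.min_count, cfg.min_fraction)
        expressed_mrna = [f for f in expressed if f not in set(lnc_gene_ids)]
        expressed_lnc = [f for f in expressed if f in set(lnc_gene_ids)]

        de_table = de_mod.run_de(cm_all, sf, feature_ids=expressed, sig_level=cfg.fdr)
        de_table.to_csv(out / f"de_{tissue}.tsv", sep="\t", index=False, float_format="%.6g")
        sig = de_table[de_table["significant"]]
        report["stages"]["de"][tissue] = {
            "samples": len(cm_all.sample_ids),
            "expressed_features": len(expressed),
            "expressed_mrna": len(expressed_mrna),
            "expressed_lncrna": len(expressed_lnc),
            "significant": int(len(sig)),
            "significant_lncrna": int(sig["feature_id"].isin(set(lnc_gene_ids)).sum()),
        }

        # cis targets on normalized counts, both timepoints pooled
        norm = normalized_counts(cm_all, sf)
        pairs = find_candidate_pairs(retained, mrna_ann, cfg.window)
        results = call_cis_targets(
            pairs,
            norm.loc[[f for f in expressed_lnc]],
            norm.loc[[f for f in expressed_mrna if f in norm.index]],
            fdr=cfg.fdr,
            expr_scale=cfg.expr_scale,
        )
        cis_table(results).to_csv(out / f"cis_{tissue}.tsv", sep="\t", index=False, float_format="%.6g")
        edge_list(results).to_csv(out / f"cis_edges_{tissue}.tsv", sep="\t", index=False)
        by_lnc, by_gene = degree_summaries(results)
        report["stages"]["cis"][tissue] = {
            "candidate_pairs": len(pairs),
            "tested_pairs": len(results),
            "cis_targets": int(sum(c.is_cis_target for c in results)),
            "lncrnas_with_targets": int(len(by_lnc)),
            "targeted_genes": int(len(by_gene)),
        }

        # enrichment of significant DE mRNAs against gene sets
        de_mrna = [f for f in sig["feature_id"] if f in set(expressed_mrna)]
        if cfg.simulate:
            collection = sim.simulate_gene_sets(rng, expressed_mrna, de_mrna)
            write_gmt(collection, out / f"gene_sets_{tissue}.gmt")
        elif cfg.gmt:
            collection = read_gmt(cfg.gmt, universe=expressed_mrna)
        else:
            collection = None
        if collection is None or not de_mrna:
            report["stages"]["enrichment"][tissue] = {"skipped": True}
        else:
            res = hypergeom_enrich(de_mrna, collection, correction="bh")
            enrichment_table(res).to_csv(
                out / f"enrichment_{tissue}.tsv", sep="\t", index=False, float_format="%.6g"
            )
            report["stages"]["enrichment"][tissue] = {
                "sets_tested": len(res),
                "significant_bh": int(sum(r.p_bh < cfg.fdr for r in res)),
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _zero_combiner():
    from lncweanflow.coding import LogisticCombiner

    return LogisticCombiner(np.zeros(5))
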