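"""End-to-end comparative analysis: read -> orient/align -> variants ->
repeats -> mask -> windows -> hotspots -> effects -> codon/expression ->
phylogeny (optional), writing one TSV/BED/JSON bundle per run."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import align as _align
from . import codon_usage as _cu
from . import effects as _effects
from . import phylo as _phylo
from . import repeats as _repeats
from . import windows as _windows
from .genome_io import (
    PlastomeRecord, read_counts_tsv, read_fasta, read_genbank, write_bed,
    write_newick, write_tsv, extract_cds,
)

log = logging.getLogger("plastcomp")


@dataclass
class PipelineConfig:
    ref_path: str | None = None
    qry_path: str | None = None
    counts_path: str | None = None
    msa_path: str | None = None
    outdir: str = "plastcomp_out"
    k: int = _align.DEFAULT_K
    max_gap: int = _align.DEFAULT_MAX_GAP
    window: int = _windows.DEFAULT_WINDOW
    step: int = _windows.DEFAULT_STEP
    threshold: float = _windows.DEFAULT_THRESHOLD
    snv_only: bool = False
    ssr_thresholds: dict = field(
        default_factory=lambda: dict(_repeats.DEFAULT_SSR_THRESHOLDS))
    repeat_min_len: int = 30
    repeat_max_mismatch: int = 3
    bootstrap_reps: int = 0
    bootstrap_method: str = "nj"
    seed: int = 0

    def validate(self) -> None:
        if not self.window >= self.step > 0:
            raise ValueError("window must be >= step > 0")
        if self.repeat_min_len < 1 or not 0 <= self.repeat_max_mismatch <= 3:
            raise ValueError("repeat parameters out of range")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


def load_record(path: str | Path) -> PlastomeRecord:
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank", ".gbff"):
        return read_genbank(path)
    recs = read_fasta(path)
    if len(recs) != 1:
        raise ValueError(f"{path}: expected exactly one record")
    return recs[0]


def attach_features_tsv(record: PlastomeRecord, path: str | Path) -> PlastomeRecord:
    from .genome_io import GeneFeature, read_tsv

    df = read_tsv(path)
    feats = [
        GeneFeature(name=row["name"], ftype=row["type"],
                    parts=[(int(row["start"]), int(row["end"]))],
                    strand=int(row["strand"]), phase=int(row.get("phase", 0)))
        for _, row in df.iterrows()
    ]
    record.features = feats
    record.__post_init__()
    return record


def run_pipeline(config: PipelineConfig, ref: PlastomeRecord | None = None,
                 qry: PlastomeRecord | None = None) -> dict:
    """Run every applicable stage; returns the summary dict (also written
    to ``summary.json``). Stages with missing inputs are skipped with a
    warning; any stage failure aborts with the stage name."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    if not log.handlers:
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    summary: dict = {"stages": []}

    def stage(name: str):
        log.info("stage %s", name)
        summary["stages"].append(name)

    if ref is None:
        if config.ref_path is None:
            raise ValueError("no reference given")
        ref = load_record(config.ref_path)
    if qry is None and config.qry_path:
        qry = load_record(config.qry_path)

    # --- repeats & SSRs on the reference
    stage("repeats")
    ssrs = _repeats.find_ssrs(ref.seq, config.ssr_thresholds)
    reps = _repeats.find_long_repeats(ref.seq, config.repeat_min_len,
                                      config.repeat_max_mismatch)
    tandems = _repeats.find_tandem_repeats(ref.seq)
    write_tsv(pd.DataFrame([asdict(s) for s in ssrs]), outdir / "ssrs.tsv")
    write_tsv(pd.DataFrame([asdict(r) for r in reps]), outdir / "long_repeats.tsv")
    write_tsv(pd.DataFrame([asdict(t) for t in tandems]), outdir / "tandem_repeats.tsv")
    by_len, by_class = _repeats.ssr_summary(ssrs)
    write_tsv(by_len, outdir / "ssr_counts_by_unit.tsv")
    write_tsv(by_class, outdir / "ssr_counts_by_class.tsv")
    write_tsv(_repeats.repeat_summary(reps), outdir / "repeat_counts.tsv")
    summary["n_ssrs"] = len(ssrs)
    summary["n_long_repeats"] = len(reps)
    summary["n_tandem_repeats"] = len(tandems)
    log.info("repeats: %d SSRs, %d long repeats, %d tandem", len(ssrs), len(reps),
             len(tandems))

    variants = []
    if qry is not None:
        stage("align")
        amap, transform, oriented = _align.align_genomes(
            ref.seq, qry.seq, config.k, config.max_gap)
        summary["reoriented_blocks"] = len(transform.flips)
        stage("variants")
        variants = _align.call_variants(amap, ref.seq, oriented)
        vrows = [{"CHROM": ref.id, "POS": v.ref_pos + 1, "REF": v.ref_allele or "-",
                  "ALT": v.alt_allele or "-", "TYPE": v.vtype} for v in variants]
        write_tsv(pd.DataFrame(vrows, columns=["CHROM", "POS", "REF", "ALT", "TYPE"]),
                  outdir / "variants.tsv")
        write_bed([(ref.id, o.ref_start, o.ref_end, "unaligned")
                   for o in amap.ops if o.type == "unaligned"],
                  outdir / "unaligned.bed")
        summary["n_variants"] = len(variants)
        summary["n_snv"] = sum(v.vtype == "SNV" for v in variants)
        summary["n_indel"] = len(variants) - summary["n_snv"]
        log.info("variants: %d (%d SNV)", len(variants), summary["n_snv"])

        stage("mask")
        mask = _windows.mask_from_repeats(reps, ref.length)
        write_bed([(ref.id, s, e) for s, e in mask], outdir / "mask.bed")

        stage("windows")
        wins = _windows.window_dissimilarity(
            amap, ref.seq, oriented, config.window, config.step, mask,
            snv_only=config.snv_only)
        wrows = [{"start": w.ref_start, "end": w.ref_end,
                  "comparable": w.n_comparable, "diff": w.n_diff,
                  "pct": "" if w.dissimilarity is None else round(w.dissimilarity, 4),
                  "masked_frac": round(w.masked_fraction, 4)} for w in wins]
        write_tsv(pd.DataFrame(wrows), outdir / "windows.tsv")
        summary["n_windows"] = len(wins)

        stage("hotspots")
        hots = _windows.call_hotspots(wins, ref.features, config.threshold)
        write_bed([(ref.id, h.ref_start, h.ref_end, h.label) for h in hots],
                  outdir / "hotspots.bed")
        write_tsv(pd.DataFrame([{"start": h.ref_start, "end": h.ref_end,
                                 "peak_pct": round(h.peak, 4), "label": h.label}
                                for h in hots]), outdir / "hotspots.tsv")
        summary["hotspots"] = [{"start": h.ref_start, "end": h.ref_end,
                                "label": h.label} for h in hots]
        log.info("hotspots: %d", len(hots))

        stage("effects")
        effs = _effects.annotate_variants(variants, ref)
        summaries = _effects.summarize_by_gene(effs)
        write_tsv(_effects.effects_frame(effs), outdir / "effects.tsv")
        write_tsv(_effects.summary_frame(summaries), outdir / "gene_variant_summary.tsv")
        summary["gene_variant_summary"] = [
            {"gene": s.gene, "n_total": s.n_total, "n_nonsyn": s.n_nonsyn,
             "n_syn": s.n_syn, "notations": s.notations} for s in summaries]

    # --- codon usage / expression
    if ref.cds_features():
        stage("codon")
        cds = {f.name: extract_cds(ref, f.name) for f in ref.cds_features()}
        table = _cu.count_codons(cds)
        write_tsv(table.to_frame().reset_index(), outdir / "codon_counts.tsv")
        summary["total_codons"] = table.total_codons()
        summary["total_codons_no_stops"] = table.total_codons(include_stops=False)
        try:
            bias = _cu.bias_scores(table)
            write_tsv(bias, outdir / "bias_scores.tsv")
            summary["genes_melp_gt_1"] = sorted(bias.loc[bias["MELP"] > 1.0, "gene"])
        except ValueError as err:
            log.warning("bias scores skipped: %s", err)
            bias = None
        if config.counts_path and bias is not None:
            stage("expression")
            counts = read_counts_tsv(config.counts_path)
            lengths = {f.name: f.spliced_length for f in ref.cds_features()}
            expr = _cu.fpkm(counts, lengths)
            write_tsv(pd.DataFrame([asdict(e) for e in expr]), outdir / "expression.tsv")
            report = _cu.bias_expression_report(bias, expr)
            write_tsv(report["category_means"], outdir / "category_mean_fpkm.tsv")
            summary["bias_expression"] = {
                "regression": report["regression"],
                "spearman": report["spearman_melp_log10fpkm"],
            }
        elif config.counts_path is None:
            log.warning("no counts table; expression stage skipped")

    # --- phylogeny
    if config.msa_path:
        stage("phylogeny")
        msa = {r.id: r.seq for r in read_fasta(config.msa_path)}
        dm = _phylo.distance_matrix(msa)
        write_tsv(pd.DataFrame(dm.matrix, index=dm.taxa, columns=dm.taxa)
                  .reset_index(names="taxon"), outdir / "jc_distances.tsv")
        if config.bootstrap_reps:
            tree = _phylo.bootstrap_support(msa, config.bootstrap_reps, config.seed,
                                            method=config.bootstrap_method)
        else:
            tree, _ = (_phylo.ml_search(msa) if len(msa) <= 7
                       else (_phylo.nj_tree(dm), 0.0))
        write_newick(tree.to_newick(with_support=bool(config.bootstrap_reps)),
                     outdir / "tree.nwk")
        summary["tree"] = tree.to_newick(with_support=bool(config.bootstrap_reps))

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
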