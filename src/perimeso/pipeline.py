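"""Pipeline orchestration: in-memory end-to-end analysis plus file-based
stages the command line composes (simulate -> segment -> callcna ->
callvar -> integrate)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cna, integrate, synth, variants
from .config import RunConfig

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed so stages are independently
    rerunnable from one root seed."""
    idx = {"array": 1, "counts": 2}[stage]
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class PipelineResult:
    cohort: synth.Cohort
    probes: pd.DataFrame
    segments: list[cna.Segment]
    burdens: pd.DataFrame
    band_calls: pd.DataFrame
    recurrent_bands: pd.DataFrame
    gene_scores: pd.DataFrame
    cascades: Mapping[str, variants.CascadeResult]
    statuses: list[integrate.SampleGeneStatus]
    summary: integrate.CohortSummary
    mutation_rates: Mapping[str, float]
    recurrences: list[variants.GeneRecurrence]

    @property
    def recovered_categories(self) -> dict[str, str]:
        return {s.sample: s.category for s in self.statuses}


def _segment_all(probes: pd.DataFrame, cfg: RunConfig) -> list[cna.Segment]:
    probes = cna.filter_probes(probes)
    segments: list[cna.Segment] = []
    for sample, sdf in probes.groupby("sample", sort=True):
        sdf = sdf.reset_index(drop=True)
        if cfg.center_logr:
            sdf = cna.center_logr(sdf, baf_threshold=cfg.baf_threshold)
        segments.extend(cna.segment_profile(
            sdf, penalty=cfg.segment_penalty, gamma=cfg.segment_gamma))
    return segments


def _call_variants(counts: pd.DataFrame, cfg: RunConfig,
                   genome: synth.GenomeModel
                   ) -> dict[str, variants.CascadeResult]:
    cascades = {}
    for sample, sdf in counts.groupby("sample", sort=True):
        cascades[sample] = variants.run_cascade(
            sdf.reset_index(drop=True), cfg.variants, genome=genome)
    return cascades


def _integrate(cohort: synth.Cohort, segments, cascades,
               cfg: RunConfig) -> list[integrate.SampleGeneStatus]:
    gene = cohort.genome.gene(cfg.target_gene)
    statuses = []
    for sample in sorted(cohort.assays):
        assays = cohort.assays[sample]
        segs = ([s for s in segments if s.sample == sample]
                if "array" in assays else [])
        calls = cascades.get(sample)
        somatic = []
        germline = []
        if calls is not None and "exome" in assays:
            for c in calls.retained:
                if c.gene != cfg.target_gene:
                    continue
                if c.category == "somatic" and c.non_silent:
                    somatic.append(c)
                elif (c.category == "germline"
                      and c.effect in ("nonsense", "frameshift")):
                    germline.append(c)
        statuses.append(integrate.assemble_status(
            sample, assays, gene, segments=segs, somatic_calls=somatic,
            germline_variants=germline,
            purity=cfg.purity_assumption,
            subclonal_af_factor=cfg.subclonal_af_factor,
            subclonal_logr_factor=cfg.subclonal_logr_factor,
            whole_chromosome_fraction=cfg.whole_chromosome_fraction))
    return statuses


def run_cohort_analysis(cfg: RunConfig | None = None,
                        seed: int | None = None) -> PipelineResult:
    """Simulate the study-design cohort and run every stage in memory."""
    cfg = cfg or RunConfig()
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    cohort = synth.build_cohort(cfg.cohort, seed=seed)
    genome, truth = cohort.genome, cohort.truth

    probes = synth.simulate_array(
        genome, truth, samples=sorted(cohort.assays),
        spacing=cfg.cohort.probe_spacing, noise_sd=cfg.cohort.noise_sd,
        seed=stage_seed(seed, "array"),
        missing_rate=cfg.cohort.missing_rate)
    segments = _segment_all(probes, cfg)
    segments = cna.call_segments(segments, cfg.logr_threshold,
                                 cfg.baf_threshold)
    burdens = cna.summarize_samples(segments, cfg.min_segment_size)
    band_calls = cna.call_cytobands(segments, genome.cytobands,
                                    cfg.cytoband_fraction)
    rec_bands = cna.recurrent_cytobands(band_calls,
                                        cfg.min_recurrent_band_samples,
                                        cfg.cytoband_fraction)
    scores = cna.gene_scores(segments, genome.genes,
                             samples=sorted(cohort.assays))

    counts = synth.simulate_counts(
        genome, truth, mean_depth=cfg.cohort.mean_depth,
        seed=stage_seed(seed, "counts"), error_rate=cfg.cohort.error_rate)
    cascades = _call_variants(counts, cfg, genome)

    rates = {}
    all_calls: list[variants.VariantCall] = []
    for sample, res in cascades.items():
        n_som = sum(1 for c in res.retained if c.category == "somatic")
        rates[sample] = variants.mutation_rate(n_som, genome.total_length)
        all_calls.extend(res.calls)
    recurrences = variants.recurrent_genes(all_calls,
                                           cfg.min_recurrent_gene_samples)

    statuses = _integrate(cohort, segments, cascades, cfg)
    summary = integrate.cohort_summary(statuses)
    return PipelineResult(cohort=cohort, probes=probes, segments=segments,
                          burdens=burdens, band_calls=band_calls,
                          recurrent_bands=rec_bands, gene_scores=scores,
                          cascades=cascades, statuses=statuses,
                          summary=summary, mutation_rates=rates,
                          recurrences=recurrences)


# ---------------------------------------------------------------------------
# file-based stages (composable subcommands)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synth.build_cohort(cfg.cohort, seed=cfg.seed)
    probes = synth.simulate_array(
        cohort.genome, cohort.truth, samples=sorted(cohort.assays),
        spacing=cfg.cohort.probe_spacing, noise_sd=cfg.cohort.noise_sd,
        seed=stage_seed(cfg.seed, "array"),
        missing_rate=cfg.cohort.missing_rate)
    counts = synth.simulate_counts(
        cohort.genome, cohort.truth, mean_depth=cfg.cohort.mean_depth,
        seed=stage_seed(cfg.seed, "counts"),
        error_rate=cfg.cohort.error_rate)
    synth.write_probes(probes, outdir / "probes.tsv")
    synth.write_counts(counts, outdir / "counts.tsv")
    synth.write_genome_json(cohort.genome, outdir / "genome.json")
    synth.write_truth_json(cohort.truth, outdir / "truth.json")
    synth.write_cytoband_bed(cohort.genome, outdir / "cytobands.bed")
    synth.write_gene_bed(cohort.genome, outdir / "genes.bed")
    manifest = pd.DataFrame(
        [{"sample": s, "assays": ",".join(a),
          "planted_category": cohort.categories[s]}
         for s, a in sorted(cohort.assays.items())])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    logger.info("simulated %d probes and %d count rows for %d samples",
                len(probes), len(counts), len(cohort.assays))


def stage_segment(cfg: RunConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    probes = synth.read_probes(outdir / "probes.tsv")
    segments = _segment_all(probes, cfg)
    cna.write_segments(segments, outdir / "segments.tsv")
    logger.info("segmented %d probes into %d segments", len(probes),
                len(segments))


def stage_callcna(cfg: RunConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    segments = cna.read_segments(outdir / "segments.tsv")
    genome = synth.read_genome_json(outdir / "genome.json")
    segments = cna.call_segments(segments, cfg.logr_threshold,
                                 cfg.baf_threshold)
    cna.write_segments(segments, outdir / "called_segments.tsv")
    cna.summarize_samples(segments, cfg.min_segment_size).to_csv(
        outdir / "sample_burden.tsv", sep="\t", index=False)
    band_calls = cna.call_cytobands(segments, genome.cytobands,
                                    cfg.cytoband_fraction)
    band_calls.to_csv(outdir / "cytoband_calls.tsv", sep="\t", index=False)
    rec = cna.recurrent_cytobands(band_calls,
                                  cfg.min_recurrent_band_samples,
                                  cfg.cytoband_fraction)
    rec.assign(samples=rec["samples"].map(lambda s: ",".join(s))).to_csv(
        outdir / "recurrent_cytobands.tsv", sep="\t", index=False)
    cna.gene_scores(segments, genome.genes).to_csv(
        outdir / "gene_scores.tsv", sep="\t", index=False)
    logger.info("called %d segments", len(segments))


def stage_callvar(cfg: RunConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    counts = synth.read_counts(outdir / "counts.tsv")
    genome = synth.read_genome_json(outdir / "genome.json")
    cascades = _call_variants(counts, cfg, genome)
    all_calls = []
    rates = {}
    for sample, res in sorted(cascades.items()):
        all_calls.extend(res.calls)
        variants.write_vcf(res.calls, genome, outdir / f"{sample}.vcf")
        n_som = sum(1 for c in res.retained if c.category == "somatic")
        rates[sample] = variants.mutation_rate(n_som, genome.total_length)
    variants.write_calls_tsv(all_calls, outdir / "calls.tsv")
    with open(outdir / "mutation_rates.json", "w") as fh:
        json.dump({"per_sample": rates,
                   "median": variants.median_rate(list(rates.values()))},
                  fh, indent=1)
    logger.info("classified %d sites across %d sample pairs",
                len(all_calls), len(cascades))


def stage_integrate(cfg: RunConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    genome = synth.read_genome_json(outdir / "genome.json")
    gene = genome.gene(cfg.target_gene)
    segments = cna.read_segments(outdir / "called_segments.tsv")
    calls = pd.read_csv(outdir / "calls.tsv", sep="\t",
                        dtype={"chrom": str}, keep_default_na=False)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")

    statuses = []
    for r in manifest.itertuples(index=False):
        sample = str(r.sample)
        assays = tuple(str(r.assays).split(","))
        segs = ([s for s in segments if s.sample == sample]
                if "array" in assays else [])
        sc = calls[(calls["sample"] == sample)
                   & (calls["filter"] == "PASS")
                   & (calls["gene"] == cfg.target_gene)]
        somatic = []
        germline = []
        for row in sc.itertuples(index=False):
            if row.category == "somatic" and row.non_silent:
                somatic.append(integrate.SomaticEvidence(
                    label=f"{row.effect}@{row.pos}",
                    af=(("exome", float(row.t_vaf)),)))
            elif (row.category == "germline"
                  and row.effect in ("nonsense", "frameshift")):
                germline.append(f"{row.effect}@{row.pos}")
        statuses.append(integrate.assemble_status(
            sample, assays, gene, segments=segs,
            external_mutations=somatic,
            germline_variants=germline,
            purity=cfg.purity_assumption,
            subclonal_af_factor=cfg.subclonal_af_factor,
            subclonal_logr_factor=cfg.subclonal_logr_factor,
            whole_chromosome_fraction=cfg.whole_chromosome_fraction))
    integrate.write_status_table(statuses, outdir / "status_table.tsv")
    integrate.write_summary_json(integrate.cohort_summary(statuses),
                                 outdir / "summary.json")
    logger.info("integrated %d samples", len(statuses))


def run_all(cfg: RunConfig, outdir: Path) -> None:
    cfg.validate()
    stage_simulate(cfg, outdir)
    stage_segment(cfg, outdir)
    stage_callcna(cfg, outdir)
    stage_callvar(cfg, outdir)
    stage_integrate(cfg, outdir)
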