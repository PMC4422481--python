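"""Paired tumor-normal variant classification and the staged filter cascade.

Each site carries ref/alt read counts for tumor and matched normal plus the
read-level quality summaries a false-positive filter inspects.  Sites are
first screened by coverage/frequency/quality minima, then classified by a
Fisher exact test on the 2x2 table [[n_ref, n_alt], [t_ref, t_alt]]:

* **somatic** — normal VAF below the heterozygous band and one-sided
  (tumor-alt-enrichment) Fisher p below alpha;
* **loh** — normal heterozygous but tumor VAF outside the band with a
  significant two-sided Fisher p (loss of one allele in the tumor);
* **germline** — tumor and normal VAF in the same genotype band
  (heterozygous [0.15, 0.85] or homozygous-alt above it);
* **unknown** — everything else.

Classified calls then pass through numbered filter stages, each recording
the first rule it fails: (1) low-quality somatic indels, (2) proximity to
indels and SNV clusters, (3) somatic significance and normal-contamination
limits, (4) a false-positive filter over read position, strand bias,
variant reads and frequency, distance to the 3' end, homopolymer context
and mapping-quality difference.  A site removed at stage k is not re-tested
downstream, so every input ends as exactly one of retained / removed(label).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import COUNT_COLUMNS, Gene, GenomeModel, cds_offset

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SiteCounts:
    """One site of a paired tumor/normal pileup comparison."""

    sample: str
    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str
    t_ref: int
    t_alt: int
    n_ref: int
    n_alt: int
    avg_qual: float   # phred mean over variant-supporting bases
    fwd_alt: int
    rev_alt: int
    read_pos: float   # mean variant position as fraction of read length
    dist3p: float     # mean distance to the 3' end (fraction)
    mapq_diff: float  # variant-read minus reference-read mapping quality
    homopolymer_len: int
    is_indel: bool = False
    indel_len: int = 0

    @property
    def t_depth(self) -> int:
        return self.t_ref + self.t_alt

    @property
    def n_depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def t_vaf(self) -> float:
        return self.t_alt / self.t_depth if self.t_depth else float("nan")

    @property
    def n_vaf(self) -> float:
        return self.n_alt / self.n_depth if self.n_depth else float("nan")


@dataclass
class VariantCall:
    """A classified site with its filter history (empty filters = retained)."""

    site: SiteCounts
    category: str = "unknown"
    somatic_p: float = float("nan")
    t_vaf: float = float("nan")
    n_vaf: float = float("nan")
    filters: list[str] = field(default_factory=list)
    gene: str | None = None
    effect: str | None = None
    non_silent: bool = False

    @property
    def passed(self) -> bool:
        return not self.filters


@dataclass(frozen=True)
class ConsequenceCall:
    gene: str | None
    effect: str | None  # silent | missense | nonsense | frameshift | inframe_indel
    non_silent: bool


@dataclass(frozen=True)
class VariantConfig:
    """All cascade thresholds.  Coverage/VAF/quality minima and the stage
    1-3 cutoffs follow the published pipeline settings; the stage-4
    false-positive thresholds are declared defaults in the spirit of the
    named criteria."""

    min_coverage: int = 10
    min_vaf: float = 0.10
    min_avg_qual: float = 17.0
    somatic_alpha: float = 0.05
    het_band: tuple[float, float] = (0.15, 0.85)
    indel_min_depth: int = 10
    indel_min_support: int = 3
    indel_max_germline_freq: float = 0.05
    indel_window: int = 3
    cluster_k: int = 3
    cluster_window: int = 10
    somatic_max_normal_vaf: float = 0.05
    fp_min_var_reads: int = 4
    fp_min_var_freq: float = 0.05
    fp_read_pos_range: tuple[float, float] = (0.1, 0.9)
    fp_min_dist3p: float = 0.1
    fp_strand_alpha: float = 0.01
    fp_strand_min_reads: int = 10
    fp_max_homopolymer: int = 5   # run >= this fails
    fp_min_mapq_diff: float = -10.0
    fp_quality_delta_enabled: bool = False


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------

def basic_filter(site: SiteCounts, cfg: VariantConfig = VariantConfig()
                 ) -> tuple[bool, str | None]:
    """Coverage / variant-frequency / base-quality minima.  Returns
    (passed, first failing label)."""
    if site.t_depth < cfg.min_coverage:
        return False, "min_coverage_tumor"
    if site.n_depth < cfg.min_coverage:
        return False, "min_coverage_normal"
    if site.t_vaf < cfg.min_vaf:
        return False, "min_vaf"
    if site.avg_qual < cfg.min_avg_qual:
        return False, "min_avg_qual"
    return True, None


def somatic_fisher_p(site: SiteCounts) -> float:
    """One-sided Fisher exact p for tumor alt enrichment over the normal on
    [[n_ref, n_alt], [t_ref, t_alt]]."""
    return float(stats.fisher_exact(
        [[site.n_ref, site.n_alt], [site.t_ref, site.t_alt]],
        alternative="greater").pvalue)


def classify_site(site: SiteCounts, cfg: VariantConfig = VariantConfig()
                  ) -> VariantCall:
    """Assign germline / somatic / loh / unknown from the paired VAFs and
    the Fisher exact test.  The site must have non-zero depth in both
    samples (pre-filtered)."""
    if site.t_depth == 0 or site.n_depth == 0:
        raise ValueError("zero-depth site must be removed by basic_filter")
    lo, hi = cfg.het_band
    t_vaf, n_vaf = site.t_vaf, site.n_vaf
    p_som = somatic_fisher_p(site)
    call = VariantCall(site=site, somatic_p=p_som, t_vaf=t_vaf, n_vaf=n_vaf)

    n_het = lo <= n_vaf <= hi
    t_het = lo <= t_vaf <= hi
    if n_vaf < lo and p_som < cfg.somatic_alpha:
        call.category = "somatic"
    elif n_het and not t_het:
        p_two = float(stats.fisher_exact(
            [[site.n_ref, site.n_alt], [site.t_ref, site.t_alt]],
            alternative="two-sided").pvalue)
        call.category = "loh" if p_two < cfg.somatic_alpha else "unknown"
    elif (n_het and t_het) or (n_vaf > hi and t_vaf > hi):
        call.category = "germline"
    else:
        call.category = "unknown"
    return call


def filter_indel(call: VariantCall, cfg: VariantConfig = VariantConfig()
                 ) -> tuple[bool, str | None]:
    """Stage 1 — low-quality somatic indels: coverage < 10x, < 3 supporting
    reads, or germline frequency strictly above 5%."""
    if not call.site.is_indel:
        raise ValueError("filter_indel applies to indel calls only")
    if call.site.t_depth < cfg.indel_min_depth:
        return False, "indel_coverage"
    if call.site.t_alt < cfg.indel_min_support:
        return False, "indel_support"
    if call.n_vaf > cfg.indel_max_germline_freq:
        return False, "indel_germline_freq"
    return True, None


def filter_proximity_and_clusters(calls: Sequence[VariantCall],
                                  cfg: VariantConfig = VariantConfig()
                                  ) -> dict[int, list[str]]:
    """Stage 2 — flags (non-destructive) per call index:

    * ``near_indel`` — an SNV within ``indel_window`` bp of a retained indel
      on the same chromosome;
    * ``snv_cluster`` — an SNV in a run of >= ``cluster_k`` SNVs spanning
      <= ``cluster_window`` bp.
    """
    flags: dict[int, list[str]] = {}
    by_chrom: dict[str, list[tuple[int, VariantCall]]] = {}
    for idx, c in enumerate(calls):
        by_chrom.setdefault(c.site.chrom, []).append((idx, c))
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t[1].site.pos)
        indel_pos = [c.site.pos for _, c in items if c.site.is_indel]
        snvs = [(i, c) for i, c in items if not c.site.is_indel]
        for i, c in snvs:
            if any(abs(c.site.pos - ip) <= cfg.indel_window
                   for ip in indel_pos):
                flags.setdefault(i, []).append("near_indel")
        pos = [c.site.pos for _, c in snvs]
        k = cfg.cluster_k
        clustered: set[int] = set()
        for a in range(len(pos) - k + 1):
            if pos[a + k - 1] - pos[a] <= cfg.cluster_window:
                clustered.update(range(a, a + k))
        for a in sorted(clustered):
            flags.setdefault(snvs[a][0], []).append("snv_cluster")
    return flags


def filter_somatic_quality(call: VariantCall,
                           cfg: VariantConfig = VariantConfig()
                           ) -> tuple[bool, str | None]:
    """Stage 3 — a somatic call is retained iff its Fisher p is significant
    and the normal is clean (<= 5% alt for SNVs, zero alt reads for
    indels)."""
    if call.category != "somatic":
        raise ValueError("filter_somatic_quality applies to somatic calls")
    if not (call.somatic_p < cfg.somatic_alpha):
        return False, "somatic_fisher"
    if call.site.is_indel:
        if call.site.n_alt > 0:
            return False, "somatic_normal_alt_indel"
    elif call.n_vaf > cfg.somatic_max_normal_vaf:
        return False, "somatic_normal_alt"
    return True, None


def fp_filter(call: VariantCall, cfg: VariantConfig = VariantConfig()
              ) -> tuple[bool, str | None]:
    """Stage 4 — read-level false-positive criteria, first failure wins."""
    s = call.site
    needed = (s.t_alt, s.t_vaf, s.read_pos, s.dist3p, s.fwd_alt, s.rev_alt,
              s.homopolymer_len, s.mapq_diff)
    if any(x is None or (isinstance(x, float) and not np.isfinite(x))
           for x in needed):
        return False, "fp_unscorable"
    if s.t_alt < cfg.fp_min_var_reads:
        return False, "fp_var_reads"
    if s.t_vaf < cfg.fp_min_var_freq:
        return False, "fp_var_freq"
    lo, hi = cfg.fp_read_pos_range
    if not (lo <= s.read_pos <= hi):
        return False, "fp_read_pos"
    if s.dist3p < cfg.fp_min_dist3p:
        return False, "fp_dist3p"
    n = s.fwd_alt + s.rev_alt
    if n >= cfg.fp_strand_min_reads:
        p = float(stats.binomtest(s.fwd_alt, n, 0.5).pvalue)
        if p < cfg.fp_strand_alpha:
            return False, "fp_strand_bias"
    if s.homopolymer_len >= cfg.fp_max_homopolymer:
        return False, "fp_homopolymer"
    if s.mapq_diff < cfg.fp_min_mapq_diff:
        return False, "fp_mapq_diff"
    return True, None


# ---------------------------------------------------------------------------
# consequence annotation (toy gene model)
# ---------------------------------------------------------------------------

def annotate_consequence(call: VariantCall | SiteCounts,
                         genome: GenomeModel) -> ConsequenceCall:
    """Classify the coding effect of a variant on the synthetic gene model.

    Substitutions use the codon table (silent / missense / nonsense);
    coding indels are frameshift iff their length is not a codon multiple,
    else in-frame.  Variants outside any coding interval carry no effect.
    """
    from Bio.Seq import Seq

    site = call.site if isinstance(call, VariantCall) else call
    for gene in genome.genes:
        if gene.chrom != site.chrom:
            continue
        if not (gene.start <= site.pos - 1 < gene.end):
            continue
        off = cds_offset(gene, site.pos)
        if off is None:
            return ConsequenceCall(gene.name, None, False)
        if site.is_indel:
            effect = ("frameshift" if site.indel_len % 3 != 0
                      else "inframe_indel")
            return ConsequenceCall(gene.name, effect, True)
        ci = off // 3
        within = off % 3
        codon = gene.cds_seq[3 * ci:3 * ci + 3]
        alt = site.alt if gene.strand == "+" else site.alt.translate(_COMP)
        new = codon[:within] + alt + codon[within + 1:]
        aa_old = str(Seq(codon).translate())
        aa_new = str(Seq(new).translate())
        if aa_new == aa_old:
            effect = "silent"
        elif aa_new == "*":
            effect = "nonsense"
        else:
            effect = "missense"
        return ConsequenceCall(gene.name, effect, effect != "silent")
    return ConsequenceCall(None, None, False)


def annotate_calls(calls: Iterable[VariantCall], genome: GenomeModel) -> None:
    for c in calls:
        cons = annotate_consequence(c, genome)
        c.gene, c.effect, c.non_silent = cons.gene, cons.effect, cons.non_silent


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageCount:
    stage: str
    n_in: int
    n_retained: int
    n_removed: int


@dataclass
class CascadeResult:
    calls: list[VariantCall]
    accounting: list[StageCount]

    @property
    def retained(self) -> list[VariantCall]:
        return [c for c in self.calls if c.passed]

    @property
    def removed(self) -> list[VariantCall]:
        return [c for c in self.calls if not c.passed]


def _site_from_row(row) -> SiteCounts:
    return SiteCounts(
        sample=row.sample, chrom=str(row.chrom), pos=int(row.pos),
        ref=str(row.ref), alt=str(row.alt),
        t_ref=int(row.t_ref), t_alt=int(row.t_alt),
        n_ref=int(row.n_ref), n_alt=int(row.n_alt),
        avg_qual=float(row.avg_qual), fwd_alt=int(row.fwd_alt),
        rev_alt=int(row.rev_alt), read_pos=float(row.read_pos),
        dist3p=float(row.dist3p), mapq_diff=float(row.mapq_diff),
        homopolymer_len=int(row.homopolymer_len),
        is_indel=bool(row.is_indel), indel_len=int(row.indel_len))


def run_cascade(counts: pd.DataFrame,
                cfg: VariantConfig = VariantConfig(),
                genome: GenomeModel | None = None) -> CascadeResult:
    """Run the full staged cascade over one sample pair's count table.

    Returns every input site as a :class:`VariantCall`, retained or removed
    with the first failing label per stage, plus per-stage accounting
    (in = retained + removed at every stage).
    """
    samples = counts["sample"].unique()
    if len(samples) > 1:
        raise ValueError("run_cascade expects one sample pair")
    accounting: list[StageCount] = []

    # basic screen, vectorized for scale
    t_depth = (counts["t_ref"] + counts["t_alt"]).to_numpy()
    n_depth = (counts["n_ref"] + counts["n_alt"]).to_numpy()
    t_vaf = counts["t_alt"].to_numpy() / np.maximum(t_depth, 1)
    qual = counts["avg_qual"].to_numpy(float)
    label = np.full(len(counts), "", dtype=object)
    label[qual < cfg.min_avg_qual] = "min_avg_qual"
    label[t_vaf < cfg.min_vaf] = "min_vaf"
    label[n_depth < cfg.min_coverage] = "min_coverage_normal"
    label[t_depth < cfg.min_coverage] = "min_coverage_tumor"

    calls: list[VariantCall] = []
    alive: list[VariantCall] = []
    for row, lab in zip(counts.itertuples(index=False), label):
        site = _site_from_row(row)
        call = VariantCall(site=site)
        if lab:
            call.filters.append(lab)
        else:
            alive.append(call)
        calls.append(call)
    accounting.append(StageCount("basic", len(calls), len(alive),
                                 len(calls) - len(alive)))

    # classification (no removal)
    for c in alive:
        cl = classify_site(c.site, cfg)
        c.category, c.somatic_p = cl.category, cl.somatic_p
        c.t_vaf, c.n_vaf = cl.t_vaf, cl.n_vaf

    # stage 1: low-quality somatic indels
    n_in = len(alive)
    nxt = []
    for c in alive:
        if c.category == "somatic" and c.site.is_indel:
            ok, lab = filter_indel(c, cfg)
            if not ok:
                c.filters.append(lab)
                continue
        nxt.append(c)
    alive = nxt
    accounting.append(StageCount("indel_quality", n_in, len(alive),
                                 n_in - len(alive)))

    # stage 2: proximity and cluster flags on surviving calls
    n_in = len(alive)
    flags = filter_proximity_and_clusters(alive, cfg)
    nxt = []
    for i, c in enumerate(alive):
        if i in flags:
            c.filters.extend(flags[i])
        else:
            nxt.append(c)
    alive = nxt
    accounting.append(StageCount("proximity_cluster", n_in, len(alive),
                                 n_in - len(alive)))

    # stage 3: somatic significance / normal contamination
    n_in = len(alive)
    nxt = []
    for c in alive:
        if c.category == "somatic":
            ok, lab = filter_somatic_quality(c, cfg)
            if not ok:
                c.filters.append(lab)
                continue
        nxt.append(c)
    alive = nxt
    accounting.append(StageCount("somatic_quality", n_in, len(alive),
                                 n_in - len(alive)))

    # stage 4: false-positive filter on germline and somatic calls
    n_in = len(alive)
    nxt = []
    for c in alive:
        if c.category in ("germline", "somatic"):
            ok, lab = fp_filter(c, cfg)
            if not ok:
                c.filters.append(lab)
                continue
        nxt.append(c)
    alive = nxt
    accounting.append(StageCount("fp_filter", n_in, len(alive),
                                 n_in - len(alive)))

    if genome is not None:
        annotate_calls(calls, genome)
    for st in accounting:
        logger.info("cascade stage %s: in=%d retained=%d removed=%d",
                    st.stage, st.n_in, st.n_retained, st.n_removed)
    return CascadeResult(calls=calls, accounting=accounting)


# ---------------------------------------------------------------------------
# cohort-level summaries
# ---------------------------------------------------------------------------

def mutation_rate(n_mutations: int, callable_bp: float) -> float:
    """Somatic mutations per callable base pair."""
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    return n_mutations / callable_bp


def median_rate(rates: Sequence[float]) -> float:
    """Cohort median; the lower middle value for even-sized cohorts."""
    if not rates:
        raise ValueError("no rates")
    s = sorted(rates)
    return s[(len(s) - 1) // 2]


@dataclass(frozen=True)
class GeneRecurrence:
    gene: str
    n_samples: int
    mutations: Mapping[str, tuple[str, ...]]  # sample -> labels


def recurrent_genes(calls: Iterable[VariantCall], min_samples: int = 2
                    ) -> list[GeneRecurrence]:
    """Genes with passed non-silent somatic mutations in >= ``min_samples``
    samples (a gene counts once per sample), sorted by support then name."""
    per_gene: dict[str, dict[str, list[str]]] = {}
    for c in calls:
        if not (c.passed and c.category == "somatic" and c.non_silent
                and c.gene):
            continue
        label = f"{c.site.ref}>{c.site.alt}@{c.site.chrom}:{c.site.pos}"
        per_gene.setdefault(c.gene, {}).setdefault(c.site.sample, []).append(label)
    out = [GeneRecurrence(gene=g, n_samples=len(bysample),
                          mutations={s: tuple(v) for s, v in bysample.items()})
           for g, bysample in per_gene.items()
           if len(bysample) >= min_samples]
    out.sort(key=lambda r: (-r.n_samples, r.gene))
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_FILTER_DESCR = {
    "min_coverage_tumor": "tumor depth below minimum",
    "min_coverage_normal": "normal depth below minimum",
    "min_vaf": "tumor variant allele frequency below minimum",
    "min_avg_qual": "mean variant base quality below minimum",
    "indel_coverage": "somatic indel coverage below minimum",
    "indel_support": "somatic indel supporting reads below minimum",
    "indel_germline_freq": "somatic indel germline frequency above maximum",
    "near_indel": "SNV within the indel proximity window",
    "snv_cluster": "SNV in a dense cluster",
    "somatic_fisher": "somatic Fisher p not significant",
    "somatic_normal_alt": "alt allele in normal above limit (SNV)",
    "somatic_normal_alt_indel": "alt allele present in normal (indel)",
    "fp_unscorable": "missing read-level quality fields",
    "fp_var_reads": "too few variant-supporting reads",
    "fp_var_freq": "variant frequency below false-positive-filter minimum",
    "fp_read_pos": "mean variant read position outside accepted range",
    "fp_dist3p": "variant too close to the 3' read end",
    "fp_strand_bias": "variant reads significantly strand biased",
    "fp_homopolymer": "variant in a long homopolymer run",
    "fp_mapq_diff": "variant reads map worse than reference reads",
}


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        s = c.site
        rows.append({
            "sample": s.sample, "chrom": s.chrom, "pos": s.pos,
            "ref": s.ref, "alt": s.alt, "category": c.category,
            "somatic_p": c.somatic_p, "t_vaf": c.t_vaf, "n_vaf": c.n_vaf,
            "t_ref": s.t_ref, "t_alt": s.t_alt,
            "n_ref": s.n_ref, "n_alt": s.n_alt,
            "is_indel": s.is_indel, "indel_len": s.indel_len,
            "gene": c.gene or "", "effect": c.effect or "",
            "non_silent": c.non_silent,
            "filter": ";".join(c.filters) if c.filters else "PASS",
        })
    return pd.DataFrame(rows)


def write_calls_tsv(calls: Iterable[VariantCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_vcf(calls: Sequence[VariantCall], genome: GenomeModel, path) -> None:
    """Write one sample pair's calls as an uncompressed VCF; FILTER carries
    the cascade labels, INFO the category, Fisher p and paired VAFs."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in genome.chromosomes:
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##INFO=<ID=CATEGORY,Number=1,Type=String,'
                    'Description="Paired classification">')
    header.add_line('##INFO=<ID=SOMATIC_P,Number=1,Type=Float,'
                    'Description="One-sided Fisher exact p (tumor alt enrichment)">')
    header.add_line('##INFO=<ID=TVAF,Number=1,Type=Float,'
                    'Description="Tumor variant allele frequency">')
    header.add_line('##INFO=<ID=NVAF,Number=1,Type=Float,'
                    'Description="Normal variant allele frequency">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">')
    header.add_line('##INFO=<ID=EFFECT,Number=1,Type=String,'
                    'Description="Coding consequence">')
    for label, descr in _FILTER_DESCR.items():
        header.add_line(f'##FILTER=<ID={label},Description="{descr}">')

    ordered = sorted(calls, key=lambda c: (c.site.chrom, c.site.pos))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in ordered:
            s = c.site
            rec = vcf.new_record(contig=s.chrom, start=s.pos - 1,
                                 alleles=(s.ref, s.alt))
            rec.info["CATEGORY"] = c.category
            if np.isfinite(c.somatic_p):
                rec.info["SOMATIC_P"] = float(c.somatic_p)
            if np.isfinite(c.t_vaf):
                rec.info["TVAF"] = float(c.t_vaf)
            if np.isfinite(c.n_vaf):
                rec.info["NVAF"] = float(c.n_vaf)
            if c.gene:
                rec.info["GENE"] = c.gene
            if c.effect:
                rec.info["EFFECT"] = c.effect
            if c.filters:
                for lab in c.filters:
                    rec.filter.add(lab)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)
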