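"""Synthetic genomes, SNP-array profiles and paired tumor-normal allele counts.

This module generates every input the analysis stages consume, together with
a recorded truth set, so segmentation, variant classification and evidence
integration can be validated against planted events without any external data.

The simulator emulates the measurable consequences of tumor biology on two
assay types:

* **SNP array** — per-probe LogR (log2 total-intensity ratio, 0 = diploid)
  and B-allele frequency (BAF).  In a tumor of purity ``p`` carrying a
  segmental event of integer copy number ``c`` in a fraction ``f`` of tumor
  cells, the expected LogR is ``log2((2 + p*f*(c - 2)) / 2)`` and the BAF of
  a heterozygous probe shifts away from 0.5 according to which parental
  allele is lost or gained.
* **Paired sequencing** — per-site tumor and normal ref/alt read counts with
  the read-level quality summaries a false-positive filter inspects.  Alt
  counts are binomial at the truth allelic fraction; somatic fractions are
  diluted by purity (a clonal heterozygous somatic variant at purity ``p``
  is expected at AF ``p/2``).

Coordinates are 0-based half-open for intervals and 1-based for point
positions (probes, variant sites), matching BED on one side and pileup
tables on the other.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["sample", "probe", "chrom", "pos", "logr", "baf"]
COUNT_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt",
    "t_ref", "t_alt", "n_ref", "n_alt",
    "avg_qual", "fwd_alt", "rev_alt", "read_pos", "dist3p",
    "mapq_diff", "homopolymer_len", "is_indel", "indel_len",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGT", "TGCA")
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_NONSTOP = [c for c in _CODONS if c not in _STOPS]


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """A gene with a toy coding model: exonic coding intervals plus the CDS
    sequence spelled on the coding strand (starts with ATG, no internal stop)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    coding: tuple[tuple[int, int], ...]
    cds_seq: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.coding)


@dataclass(frozen=True)
class GenomeModel:
    """Chromosomes, a tiling cytoband map, and toy genes."""

    chromosomes: tuple[tuple[str, int], ...]
    cytobands: tuple[tuple[str, int, int, str], ...]
    genes: tuple[Gene, ...]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"unknown gene {name!r}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def validate(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for _, length in self.chromosomes:
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")
        for chrom, length in self.chromosomes:
            bands = [b for b in self.cytobands if b[0] == chrom]
            if not bands:
                raise ValueError(f"chromosome {chrom} has no cytobands")
            bands = sorted(bands, key=lambda b: b[1])
            if bands[0][1] != 0 or bands[-1][2] != length:
                raise ValueError(f"cytobands do not tile chromosome {chrom}")
            for (_, _, e1, _), (_, s2, _, _) in zip(bands, bands[1:]):
                if e1 != s2:
                    raise ValueError(f"cytobands overlap or gap on {chrom}")
        lengths = dict(self.chromosomes)
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.name} on unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= lengths[g.chrom]):
                raise ValueError(f"gene {g.name} outside chromosome bounds")
            for s, e in g.coding:
                if not (g.start <= s < e <= g.end):
                    raise ValueError(f"coding interval of {g.name} outside gene")
            if g.cds_length != len(g.cds_seq):
                raise ValueError(f"CDS length mismatch for {g.name}")
            if g.cds_length % 3 != 0:
                raise ValueError(f"CDS of {g.name} not a codon multiple")


@dataclass(frozen=True)
class GenomeConfig:
    """Shape of the synthetic genome (a scaled stand-in for a real assembly:
    a few chromosomes with dense uniform probes instead of hg19)."""

    chromosomes: tuple[tuple[str, int], ...] = (
        ("1", 80_000_000), ("3", 60_000_000), ("22", 40_000_000))
    bands_per_chromosome: int = 8
    genes_per_chromosome: int = 20
    gene_length: int = 12_000
    exons_per_gene: int = 3
    exon_length: int = 402  # codon multiple
    named_genes: tuple[tuple[str, int, str], ...] = ()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP), size=n_codons - 1)
    return "ATG" + "".join(_NONSTOP[i] for i in idx)


def _make_gene(chrom: str, start: int, name: str, strand: str,
               cfg: GenomeConfig, rng: np.random.Generator) -> Gene:
    step = cfg.gene_length // cfg.exons_per_gene
    coding = tuple((start + j * step, start + j * step + cfg.exon_length)
                   for j in range(cfg.exons_per_gene))
    n_codons = cfg.exons_per_gene * cfg.exon_length // 3
    return Gene(chrom=chrom, start=start, end=start + cfg.gene_length,
                name=name, strand=strand, coding=coding,
                cds_seq=_random_cds(rng, n_codons))


def make_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Build a deterministic synthetic genome: cytobands that tile each
    chromosome and genes with toy coding structure."""
    cfg = config or GenomeConfig()
    if any(length <= 0 for _, length in cfg.chromosomes):
        raise ValueError("chromosome lengths must be positive")
    if cfg.bands_per_chromosome < 1:
        raise ValueError("bands_per_chromosome must be >= 1")
    rng = np.random.default_rng(seed)

    cytobands: list[tuple[str, int, int, str]] = []
    for chrom, length in cfg.chromosomes:
        k = cfg.bands_per_chromosome
        if k == 1:
            cuts: list[int] = []
        else:
            cuts = sorted(np.unique(
                np.round(np.sort(rng.uniform(0.03, 0.97, k - 1)) * length)
                .astype(int)))
        edges = [0, *cuts, length]
        n_p = len(edges) // 2  # bands on the p arm
        for i, (s, e) in enumerate(zip(edges, edges[1:])):
            band = (f"{chrom}p{n_p - i}" if i < n_p
                    else f"{chrom}q{i - n_p + 1}")
            cytobands.append((chrom, int(s), int(e), band))

    genes: list[Gene] = []
    named = {(c, s): n for c, s, n in cfg.named_genes}
    for chrom, start, name in cfg.named_genes:
        genes.append(_make_gene(chrom, start, name, "+", cfg, rng))
    for chrom, length in cfg.chromosomes:
        if cfg.genes_per_chromosome == 0:
            continue
        starts = np.sort(rng.integers(
            0, max(1, length - cfg.gene_length),
            size=cfg.genes_per_chromosome))
        last_end = -1
        for j, s in enumerate(starts):
            s = int(s)
            if s < last_end or (chrom, s) in named:
                continue  # drop overlapping placements
            if any(g.chrom == chrom and s < g.end and s + cfg.gene_length > g.start
                   for g in genes):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_make_gene(chrom, s, f"G{chrom}_{j:03d}", strand,
                                    cfg, rng))
            last_end = s + cfg.gene_length
    model = GenomeModel(chromosomes=tuple(cfg.chromosomes),
                        cytobands=tuple(cytobands), genes=tuple(genes))
    model.validate()
    return model


# -- coordinate / codon helpers ---------------------------------------------

def cds_offset(gene: Gene, pos: int) -> int | None:
    """Map a 1-based genomic position to a 0-based offset in the CDS, or
    None when the position is non-coding."""
    p0 = pos - 1
    off = 0
    for s, e in gene.coding:
        if s <= p0 < e:
            fwd = off + (p0 - s)
            return fwd if gene.strand == "+" else gene.cds_length - 1 - fwd
        off += e - s
    return None


def cds_offset_to_pos(gene: Gene, offset: int) -> int:
    """Inverse of :func:`cds_offset` (1-based genomic position)."""
    if not (0 <= offset < gene.cds_length):
        raise ValueError("CDS offset out of range")
    fwd = offset if gene.strand == "+" else gene.cds_length - 1 - offset
    off = 0
    for s, e in gene.coding:
        if fwd < off + (e - s):
            return s + (fwd - off) + 1
        off += e - s
    raise AssertionError("unreachable")


def genomic_base(gene: Gene, pos: int) -> str | None:
    """Reference base (genome strand) at a coding position, else None."""
    off = cds_offset(gene, pos)
    if off is None:
        return None
    b = gene.cds_seq[off]
    return b if gene.strand == "+" else b.translate(_COMP)


def stop_gain_substitution(gene: Gene, k: int = 0) -> tuple[int, str, str]:
    """The k-th substitution (scanning the CDS 5'->3') that turns a sense
    codon into a stop.  Returns (1-based genomic pos, ref, alt) on the
    genome strand."""
    found = 0
    for i in range(1, gene.cds_length // 3):
        codon = gene.cds_seq[3 * i:3 * i + 3]
        for j in range(3):
            for alt in _BASES:
                if alt == codon[j]:
                    continue
                if codon[:j] + alt + codon[j + 1:] in _STOPS:
                    if found == k:
                        off = 3 * i + j
                        pos = cds_offset_to_pos(gene, off)
                        ref, a = codon[j], alt
                        if gene.strand == "-":
                            ref = ref.translate(_COMP)
                            a = a.translate(_COMP)
                        return pos, ref, a
                    found += 1
    raise ValueError("not enough stop-gain candidates in CDS")


def silent_substitution(gene: Gene, k: int = 0) -> tuple[int, str, str]:
    """The k-th third-position substitution that preserves the amino acid."""
    from Bio.Seq import Seq

    found = 0
    for i in range(1, gene.cds_length // 3):
        codon = gene.cds_seq[3 * i:3 * i + 3]
        aa = str(Seq(codon).translate())
        for alt in _BASES:
            if alt == codon[2]:
                continue
            new = codon[:2] + alt
            if new not in _STOPS and str(Seq(new).translate()) == aa:
                if found == k:
                    pos = cds_offset_to_pos(gene, 3 * i + 2)
                    ref, a = codon[2], alt
                    if gene.strand == "-":
                        ref = ref.translate(_COMP)
                        a = a.translate(_COMP)
                    return pos, ref, a
                found += 1
    raise ValueError("not enough silent candidates in CDS")


def coding_deletion(gene: Gene, length: int, exon: int = 0,
                    offset_in_exon: int = 10) -> tuple[int, str, str, int]:
    """A deletion of ``length`` bp fully inside one coding exon.

    Returns (1-based anchor pos, ref, alt, indel_len) in left-anchored
    VCF style; ``indel_len`` is negative for deletions.
    """
    s, e = gene.coding[exon]
    if offset_in_exon + length + 1 > e - s:
        raise ValueError("deletion does not fit in exon")
    anchor0 = s + offset_in_exon  # 0-based anchor base, deletion follows
    # Spell bases from the genome strand via the CDS.
    bases = []
    for p0 in range(anchor0, anchor0 + length + 1):
        b = genomic_base(gene, p0 + 1)
        bases.append(b if b is not None else "A")
    ref = "".join(bases)
    return anchor0 + 1, ref, ref[0], -length


# ---------------------------------------------------------------------------
# truth set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNEvent:
    """A planted copy-number event: copy number ``cn`` in a fraction
    ``cell_fraction`` of tumor cells over [start, end)."""

    sample: str
    chrom: str
    start: int
    end: int
    cn: int
    cell_fraction: float = 1.0


@dataclass(frozen=True)
class VariantTruth:
    """A planted small variant.  ``target_af`` is the allelic fraction in
    tumor cells carrying the variant (0.5 for clonal heterozygous); the
    observable tumor AF of a somatic variant is diluted by purity.
    ``detection_efficiency`` < 1 drops a fraction of alt reads, emulating
    alignment dropout over long indels."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str  # germline_het | germline_hom | somatic
    target_af: float = 0.5
    is_indel: bool = False
    indel_len: int = 0
    detection_efficiency: float = 1.0


@dataclass(frozen=True)
class TruthSet:
    purity: float
    cn_events: tuple[CNEvent, ...] = ()
    variants: tuple[VariantTruth, ...] = ()

    def samples(self) -> list[str]:
        seen = {ev.sample for ev in self.cn_events}
        seen |= {v.sample for v in self.variants}
        return sorted(seen)

    def validate(self, genome: GenomeModel) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must be in [0, 1]")
        for ev in self.cn_events:
            length = genome.chrom_length(ev.chrom)
            if not (0 <= ev.start < ev.end <= length):
                raise ValueError(f"CN event outside {ev.chrom}: {ev}")
            if not (0.0 < ev.cell_fraction <= 1.0):
                raise ValueError("cell_fraction must be in (0, 1]")
            if ev.cn not in (0, 1, 2, 3):
                raise ValueError("copy number must be in {0,1,2,3}")
        for v in self.variants:
            length = genome.chrom_length(v.chrom)
            if not (1 <= v.pos <= length):
                raise ValueError(f"variant outside {v.chrom}: {v}")
            if not (0.0 < v.target_af <= 1.0):
                raise ValueError("target_af must be in (0, 1]")
            if v.origin not in ("germline_het", "germline_hom", "somatic"):
                raise ValueError(f"unknown origin {v.origin!r}")


# ---------------------------------------------------------------------------
# array simulation
# ---------------------------------------------------------------------------

def simulate_array(genome: GenomeModel, truth: TruthSet,
                   samples: Sequence[str] | None = None,
                   spacing: int = 50_000, noise_sd: float = 0.05,
                   seed: int = 0, het_prob: float = 0.3,
                   missing_rate: float = 0.0) -> pd.DataFrame:
    """Simulate per-probe LogR/BAF for each sample.

    Probes sit on a uniform grid (one per ``spacing`` bp).  Expected LogR in
    a region carrying copy number ``c`` in tumor-cell fraction ``f`` is
    ``log2((2 + purity*f*(c-2))/2)``; with noise 0 the values are exact, so
    closed-form checks hold to machine precision.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    truth.validate(genome)
    if samples is None:
        samples = truth.samples() or ["S1"]
    rng = np.random.default_rng(seed)
    p = truth.purity

    frames = []
    for sample in samples:
        events = [ev for ev in truth.cn_events if ev.sample == sample]
        for chrom, length in genome.chromosomes:
            pos = np.arange(spacing, length + 1, spacing, dtype=np.int64)
            n = len(pos)
            het = rng.random(n) < het_prob
            hom_b = (~het) & (rng.random(n) < 0.5)
            baf = np.where(het, 0.5, np.where(hom_b, 1.0, 0.0))
            logr = np.zeros(n)
            for ev in events:
                if ev.chrom != chrom:
                    continue
                m = (pos - 1 >= ev.start) & (pos - 1 < ev.end)
                q = p * ev.cell_fraction
                total = 2.0 + q * (ev.cn - 2)
                logr[m] = np.log2(max(total, 1e-3) / 2.0)
                hetm = m & het
                if ev.cn == 1:
                    # which haplotype is lost is random per probe
                    b_kept = rng.random(n) < 0.5
                    nb = np.where(b_kept, 1.0, 0.0)
                    baf[hetm] = ((1 - q) + q * nb[hetm]) / (2 - q)
                elif ev.cn == 3:
                    b_dup = rng.random(n) < 0.5
                    nb = np.where(b_dup, 2.0, 1.0)
                    baf[hetm] = ((1 - q) + q * nb[hetm]) / (2 + q)
                # cn 0: het BAF stays 0.5, hom stays 0/1 (exact mixture)
            if noise_sd > 0:
                logr = logr + rng.normal(0.0, noise_sd, n)
                baf = np.clip(baf + rng.normal(0.0, noise_sd, n), 0.0, 1.0)
            if missing_rate > 0:
                logr = np.where(rng.random(n) < missing_rate, np.nan, logr)
            frames.append(pd.DataFrame({
                "sample": sample,
                "probe": [f"p_{chrom}_{x}" for x in pos],
                "chrom": chrom, "pos": pos, "logr": logr, "baf": baf,
            }))
    return pd.concat(frames, ignore_index=True)[PROBE_COLUMNS]


# ---------------------------------------------------------------------------
# paired count simulation
# ---------------------------------------------------------------------------

def _quality_block(rng: np.random.Generator, n: int, alt: np.ndarray,
                   base_qual: float) -> dict[str, np.ndarray]:
    return {
        "avg_qual": np.clip(rng.normal(base_qual, 2.0, n), 10.0, 41.0),
        "fwd_alt": rng.binomial(alt, 0.5),
        "read_pos": np.clip(rng.normal(0.5, 0.05, n), 0.0, 1.0),
        "dist3p": np.clip(rng.normal(0.5, 0.05, n), 0.0, 1.0),
        "mapq_diff": rng.normal(0.0, 1.0, n),
        "homopolymer_len": rng.integers(1, 4, n),
    }


def simulate_counts(genome: GenomeModel, truth: TruthSet,
                    mean_depth: float = 100.0, seed: int = 0,
                    error_rate: float = 1e-3,
                    n_background_sites: int = 0,
                    samples: Sequence[str] | None = None,
                    base_qual: float = 34.0) -> pd.DataFrame:
    """Simulate the per-site tumor/normal count table a paired pileup
    comparison would consume.

    Germline variants appear in both members of a pair; somatic alt
    fractions are ``target_af * purity``; background sites carry alt reads
    only through the per-base ``error_rate``.
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    truth.validate(genome)
    if samples is None:
        samples = truth.samples() or ["S1"]
    rng = np.random.default_rng(seed)
    p = truth.purity

    rows: list[dict] = []
    for v in truth.variants:
        if v.sample not in samples:
            continue
        nd = max(1, int(rng.poisson(mean_depth)))
        td = max(1, int(rng.poisson(mean_depth)))
        if v.origin == "germline_het":
            n_af = t_af = 0.5
        elif v.origin == "germline_hom":
            n_af = t_af = 1.0 - error_rate
        else:
            n_af = error_rate
            t_af = min(1.0, v.target_af * p)
        n_alt = int(rng.binomial(nd, n_af))
        t_alt = int(rng.binomial(td, t_af))
        if v.detection_efficiency < 1.0:
            kept = int(rng.binomial(t_alt, v.detection_efficiency))
            td = td - t_alt + kept
            t_alt = kept
        q = _quality_block(rng, 1, np.array([t_alt]), base_qual)
        rows.append({
            "sample": v.sample, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt,
            "t_ref": td - t_alt, "t_alt": t_alt,
            "n_ref": nd - n_alt, "n_alt": n_alt,
            "avg_qual": float(q["avg_qual"][0]),
            "fwd_alt": int(q["fwd_alt"][0]),
            "rev_alt": t_alt - int(q["fwd_alt"][0]),
            "read_pos": float(q["read_pos"][0]),
            "dist3p": float(q["dist3p"][0]),
            "mapq_diff": float(q["mapq_diff"][0]),
            "homopolymer_len": int(q["homopolymer_len"][0]),
            "is_indel": v.is_indel, "indel_len": v.indel_len,
        })
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)

    if n_background_sites > 0:
        chroms = [c for c, _ in genome.chromosomes]
        lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
        probs = lengths / lengths.sum()
        blocks = []
        for sample in samples:
            n = n_background_sites
            ci = rng.choice(len(chroms), size=n, p=probs)
            pos = (rng.random(n) * lengths[ci]).astype(np.int64) + 1
            nd = np.maximum(1, rng.poisson(mean_depth, n))
            td = np.maximum(1, rng.poisson(mean_depth, n))
            n_alt = rng.binomial(nd, error_rate)
            t_alt = rng.binomial(td, error_rate)
            refs = rng.integers(0, 4, n)
            alts = (refs + rng.integers(1, 4, n)) % 4
            q = _quality_block(rng, n, t_alt, base_qual)
            blocks.append(pd.DataFrame({
                "sample": sample,
                "chrom": np.array(chroms, dtype=object)[ci],
                "pos": pos,
                "ref": np.array(list(_BASES), dtype=object)[refs],
                "alt": np.array(list(_BASES), dtype=object)[alts],
                "t_ref": td - t_alt, "t_alt": t_alt,
                "n_ref": nd - n_alt, "n_alt": n_alt,
                "avg_qual": q["avg_qual"], "fwd_alt": q["fwd_alt"],
                "rev_alt": t_alt - q["fwd_alt"],
                "read_pos": q["read_pos"], "dist3p": q["dist3p"],
                "mapq_diff": q["mapq_diff"],
                "homopolymer_len": q["homopolymer_len"],
                "is_indel": False, "indel_len": 0,
            }))
        frames = [b for b in (df, *blocks) if not b.empty]
        df = pd.concat(frames, ignore_index=True)

    return (df.sort_values(["sample", "chrom", "pos"], kind="mergesort")
              .reset_index(drop=True))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_probes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_probes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})


def write_cytoband_bed(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, name in genome.cytobands:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_gene_bed(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        for g in genome.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def genome_to_dict(genome: GenomeModel) -> dict:
    return {
        "chromosomes": [list(c) for c in genome.chromosomes],
        "cytobands": [list(b) for b in genome.cytobands],
        "genes": [{**asdict(g), "coding": [list(iv) for iv in g.coding]}
                  for g in genome.genes],
    }


def genome_from_dict(d: Mapping) -> GenomeModel:
    genes = tuple(Gene(chrom=g["chrom"], start=g["start"], end=g["end"],
                       name=g["name"], strand=g["strand"],
                       coding=tuple(tuple(iv) for iv in g["coding"]),
                       cds_seq=g["cds_seq"])
                  for g in d["genes"])
    return GenomeModel(
        chromosomes=tuple((c, int(l)) for c, l in d["chromosomes"]),
        cytobands=tuple((c, int(s), int(e), n) for c, s, e, n in d["cytobands"]),
        genes=genes)


def write_genome_json(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(genome_to_dict(genome), fh, indent=1)


def read_genome_json(path) -> GenomeModel:
    with open(path) as fh:
        return genome_from_dict(json.load(fh))


def truth_to_dict(truth: TruthSet) -> dict:
    return {"purity": truth.purity,
            "cn_events": [asdict(e) for e in truth.cn_events],
            "variants": [asdict(v) for v in truth.variants]}


def truth_from_dict(d: Mapping) -> TruthSet:
    return TruthSet(purity=d["purity"],
                    cn_events=tuple(CNEvent(**e) for e in d["cn_events"]),
                    variants=tuple(VariantTruth(**v) for v in d["variants"]))


def write_truth_json(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_to_dict(truth), fh, indent=1)


def read_truth_json(path) -> TruthSet:
    with open(path) as fh:
        return truth_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# study-design cohort builder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """The simulated study design: a 12-sample cohort in which a target
    tumor-suppressor gene is altered by somatic mutation only, segmental or
    whole-chromosome loss only, both, or neither.

    Defaults model tumors of >= 70% purity sequenced at ~100x with SNP-array
    LogR noise of 0.05, a genome-wide somatic rate of 1.3 per Mb, and a
    recurrently deleted 15 Mb region around the target gene.
    """

    n_mutation_only: int = 3
    n_loss_only: int = 3
    n_both: int = 2
    n_none: int = 4
    purity: float = 0.7
    mean_depth: float = 100.0
    noise_sd: float = 0.05
    probe_spacing: int = 50_000
    error_rate: float = 1e-3
    somatic_rate_per_bp: float = 1.3e-6
    n_germline_het: int = 30
    target_gene: str = "BAP1"
    loss_chrom: str = "3"
    loss_start: int = 2_000_000
    loss_size: int = 15_000_000
    clonal_af: float = 0.5
    subclonal_cell_fraction: float = 0.5
    long_indel_len: int = 42
    indel_detection_efficiency: float = 0.6
    missing_rate: float = 0.0


@dataclass(frozen=True)
class Cohort:
    genome: GenomeModel
    truth: TruthSet
    categories: Mapping[str, str]   # planted per-sample gene status
    assays: Mapping[str, tuple[str, ...]]


def build_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Plant the full study design and return genome + truth + expected
    per-sample category for the target gene."""
    cfg = config or CohortConfig()
    genome = make_genome(GenomeConfig(
        named_genes=((cfg.loss_chrom, 9_000_000, cfg.target_gene),)), seed=seed)
    gene = genome.gene(cfg.target_gene)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))

    n_total = cfg.n_mutation_only + cfg.n_loss_only + cfg.n_both + cfg.n_none
    names = [f"S{i + 1:02d}" for i in range(n_total)]
    cats = (["mutation_only"] * cfg.n_mutation_only
            + ["loss_only"] * cfg.n_loss_only
            + ["both"] * cfg.n_both
            + ["none"] * cfg.n_none)
    categories = dict(zip(names, cats))
    assays = {s: ("array", "exome", "targeted") for s in names}

    # The planted segmental loss models a recurrently deleted cytoband:
    # widen the nominal interval so the band holding the gene is fully
    # covered (the >75%-of-band rule then sees the event in every carrier).
    loss_start, loss_end = cfg.loss_start, cfg.loss_start + cfg.loss_size
    band = next(b for b in genome.cytobands
                if b[0] == cfg.loss_chrom and b[1] <= gene.midpoint < b[2])
    loss_start = min(loss_start, band[1])
    loss_end = max(loss_end, band[2])
    chrom_len = genome.chrom_length(cfg.loss_chrom)
    events: list[CNEvent] = []
    variants: list[VariantTruth] = []
    stop_k = 0

    loss_samples = [s for s in names if categories[s] == "loss_only"]
    both_samples = [s for s in names if categories[s] == "both"]
    mut_samples = [s for s in names if categories[s] == "mutation_only"]

    for i, s in enumerate(loss_samples):
        if i == len(loss_samples) - 1:
            # whole-chromosome loss; its carrier also bears a germline
            # nonsense in the target gene (predisposition-style finding)
            events.append(CNEvent(s, cfg.loss_chrom, 0, chrom_len, 1))
            pos, ref, alt = stop_gain_substitution(gene, k=stop_k); stop_k += 1
            variants.append(VariantTruth(s, gene.chrom, pos, ref, alt,
                                         "germline_het"))
        else:
            events.append(CNEvent(s, cfg.loss_chrom, loss_start, loss_end, 1))

    for s in mut_samples:
        pos, ref, alt = stop_gain_substitution(gene, k=stop_k); stop_k += 1
        variants.append(VariantTruth(s, gene.chrom, pos, ref, alt, "somatic",
                                     target_af=cfg.clonal_af))

    for i, s in enumerate(both_samples):
        if i == 0:
            # clonal loss + long in-frame deletion with alignment dropout
            events.append(CNEvent(s, cfg.loss_chrom, loss_start, loss_end, 1))
            pos, ref, alt, ilen = coding_deletion(gene, cfg.long_indel_len)
            variants.append(VariantTruth(
                s, gene.chrom, pos, ref, alt, "somatic",
                target_af=cfg.clonal_af, is_indel=True, indel_len=ilen,
                detection_efficiency=cfg.indel_detection_efficiency))
        else:
            # subclonal loss + subclonal nonsense
            events.append(CNEvent(s, cfg.loss_chrom, loss_start, loss_end, 1,
                                  cell_fraction=cfg.subclonal_cell_fraction))
            pos, ref, alt = stop_gain_substitution(gene, k=stop_k); stop_k += 1
            variants.append(VariantTruth(
                s, gene.chrom, pos, ref, alt, "somatic",
                target_af=cfg.clonal_af * cfg.subclonal_cell_fraction))

    # genome-wide passengers and germline heterozygous background
    chroms = [c for c, _ in genome.chromosomes]
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    genes_by_chrom: dict[str, list[Gene]] = {}
    for g in genome.genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    def draw_site(sample: str, used: set) -> tuple[str, int, str, str] | None:
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        pos = int(rng.integers(1, int(lengths[ci]) + 1))
        if (sample, chrom, pos) in used:
            return None
        if chrom == gene.chrom and gene.start <= pos - 1 < gene.end:
            return None  # keep the target gene clean of passengers
        ref = None
        for g in genes_by_chrom.get(chrom, []):
            if g.start <= pos - 1 < g.end:
                ref = genomic_base(g, pos)
                break
        if ref is None:
            ref = _BASES[int(rng.integers(0, 4))]
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        used.add((sample, chrom, pos))
        return chrom, pos, ref, alt

    used: set = {(v.sample, v.chrom, v.pos) for v in variants}
    for s in names:
        n_pass = int(rng.poisson(cfg.somatic_rate_per_bp * genome.total_length))
        for _ in range(n_pass):
            site = draw_site(s, used)
            if site is None:
                continue
            chrom, pos, ref, alt = site
            variants.append(VariantTruth(s, chrom, pos, ref, alt, "somatic",
                                         target_af=cfg.clonal_af))
        for _ in range(cfg.n_germline_het):
            site = draw_site(s, used)
            if site is None:
                continue
            chrom, pos, ref, alt = site
            variants.append(VariantTruth(s, chrom, pos, ref, alt, "germline_het"))

    truth = TruthSet(purity=cfg.purity, cn_events=tuple(events),
                     variants=tuple(variants))
    truth.validate(genome)
    return Cohort(genome=genome, truth=truth, categories=categories,
                  assays=assays)
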