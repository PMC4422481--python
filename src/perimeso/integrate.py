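"""Integration of copy-number, somatic-mutation and germline evidence into a
per-sample gene status table and a cohort summary.

Evidence for a target gene is gathered per sample from the assays that
sample actually received (copy-number array ``A``, whole-exome sequencing
``E``, targeted sequencing ``T``): a deleted segment containing the gene is
loss evidence; passed somatic calls in the gene are mutation evidence;
germline loss-of-function variants are reported but do not by themselves
make a sample "altered".  Each sample lands in exactly one category:
``both`` (loss and at least one somatic mutation), ``mutation_only``,
``loss_only`` or ``none``.

Subclonality is flagged quantitatively: a somatic allelic fraction below
half the clonal-heterozygous expectation (purity/2), or a deleted segment
whose |mean LogR| is below half the clonal one-copy expectation
|log2(1 - purity/2)|.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cna import Segment

ASSAY_LETTER = {"array": "A", "exome": "E", "targeted": "T"}
LETTER_ASSAY = {v: k for k, v in ASSAY_LETTER.items()}
ASSAY_ORDER = ("array", "exome", "targeted")

CATEGORIES = ("mutation_only", "loss_only", "both", "none")


@dataclass(frozen=True)
class LossEvidence:
    """A copy-number loss over the gene: segment size, whole-chromosome
    marker (chromosome name) when the segment spans the probed chromosome,
    and a subclonal marker when the amplitude is below the clonal
    expectation."""

    size_bp: int | None = None
    whole_chromosome: str | None = None
    subclonal: bool = False


@dataclass(frozen=True)
class SomaticEvidence:
    """One somatic mutation with its allelic fraction per assay."""

    label: str
    af: tuple[tuple[str, float], ...]  # (assay, fraction), assay order

    def af_dict(self) -> dict[str, float]:
        return dict(self.af)


@dataclass(frozen=True)
class SampleGeneStatus:
    sample: str
    assays: tuple[str, ...]
    germline_variant: str | None
    loss: LossEvidence | None
    somatic_mutations: tuple[SomaticEvidence, ...]
    subclonal: bool
    category: str


@dataclass(frozen=True)
class CohortSummary:
    n_samples: int
    n_mutation_only: int
    n_loss_only: int
    n_both: int
    n_altered: int
    fraction_altered: float
    percent_altered: int  # truncated to the integer


def _categorize(loss: LossEvidence | None,
                mutations: Sequence[SomaticEvidence]) -> str:
    if loss is not None and mutations:
        return "both"
    if mutations:
        return "mutation_only"
    if loss is not None:
        return "loss_only"
    return "none"


def status_from_evidence(sample: str, assays: Iterable[str],
                         germline_variant: str | None = None,
                         loss: LossEvidence | None = None,
                         mutations: Sequence[SomaticEvidence] = (),
                         purity: float = 0.7,
                         subclonal_af_factor: float = 0.5) -> SampleGeneStatus:
    """Derive category and subclonality flag from assembled evidence."""
    assays = tuple(a for a in ASSAY_ORDER if a in set(assays))
    if not assays:
        raise ValueError("sample must declare at least one assay")
    if loss is not None and not ({"array", "exome"} & set(assays)):
        raise ValueError("loss evidence requires the array or exome assay")
    if mutations and not ({"exome", "targeted"} & set(assays)):
        raise ValueError("mutation evidence requires a sequencing assay")
    clonal_af = purity / 2.0
    af_subclonal = any(f < subclonal_af_factor * clonal_af
                       for m in mutations for _, f in m.af)
    subclonal = af_subclonal or (loss is not None and loss.subclonal)
    return SampleGeneStatus(
        sample=sample, assays=assays, germline_variant=germline_variant,
        loss=loss, somatic_mutations=tuple(mutations), subclonal=subclonal,
        category=_categorize(loss, mutations))


def assemble_status(sample: str, assays: Iterable[str], gene,
                    segments: Sequence[Segment] = (),
                    somatic_calls: Sequence = (),
                    germline_variants: Sequence = (),
                    external_mutations: Sequence[SomaticEvidence] = (),
                    purity: float = 0.7,
                    subclonal_af_factor: float = 0.5,
                    subclonal_logr_factor: float = 0.5,
                    whole_chromosome_fraction: float = 0.95
                    ) -> SampleGeneStatus:
    """Assemble one sample's status for ``gene`` from called segments,
    passed somatic calls (exome) and externally provided mutation records
    (targeted assay for samples without exome data).

    Evidence may only come from declared assays; providing segments for a
    sample without the array (or exome) assay is an error.
    """
    assay_set = set(assays)
    segments = [s for s in segments if s.sample == sample]
    if segments and not ({"array", "exome"} & assay_set):
        raise ValueError(
            f"segment evidence for {sample} without an array/exome assay")

    mid = (gene.start + gene.end) // 2
    loss: LossEvidence | None = None
    hit = next((s for s in segments
                if s.chrom == gene.chrom and s.status == "deleted"
                and s.start <= mid < s.end), None)
    if hit is not None:
        chrom_segs = [s for s in segments if s.chrom == gene.chrom]
        span = (max(s.end for s in chrom_segs)
                - min(s.start for s in chrom_segs))
        whole = hit.length >= whole_chromosome_fraction * span
        clonal_amp = abs(math.log2(1.0 - purity / 2.0))
        sub = abs(hit.mean_logr) < subclonal_logr_factor * clonal_amp
        loss = LossEvidence(size_bp=hit.length,
                            whole_chromosome=gene.chrom if whole else None,
                            subclonal=sub)

    mutations: list[SomaticEvidence] = []
    for c in somatic_calls:
        if c.site.sample != sample:
            continue
        if "exome" not in assay_set:
            raise ValueError(f"somatic exome call for {sample} without exome")
        label = (f"{c.site.ref}>{c.site.alt}@{c.site.pos}" if not c.effect
                 else f"{c.effect}@{c.site.pos}")
        mutations.append(SomaticEvidence(label=label,
                                         af=(("exome", float(c.t_vaf)),)))
    mutations.extend(external_mutations)

    germline = None
    for g in germline_variants:
        germline = g if isinstance(g, str) else \
            f"{g.effect or 'variant'}@{g.site.pos}"
        break

    return status_from_evidence(sample, assay_set, germline, loss, mutations,
                                purity=purity,
                                subclonal_af_factor=subclonal_af_factor)


def cohort_summary(statuses: Sequence[SampleGeneStatus]) -> CohortSummary:
    """Counts per category and the altered fraction (also rendered as a
    truncated integer percentage)."""
    if not statuses:
        raise ValueError("empty cohort")
    n = len(statuses)
    n_mut = sum(s.category == "mutation_only" for s in statuses)
    n_loss = sum(s.category == "loss_only" for s in statuses)
    n_both = sum(s.category == "both" for s in statuses)
    n_alt = n_mut + n_loss + n_both
    return CohortSummary(n_samples=n, n_mutation_only=n_mut,
                         n_loss_only=n_loss, n_both=n_both, n_altered=n_alt,
                         fraction_altered=n_alt / n,
                         percent_altered=int(100 * n_alt / n))


# ---------------------------------------------------------------------------
# rendering / parsing (round-trippable status table)
# ---------------------------------------------------------------------------

def _format_af(f: float) -> str:
    return f"{round(f * 100):d}%"


def _render_loss(status: SampleGeneStatus) -> str:
    if "array" not in status.assays:
        return "NA"
    loss = status.loss
    if loss is None:
        return ""
    if loss.whole_chromosome:
        return f"chr{loss.whole_chromosome}"
    if loss.subclonal:
        return "subclonal"
    return f"{loss.size_bp / 1e6:g} Mb"


def _render_somatic(status: SampleGeneStatus) -> str:
    parts = []
    for m in status.somatic_mutations:
        afs = list(m.af)
        if len(afs) == 1:
            parts.append(f"{m.label} ({_format_af(afs[0][1])})")
        else:
            inner = ", ".join(f"{ASSAY_LETTER[a]}:{_format_af(f)}"
                              for a, f in afs)
            parts.append(f"{m.label} ({inner})")
    return "; ".join(parts)


def render_status_table(statuses: Sequence[SampleGeneStatus]) -> pd.DataFrame:
    """One row per sample in the published table style: assay string in
    A/E/T notation, NA for cells whose assay was not run, blank for
    assayed-but-negative."""
    rows = []
    for s in statuses:
        rows.append({
            "sample": s.sample,
            "assays": " + ".join(ASSAY_LETTER[a] for a in s.assays),
            "germline": ("NA" if "exome" not in s.assays
                         else (s.germline_variant or "")),
            "loh": _render_loss(s),
            "somatic": _render_somatic(s),
            "category": s.category,
        })
    return pd.DataFrame(rows, columns=["sample", "assays", "germline",
                                       "loh", "somatic", "category"])


_MUT_RE = re.compile(r"^(?P<label>.+?) \((?P<afs>[^)]*)\)$")


def _parse_somatic(cell: str, assays: tuple[str, ...]
                   ) -> tuple[SomaticEvidence, ...]:
    if not cell:
        return ()
    out = []
    for part in cell.split("; "):
        m = _MUT_RE.match(part)
        if not m:
            raise ValueError(f"unparseable mutation cell {part!r}")
        afs = []
        for token in m.group("afs").split(", "):
            if ":" in token:
                letter, pct = token.split(":")
                assay = LETTER_ASSAY[letter]
            else:
                pct = token
                assay = "exome" if "exome" in assays else "targeted"
            afs.append((assay, float(pct.rstrip("%")) / 100.0))
        out.append(SomaticEvidence(label=m.group("label"), af=tuple(afs)))
    return tuple(out)


def parse_status_table(df: pd.DataFrame, purity: float = 0.7,
                       subclonal_af_factor: float = 0.5
                       ) -> list[SampleGeneStatus]:
    """Read a rendered status table back into statuses (the categories are
    re-derived from the parsed evidence, so integration is idempotent on
    its own output)."""
    statuses = []
    for r in df.itertuples(index=False):
        assays = tuple(LETTER_ASSAY[t] for t in str(r.assays).split(" + "))
        germline = None if str(r.germline) in ("", "NA") else str(r.germline)
        cell = str(r.loh)
        if cell in ("", "NA"):
            loss = None
        elif cell.startswith("chr"):
            loss = LossEvidence(whole_chromosome=cell[3:])
        elif cell == "subclonal":
            loss = LossEvidence(subclonal=True)
        else:
            size = int(round(float(cell.split(" ")[0]) * 1e6))
            loss = LossEvidence(size_bp=size)
        mutations = _parse_somatic(str(r.somatic), assays)
        statuses.append(status_from_evidence(
            str(r.sample), assays, germline, loss, mutations,
            purity=purity, subclonal_af_factor=subclonal_af_factor))
    return statuses


def write_status_table(statuses: Sequence[SampleGeneStatus], path) -> None:
    render_status_table(statuses).to_csv(path, sep="\t", index=False)


def read_status_table(path, purity: float = 0.7) -> list[SampleGeneStatus]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return parse_status_table(df, purity=purity)


def write_summary_json(summary: CohortSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.__dict__, fh, indent=1)
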