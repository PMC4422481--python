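"""Copy-number analysis from SNP-array LogR/BAF profiles.

The stages mirror an array-based tumor copy-number workflow:

1. drop probes with a missing LogR in any sample of the cohort,
2. optionally re-center each sample's LogR on allelically balanced
   chromosomes (robust to whole-chromosome aneuploidy, which can be masked
   when normalization centers on an aneuploid genome),
3. segment each chromosome by an exact penalized least-squares
   piecewise-constant fit (dynamic programming over breakpoints),
4. call segments amplified (mean LogR > 0.25) / deleted (< -0.25) and flag
   loss of heterozygosity when the mean mirrored BAF over heterozygous-
   informative probes exceeds 0.55,
5. summarize per-sample burden over large (> 1 Mb) segments, score
   cytoband recurrence (> 75% of band length deleted/amplified), and compute
   per-gene net LogR / net mirrored-BAF sums across samples.

Mirrored BAF is max(b, 1-b): under allelic imbalance the raw BAF of
heterozygous probes splits symmetrically around 0.5, and folding the split
into the upper tail turns it into a one-sided LOH statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LOGR_THRESHOLD = 0.25
BAF_THRESHOLD = 0.55
CYTOBAND_FRACTION = 0.75
HET_BAND = (0.15, 0.85)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_probes",
               "mean_logr", "mean_mirrored_baf", "status", "loh"]


@dataclass(frozen=True)
class Segment:
    """A contiguous constant-copy-number interval (0-based half-open)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_probes: int
    mean_logr: float
    mean_mirrored_baf: float  # NaN when no informative probe
    status: str = "neutral"   # neutral | deleted | amplified
    loh: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# probe-level steps
# ---------------------------------------------------------------------------

def filter_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Retain a probe only if its LogR is non-missing in every sample.

    Order is preserved; the rule is applied cohort-wide so all samples keep
    an identical probe grid.
    """
    if probes.empty:
        return probes.copy()
    n_samples = probes["sample"].nunique()
    ok = (probes.assign(_ok=probes["logr"].notna())
          .groupby(["chrom", "pos"])["_ok"].transform("sum"))
    cnt = probes.groupby(["chrom", "pos"])["logr"].transform("size")
    keep = (ok == n_samples) & (cnt == n_samples)
    return probes.loc[keep.to_numpy()].reset_index(drop=True)


def _informative_mirrored(baf: np.ndarray,
                          het_band: tuple[float, float] = HET_BAND) -> np.ndarray:
    lo, hi = het_band
    b = baf[np.isfinite(baf) & (baf > lo) & (baf < hi)]
    return np.maximum(b, 1.0 - b)


def center_logr(probes: pd.DataFrame,
                baf_threshold: float = BAF_THRESHOLD,
                het_band: tuple[float, float] = HET_BAND) -> pd.DataFrame:
    """Median-center LogR per sample using only chromosomes whose mirrored
    BAF shows no allelic imbalance.

    Centering on balanced chromosomes keeps a whole-chromosome loss visible:
    a global median would drag an aneuploid genome back toward LogR 0.
    """
    out = probes.copy()
    for sample, sdf in probes.groupby("sample", sort=False):
        balanced: list[str] = []
        for chrom, cdf in sdf.groupby("chrom", sort=False):
            m = _informative_mirrored(cdf["baf"].to_numpy(float), het_band)
            if len(m) == 0 or float(np.mean(m)) <= baf_threshold:
                balanced.append(chrom)
        mask = out["sample"] == sample
        sel = sdf["chrom"].isin(balanced) if balanced else slice(None)
        ref = sdf.loc[sel, "logr"] if balanced else sdf["logr"]
        offset = float(np.nanmedian(ref.to_numpy(float)))
        out.loc[mask, "logr"] = out.loc[mask, "logr"] - offset
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_values(y: np.ndarray, penalty: float) -> list[tuple[int, int]]:
    """Exact minimizer of  sum of squared deviations + penalty * breakpoints.

    Dynamic programming over all partitions of ``y`` into contiguous runs;
    returns half-open index intervals.  O(n^2) with a vectorized inner loop.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return []
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    best = np.empty(n + 1)
    best[0] = -penalty  # first segment carries no breakpoint cost
    prev = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        i = np.arange(j)
        sse = np.maximum(s2[j] - s2[i] - (s1[j] - s1[i]) ** 2 / (j - i), 0.0)
        tot = best[:j] + sse + penalty
        k = int(np.argmin(tot))
        best[j] = tot[k]
        prev[j] = k
    cuts = []
    j = n
    while j > 0:
        cuts.append((prev[j], j))
        j = prev[j]
    return cuts[::-1]


def _auto_penalty(y: np.ndarray, gamma: float) -> float:
    """Default penalty gamma * sd^2 * log(n) with sd from a robust
    first-difference estimate (MAD-based, insensitive to true jumps)."""
    n = len(y)
    if n < 2:
        return 1e-6
    d = np.diff(y)
    sd = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)
    return max(gamma * sd * sd * math.log(n), 1e-6)


def segment_profile(probes: pd.DataFrame, penalty: float | None = None,
                    gamma: float = 40.0,
                    het_band: tuple[float, float] = HET_BAND) -> list[Segment]:
    """Segment one sample's probe profile per chromosome.

    ``probes`` must hold a single sample sorted by (chrom, pos).  Segment
    boundaries fall at midpoints between flanking probes, so segments tile
    the probed span of each chromosome.
    """
    if penalty is not None and penalty <= 0:
        raise ValueError("penalty must be positive")
    samples = probes["sample"].unique()
    if len(samples) != 1:
        raise ValueError("segment_profile expects exactly one sample")
    grp = probes.groupby("chrom", sort=False)
    for _, cdf in grp:
        if not cdf["pos"].is_monotonic_increasing:
            raise ValueError("probes must be sorted by (chrom, pos)")

    clean = probes[probes["logr"].notna()]
    if penalty is None:
        penalty = _auto_penalty(clean["logr"].to_numpy(float), gamma)

    segments: list[Segment] = []
    for chrom, cdf in clean.groupby("chrom", sort=False):
        pos = cdf["pos"].to_numpy(np.int64)
        y = cdf["logr"].to_numpy(float)
        baf = cdf["baf"].to_numpy(float)
        pieces = segment_values(y, penalty)
        # breakpoint coordinates: midpoints between adjacent probes (0-based)
        bounds = np.empty(len(pos) + 1, dtype=np.int64)
        bounds[0] = pos[0] - 1
        bounds[-1] = pos[-1]
        if len(pos) > 1:
            bounds[1:-1] = (pos[:-1] + pos[1:] - 2) // 2 + 1
        for i, j in pieces:
            m = _informative_mirrored(baf[i:j], het_band)
            segments.append(Segment(
                sample=samples[0], chrom=chrom,
                start=int(bounds[i]), end=int(bounds[j]),
                n_probes=j - i, mean_logr=float(np.mean(y[i:j])),
                mean_mirrored_baf=float(np.mean(m)) if len(m) else float("nan")))
    return segments


# ---------------------------------------------------------------------------
# calling & summaries
# ---------------------------------------------------------------------------

def call_segments(segments: Iterable[Segment],
                  logr_threshold: float = LOGR_THRESHOLD,
                  baf_threshold: float = BAF_THRESHOLD) -> list[Segment]:
    """Apply the amplification/deletion LogR thresholds (strict) and the
    mirrored-BAF LOH threshold (strict)."""
    out = []
    for seg in segments:
        if seg.mean_logr > logr_threshold:
            status = "amplified"
        elif seg.mean_logr < -logr_threshold:
            status = "deleted"
        else:
            status = "neutral"
        loh = (np.isfinite(seg.mean_mirrored_baf)
               and seg.mean_mirrored_baf > baf_threshold)
        out.append(replace(seg, status=status, loh=bool(loh)))
    return out


@dataclass(frozen=True)
class SampleBurden:
    sample: str
    bp_lost: int
    bp_gained: int
    n_lost: int
    n_gained: int


def summarize_sample(segments: Iterable[Segment],
                     min_size: int = 1_000_000) -> SampleBurden:
    """Cumulative base pairs lost/gained in large (length > min_size)
    segments, with segment counts."""
    segs = list(segments)
    samples = {s.sample for s in segs}
    if len(samples) > 1:
        raise ValueError("summarize_sample expects one sample")
    sample = samples.pop() if samples else ""
    big = [s for s in segs if s.length > min_size]
    lost = [s for s in big if s.status == "deleted"]
    gained = [s for s in big if s.status == "amplified"]
    return SampleBurden(sample=sample,
                        bp_lost=sum(s.length for s in lost),
                        bp_gained=sum(s.length for s in gained),
                        n_lost=len(lost), n_gained=len(gained))


def summarize_samples(segments: Iterable[Segment],
                      min_size: int = 1_000_000) -> pd.DataFrame:
    by_sample: dict[str, list[Segment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample, []).append(s)
    rows = [summarize_sample(v, min_size) for _, v in sorted(by_sample.items())]
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["sample", "bp_lost", "bp_gained",
                                 "n_lost", "n_gained"])


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def call_cytobands(segments: Iterable[Segment],
                   cytobands: Sequence[tuple[str, int, int, str]],
                   fraction: float = CYTOBAND_FRACTION) -> pd.DataFrame:
    """Per sample and band: fraction of band length overlapped by deleted /
    amplified / LOH-flagged segments, and the band status (strict
    > ``fraction`` rule)."""
    segs = list(segments)
    samples = sorted({s.sample for s in segs})
    rows = []
    for sample in samples:
        ssegs = [s for s in segs if s.sample == sample]
        for chrom, b0, b1, band in cytobands:
            blen = b1 - b0
            fd = fa = fl = 0.0
            for s in ssegs:
                if s.chrom != chrom:
                    continue
                ov = _overlap(s.start, s.end, b0, b1)
                if ov == 0:
                    continue
                if s.status == "deleted":
                    fd += ov / blen
                elif s.status == "amplified":
                    fa += ov / blen
                if s.loh:
                    fl += ov / blen
            status = ("deleted" if fd > fraction
                      else "amplified" if fa > fraction else "neutral")
            rows.append({"sample": sample, "band": band, "chrom": chrom,
                         "start": b0, "end": b1,
                         "fraction_deleted": fd, "fraction_amplified": fa,
                         "fraction_loh": fl, "status": status})
    return pd.DataFrame(rows, columns=["sample", "band", "chrom", "start",
                                       "end", "fraction_deleted",
                                       "fraction_amplified", "fraction_loh",
                                       "status"])


def recurrent_cytobands(band_calls: pd.DataFrame, min_samples: int = 3,
                        loh_fraction: float = CYTOBAND_FRACTION) -> pd.DataFrame:
    """Bands deleted (or mostly LOH-flagged) in at least ``min_samples``
    samples, sorted by support then band name."""
    if band_calls.empty:
        return pd.DataFrame(columns=["band", "n_samples", "samples"])
    support = band_calls[(band_calls["status"] == "deleted")
                         | (band_calls["fraction_loh"] >= loh_fraction)]
    if support.empty:
        return pd.DataFrame(columns=["band", "n_samples", "samples"])
    agg = (support.groupby("band")["sample"]
           .agg(lambda s: sorted(set(s))).reset_index())
    agg["n_samples"] = agg["sample"].map(len)
    agg = agg[agg["n_samples"] >= min_samples]
    agg = agg.sort_values(["n_samples", "band"],
                          ascending=[False, True], kind="mergesort")
    return (agg.rename(columns={"sample": "samples"})
            [["band", "n_samples", "samples"]].reset_index(drop=True))


def gene_scores(segments: Iterable[Segment],
                genes: Sequence, samples: Sequence[str] | None = None
                ) -> pd.DataFrame:
    """Net LogR and net mirrored BAF per gene, summed across samples.

    A gene is assigned to the segment containing its midpoint; a sample in
    which the gene is not covered by any segment contributes 0 to net LogR
    and the neutral 0.5 to net mirrored BAF.
    """
    segs = list(segments)
    if samples is None:
        samples = sorted({s.sample for s in segs})
    by_sample: dict[str, list[Segment]] = {s: [] for s in samples}
    for s in segs:
        if s.sample in by_sample:
            by_sample[s.sample].append(s)
    rows = []
    for g in genes:
        chrom = g.chrom
        mid = (g.start + g.end) // 2
        net_logr = 0.0
        net_baf = 0.0
        for sample in samples:
            hit = None
            for s in by_sample[sample]:
                if s.chrom == chrom and s.start <= mid < s.end:
                    hit = s
                    break
            if hit is None:
                net_baf += 0.5
            else:
                net_logr += hit.mean_logr
                net_baf += (hit.mean_mirrored_baf
                            if np.isfinite(hit.mean_mirrored_baf) else 0.5)
        rows.append({"gene": g.name, "chrom": chrom,
                     "net_logr": net_logr, "net_baf": net_baf})
    return pd.DataFrame(rows, columns=["gene", "chrom", "net_logr", "net_baf"])


# ---------------------------------------------------------------------------
# IO (SEG-style TSV; emitted coordinates are 1-based inclusive)
# ---------------------------------------------------------------------------

def segments_to_frame(segments: Iterable[Segment]) -> pd.DataFrame:
    rows = [{"sample": s.sample, "chrom": s.chrom,
             "start": s.start + 1, "end": s.end, "n_probes": s.n_probes,
             "mean_logr": s.mean_logr,
             "mean_mirrored_baf": s.mean_mirrored_baf,
             "status": s.status, "loh": s.loh} for s in segments]
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def frame_to_segments(df: pd.DataFrame) -> list[Segment]:
    return [Segment(sample=r.sample, chrom=str(r.chrom),
                    start=int(r.start) - 1, end=int(r.end),
                    n_probes=int(r.n_probes), mean_logr=float(r.mean_logr),
                    mean_mirrored_baf=float(r.mean_mirrored_baf),
                    status=str(r.status), loh=bool(r.loh))
            for r in df.itertuples()]


def write_segments(segments: Iterable[Segment], path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return frame_to_segments(df)


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader for cytoband/gene interval files (0-based
    half-open, first four columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]),
                        f[3] if len(f) > 3 else ""))
    return out
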