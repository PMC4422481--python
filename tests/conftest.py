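import pytest

from perimeso import synth
from perimeso.variants import SiteCounts


def make_site(**kw) -> SiteCounts:
    """A well-behaved paired site; override any field."""
    d = dict(sample="S1", chrom="1", pos=1000, ref="A", alt="T",
             t_ref=60, t_alt=40, n_ref=100, n_alt=0,
             avg_qual=35.0, read_pos=0.5, dist3p=0.5, mapq_diff=0.0,
             homopolymer_len=1, is_indel=False, indel_len=0)
    d.update(kw)
    d.setdefault("fwd_alt", d["t_alt"] // 2)
    d.setdefault("rev_alt", d["t_alt"] - d["fwd_alt"])
    return SiteCounts(**d)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture(scope="session")
def toy_genome():
    """One 5 Mb chromosome with a named target gene and a few background
    genes."""
    return synth.make_genome(synth.GenomeConfig(
        chromosomes=(("1", 5_000_000),),
        bands_per_chromosome=4, genes_per_chromosome=4,
        named_genes=(("1", 1_000_000, "TG"),)), seed=11)
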