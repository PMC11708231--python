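import numpy as np
import pytest

from deltastats.patterns import PATTERNS, PatternCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_counts(**kwargs) -> PatternCounts:
    """PatternCounts with the named patterns set and all others zero."""
    pc = PatternCounts()
    for pat, v in kwargs.items():
        pc.counts[pat] = float(v)
    pc.n_sites_retained = int(sum(kwargs.values()))
    return pc


def random_counts(rng, low=0, high=1000) -> PatternCounts:
    return PatternCounts.from_array(rng.integers(low, high, size=len(PATTERNS)))


@pytest.fixture
def tiny_vcf(tmp_path):
    """A small uncompressed VCF over five single-sample populations."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=1000000>",
        "##contig=<ID=chr2,length=1000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5",
        # (C,T,C,T,C) -> ABABA
        "chr1\t100\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t0/0\t1/1\t0/0",
        # (T,C,C,C,C) -> BAAAA
        "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t0/0\t0/0\t0/0",
        # missing genotype -> skipped
        "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t0/0\t0/0\t1/1\t0/0",
        # triallelic -> skipped
        "chr1\t400\t.\tG\tA,T\t.\tPASS\t.\tGT\t0/0\t1/1\t2/2\t0/0\t0/0",
        # constant -> skipped
        "chr1\t500\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0",
        # heterozygous first alleles: 0,1,0,0,1 -> (A,G,A,A,G) -> ABAAB
        "chr2\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/0\t0/0\t0/1\t1/1",
    ]
    path = tmp_path / "sites.vcf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def popmap_file(tmp_path):
    path = tmp_path / "popmap.tsv"
    path.write_text("".join(f"s{i}\t{i}\n" for i in range(1, 6)))
    return path
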