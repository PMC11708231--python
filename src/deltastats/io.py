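"""Readers and writers: VCF and site tables in, TSV panels and counts out.

The five analysis populations map onto tree leaves 1..5 through a *popmap*,
a two-column TSV of ``sample<TAB>leaf-label``.  In haploid mode exactly one
sample is designated per leaf and the first allele of its genotype is used
(a seeded random draw is available for heterozygotes); in frequency mode all
mapped samples contribute to a per-population alt-allele frequency.
"""

from __future__ import annotations

import random
import sys
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, TextIO

import pysam

from .patterns import PATTERNS, PatternCounts, SiteObservation
from .statistics import StatisticResult

__all__ = [
    "PopulationMap",
    "read_popmap",
    "read_vcf_sites",
    "read_site_table",
    "read_sites",
    "write_counts",
    "read_counts",
    "write_panel",
]

LEAF_LABELS = ("1", "2", "3", "4", "5")


@dataclass
class PopulationMap:
    """Ordered mapping of tree leaves 1..5 to sample identifiers."""

    samples: Dict[str, List[str]]  # leaf label -> sample names
    mode: str = "haploid"

    def __post_init__(self) -> None:
        if self.mode not in ("haploid", "frequency"):
            raise ValueError(f"unknown mode {self.mode!r}")
        missing = [l for l in LEAF_LABELS if not self.samples.get(l)]
        if missing:
            raise ValueError(f"popmap must cover all five leaves; missing {missing}")
        if self.mode == "haploid":
            bad = [l for l in LEAF_LABELS if len(self.samples[l]) != 1]
            if bad:
                raise ValueError(
                    f"haploid mode needs exactly one sample per leaf; leaves {bad} differ")

    def all_samples(self) -> List[str]:
        return [s for l in LEAF_LABELS for s in self.samples[l]]


def read_popmap(path, mode: str = "haploid") -> PopulationMap:
    samples: Dict[str, List[str]] = {l: [] for l in LEAF_LABELS}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            sample, leaf = parts
            if leaf not in samples:
                raise ValueError(f"popmap leaf label must be 1..5, got {leaf!r}")
            samples[leaf].append(sample)
    return PopulationMap(samples=samples, mode=mode)


def read_vcf_sites(
    path,
    popmap: PopulationMap,
    mode: Optional[str] = None,
    seed: Optional[int] = None,
    log: Optional[TextIO] = None,
) -> Iterator[SiteObservation]:
    """Stream biallelic SNP records from a VCF as :class:`SiteObservation`.

    Haploid mode emits allele symbols (first genotype allele of the
    designated sample, or a seeded random draw when ``seed`` is given);
    frequency mode emits per-population alt-allele frequencies over all
    called alleles.  Unusable records yield a site whose alleles contain
    ``None`` markers so the counting layer can tally the skip.
    """
    mode = mode or popmap.mode
    rng = random.Random(seed) if seed is not None else None
    vcf = pysam.VariantFile(str(path))
    header_samples = set(vcf.header.samples)
    for s in popmap.all_samples():
        if s not in header_samples:
            raise ValueError(f"sample {s!r} from popmap not present in VCF header")
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            yield SiteObservation(rec.chrom, rec.pos, [None] * 5,
                                  ref=rec.ref, alt=",".join(rec.alts or ()),
                                  skip_reason="multiallelic")
            continue
        alleles_at = {0: rec.ref, 1: rec.alts[0]}
        if mode == "haploid":
            out: List[Optional[str]] = []
            for leaf in LEAF_LABELS:
                gt = rec.samples[popmap.samples[leaf][0]].get("GT")
                if gt is None or len(gt) == 0 or gt[0] is None:
                    out.append(None)
                    continue
                allele_idx = gt[0]
                if rng is not None and len(gt) > 1 and gt[1] is not None:
                    allele_idx = rng.choice([a for a in gt if a is not None])
                out.append(alleles_at.get(allele_idx))
            yield SiteObservation(rec.chrom, rec.pos, out, ref=rec.ref, alt=rec.alts[0])
        else:
            freqs: List[Optional[float]] = []
            for leaf in LEAF_LABELS:
                alt = tot = 0
                for sample in popmap.samples[leaf]:
                    gt = rec.samples[sample].get("GT") or ()
                    for a in gt:
                        if a is None:
                            continue
                        tot += 1
                        if a == 1:
                            alt += 1
                freqs.append(alt / tot if tot else None)
            yield SiteObservation(rec.chrom, rec.pos, freqs, ref=rec.ref, alt=rec.alts[0])


def read_site_table(path, mode: str = "haploid") -> Iterator[SiteObservation]:
    """Plain TSV site table: chrom, pos, then 5 allele (or frequency) columns.

    A header row naming the taxa is required; lines starting with ``#`` are
    ignored.
    """
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if len(header) != 7:
                    raise ValueError(
                        "site table needs 7 columns: chrom, pos, and 5 taxa")
                continue
            if len(parts) != 7:
                raise ValueError(f"malformed site-table line: {line!r}")
            chrom, pos = parts[0], int(parts[1])
            vals: List = parts[2:]
            if mode == "frequency":
                vals = [float(v) if v not in (".", "") else None for v in vals]
            else:
                vals = [v if v not in (".", "") else None for v in vals]
            yield SiteObservation(chrom, pos, vals)


def read_sites(
    path,
    popmap: Optional[PopulationMap] = None,
    mode: str = "haploid",
    seed: Optional[int] = None,
) -> Iterator[SiteObservation]:
    """Dispatch to the VCF or TSV reader based on the file name."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz") or p.endswith(".bcf"):
        if popmap is None:
            raise ValueError("VCF input requires a popmap")
        return read_vcf_sites(p, popmap, mode=mode, seed=seed)
    return read_site_table(p, mode=mode)


def write_counts(counts: PatternCounts, fh: TextIO) -> None:
    fh.write("pattern\tcount\n")
    for p in PATTERNS:
        fh.write(f"{p}\t{counts.counts[p]:.17g}\n")
    fh.write(f"#n_sites_retained\t{counts.n_sites_retained}\n")
    fh.write(f"#n_sites_skipped\t{counts.n_sites_skipped}\n")
    for reason, n in sorted(counts.skip_reasons.items()):
        fh.write(f"#skipped.{reason}\t{n}\n")


def read_counts(path) -> PatternCounts:
    pc = PatternCounts()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("pattern\t"):
                continue
            key, val = line.split("\t")
            if key.startswith("#"):
                key = key[1:]
                if key == "n_sites_retained":
                    pc.n_sites_retained = int(val)
                elif key == "n_sites_skipped":
                    pc.n_sites_skipped = int(val)
                elif key.startswith("skipped."):
                    pc.skip_reasons[key[len("skipped."):]] = int(val)
                continue
            if key not in pc.counts:
                raise ValueError(f"unknown pattern code {key!r}")
            pc.counts[key] = float(val)
    return pc


def write_panel(results: Sequence[StatisticResult], fh: TextIO) -> None:
    fh.write("statistic\tn_left\tn_right\tunscaled\tscaled\tZ\twald_radius\tclass\n")
    for r in results:
        fh.write(
            f"{r.name}\t{r.n_left:.10g}\t{r.n_right:.10g}\t{r.unscaled:.10g}\t"
            f"{r.scaled:.6f}\t{r.z:.4f}\t{r.wald_radius:.6f}\t{r.classification}\n"
        )
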