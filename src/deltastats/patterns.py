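"""Polarized allelic patterns for five-taxon site data.

At a biallelic site observed in five taxa (ordered to match the leaf labels
1..5 of the species tree under study), allele ``A`` denotes the symbol seen
more often (at least three times out of five) and ``B`` the minority allele.
No ancestral state is called: taxon 5 may carry either allele (the outgroup
mutation assumption), so complementary raw patterns such as CTCTC / TCTCT
collapse onto the same polarized code.  Fifteen codes are possible: five
singletons (one ``B``) and ten doubletons (two ``B``s); a five-taxon site can
never tie, so polarization is always well defined unless the site is
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "PATTERNS",
    "PATTERN_INDEX",
    "SINGLETONS",
    "DOUBLETONS",
    "SiteObservation",
    "PatternCounts",
    "pattern_from_mask",
    "mask_from_pattern",
    "polarize_site",
    "frequency_weights",
    "count_patterns",
]

N_TAXA = 5


def pattern_from_mask(mask: int) -> str:
    """Code string for the set of taxa carrying ``B`` (bit i = taxon i+1)."""
    if not 0 < mask < 2**N_TAXA:
        raise ValueError(f"mask out of range: {mask}")
    if bin(mask).count("1") > 2:
        mask ^= 2**N_TAXA - 1
    return "".join("B" if mask >> i & 1 else "A" for i in range(N_TAXA))


def mask_from_pattern(code: str) -> int:
    mask = 0
    for i, c in enumerate(code):
        if c == "B":
            mask |= 1 << i
    return mask


#: The 15 valid codes, in canonical (ascending bitmask) order.
PATTERNS: tuple = tuple(
    pattern_from_mask(m) for m in range(1, 2**N_TAXA) if bin(m).count("1") <= 2
)
PATTERN_INDEX: Dict[str, int] = {p: i for i, p in enumerate(PATTERNS)}
SINGLETONS = tuple(p for p in PATTERNS if p.count("B") == 1)
DOUBLETONS = tuple(p for p in PATTERNS if p.count("B") == 2)

# mask (0..31) -> canonical pattern row, -1 for constant (0 or 31)
_MASK_TO_ROW = np.full(2**N_TAXA, -1, dtype=np.int64)
for _m in range(1, 2**N_TAXA - 1):
    _c = _m if bin(_m).count("1") <= 2 else _m ^ (2**N_TAXA - 1)
    _MASK_TO_ROW[_m] = PATTERN_INDEX[pattern_from_mask(_c)]


@dataclass
class SiteObservation:
    """One biallelic site: per-taxon allele symbols or allele frequencies.

    ``alleles`` holds either 5 single-character symbols (haploid mode) or 5
    frequencies in [0, 1] of the *same* allele (frequency mode).  ``ref`` and
    ``alt`` are carried for provenance only; polarization never consults them.
    """

    chrom: str
    pos: int  # 1-based
    alleles: Sequence[Union[str, float, None]]
    ref: Optional[str] = None
    alt: Optional[str] = None
    skip_reason: Optional[str] = None  # pre-marked unusable record (e.g. multiallelic)


@dataclass
class PatternCounts:
    """Accumulated (possibly fractional) counts per polarized pattern."""

    counts: Dict[str, float] = field(default_factory=lambda: {p: 0.0 for p in PATTERNS})
    n_sites_retained: int = 0
    n_sites_skipped: int = 0
    skip_reasons: Dict[str, int] = field(default_factory=dict)

    def __getitem__(self, pattern: str) -> float:
        return self.counts[pattern]

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[p] for p in PATTERNS], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "PatternCounts":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PATTERNS),):
            raise ValueError(f"expected {len(PATTERNS)} pattern counts, got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("pattern counts must be non-negative")
        pc = cls()
        for p, v in zip(PATTERNS, arr):
            pc.counts[p] = float(v)
        pc.n_sites_retained = int(round(float(arr.sum())))
        return pc

    def _skip(self, reason: str) -> None:
        self.n_sites_skipped += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1

    def add(self, other: "PatternCounts") -> "PatternCounts":
        for p in PATTERNS:
            self.counts[p] += other.counts[p]
        self.n_sites_retained += other.n_sites_retained
        self.n_sites_skipped += other.n_sites_skipped
        for k, v in other.skip_reasons.items():
            self.skip_reasons[k] = self.skip_reasons.get(k, 0) + v
        return self


def polarize_site(alleles: Sequence[str]) -> Optional[str]:
    """Polarize 5 allele symbols into a pattern code, or ``None`` if constant.

    The majority symbol maps to ``A``, the minority to ``B``.  Raises
    ``ValueError`` if more than two distinct symbols are present (the site is
    not biallelic) or if any symbol is missing.
    """
    if len(alleles) != N_TAXA:
        raise ValueError(f"expected {N_TAXA} alleles, got {len(alleles)}")
    distinct = []
    for a in alleles:
        if a is None or a in (".", ""):
            raise ValueError("missing allele")
        if a not in distinct:
            distinct.append(a)
    if len(distinct) == 1:
        return None
    if len(distinct) > 2:
        raise ValueError(f"more than two alleles at site: {distinct}")
    mask = 0
    for i, a in enumerate(alleles):
        if a == distinct[0]:
            mask |= 1 << i
    return pattern_from_mask(mask if bin(mask).count("1") <= 2 else mask ^ 0b11111)


def frequency_weights(freqs: Sequence[float]) -> Dict[str, float]:
    """Per-pattern probability weights from 5 allele frequencies.

    ``freqs`` are frequencies of one allele (either one — the result is
    invariant) in each of the 5 populations.  The weight of pattern P is

        sum over the two alleles a of  prod_i [ f_i(a) if P_i = B else 1 - f_i(a) ]

    i.e. the probability that a random haploid draw per population realises P
    under either assignment of the allele to ``B``.  Because valid patterns
    carry at most two ``B``s, the two-allele sum implements the merging of
    complementary raw patterns exactly; the remaining probability mass sits on
    the two constant classes and is discarded.
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (N_TAXA,):
        raise ValueError(f"expected {N_TAXA} frequencies")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    # probability of each of the 32 raw B-assignments, then fold complements
    out: Dict[str, float] = {}
    for p in PATTERNS:
        mask = mask_from_pattern(p)
        w = 1.0
        v = 1.0
        for i in range(N_TAXA):
            if mask >> i & 1:
                w *= f[i]
                v *= 1.0 - f[i]
            else:
                w *= 1.0 - f[i]
                v *= f[i]
        out[p] = w + v
    return out


def count_patterns(
    sites: Iterable[SiteObservation], mode: str = "haploid"
) -> PatternCounts:
    """Aggregate a stream of sites into :class:`PatternCounts`.

    ``mode`` is ``"haploid"`` (symbols, integer counts) or ``"frequency"``
    (allele frequencies, fractional weights).  Sites that cannot be used are
    skipped and tallied by reason (``missing``, ``multiallelic``,
    ``constant``).
    """
    if mode not in ("haploid", "frequency"):
        raise ValueError(f"unknown mode: {mode}")
    pc = PatternCounts()
    for site in sites:
        if site.skip_reason is not None:
            pc._skip(site.skip_reason)
            continue
        alleles = site.alleles
        if any(a is None or a in (".", "") for a in alleles):
            pc._skip("missing")
            continue
        if mode == "haploid":
            try:
                pat = polarize_site([str(a) for a in alleles])
            except ValueError as err:
                pc._skip("missing" if "missing" in str(err) else "multiallelic")
                continue
            if pat is None:
                pc._skip("constant")
                continue
            pc.counts[pat] += 1.0
            pc.n_sites_retained += 1
        else:
            try:
                f = [float(a) for a in alleles]
            except (TypeError, ValueError):
                pc._skip("missing")
                continue
            if any(x != x for x in f):  # NaN = missing frequency
                pc._skip("missing")
                continue
            w = frequency_weights(f)
            tot = sum(w.values())
            if tot == 0.0:
                pc._skip("constant")
                continue
            for p, v in w.items():
                pc.counts[p] += v
            pc.n_sites_retained += 1
    return pc


def counts_from_pattern_list(patterns: Iterable[str]) -> PatternCounts:
    """Build :class:`PatternCounts` from an iterable of pattern codes."""
    pc = PatternCounts()
    for p in patterns:
        pc.counts[p] += 1.0
        pc.n_sites_retained += 1
    return pc
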