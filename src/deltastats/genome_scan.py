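"""Windowed local-ancestry scan: per-window Δ-statistic signatures.

Introgression enters on the scale of whole chromosomes and is broken down by
recombination, so zooming into small nonoverlapping windows makes it
reasonable to assume each window carries traces of at most one gene-flow
event (the single-event assumption).  Each window's pattern counts yield a
panel, a signature, and a classification against the prediction table;
windows with no significant statistic fall under "Nothing" and signatures
matching no table row under "Unknown scenario".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .patterns import PatternCounts, SiteObservation, count_patterns
from .predictions import (
    NOTHING,
    MatchResult,
    PredictionTable,
    match_signature,
    prediction_table,
)
from .statistics import StatisticPanel, compute_panel

__all__ = ["Window", "WindowResult", "scan", "aggregate"]


@dataclass
class Window:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    n_sites_retained: int


@dataclass
class WindowResult:
    window: Window
    counts: PatternCounts
    panel: StatisticPanel
    match: MatchResult

    @property
    def signature(self) -> str:
        return self.panel.signature

    @property
    def category(self) -> str:
        return self.match.category


def scan(
    sites: Iterable[SiteObservation],
    window_size_bp: int,
    tree: str,
    include_singletons: bool = True,
    alpha: float = 0.01,
    mode: str = "haploid",
    table: Optional[PredictionTable] = None,
) -> List[WindowResult]:
    """Bucket sorted sites into fixed-width windows and classify each one.

    Windows are genomic bins of ``window_size_bp`` anchored at coordinate 1
    of each chromosome (window index ``(pos - 1) // size``); coordinates in
    the output are 0-based half-open.  Input must be sorted by (chrom, pos);
    an out-of-order site raises ``ValueError``.  A window with no retained
    sites carries the all-zero signature and is categorized "Nothing".
    """
    if window_size_bp <= 0:
        raise ValueError("window_size_bp must be positive")
    if table is None:
        table = prediction_table(tree, include_singletons=include_singletons)

    results: List[WindowResult] = []
    bucket: List[SiteObservation] = []
    current: Optional[Tuple[str, int]] = None  # (chrom, window index)
    last: Optional[Tuple[str, int]] = None
    seen_chroms: set = set()

    def flush() -> None:
        if current is None:
            return
        chrom, widx = current
        counts = count_patterns(bucket, mode=mode)
        panel = compute_panel(counts, tree, include_singletons=include_singletons,
                              alpha=alpha)
        match = match_signature(panel, table)
        results.append(
            WindowResult(
                window=Window(
                    chrom=chrom,
                    start=widx * window_size_bp,
                    end=(widx + 1) * window_size_bp,
                    n_sites_retained=counts.n_sites_retained,
                ),
                counts=counts,
                panel=panel,
                match=match,
            )
        )

    for site in sites:
        if last is not None:
            lchrom, lpos = last
            if site.chrom == lchrom and site.pos < lpos:
                raise ValueError(
                    f"input not sorted: {site.chrom}:{site.pos} after {lchrom}:{lpos}")
            if site.chrom != lchrom and site.chrom in seen_chroms:
                raise ValueError(f"input not sorted: chromosome {site.chrom} reappears")
        last = (site.chrom, site.pos)
        seen_chroms.add(site.chrom)
        widx = (site.pos - 1) // window_size_bp
        key = (site.chrom, widx)
        if key != current:
            flush()
            current = key
            bucket = []
        bucket.append(site)
    flush()
    return results


def aggregate(results: List[WindowResult], table: PredictionTable) -> Dict[str, int]:
    """Window counts per category (every ambiguity class + Nothing + unknown).

    Categories with zero windows are included so the output enumerates the
    full partition; counts always sum to the number of windows.
    """
    out: Dict[str, int] = {NOTHING: 0}
    for cls in table.ambiguity_classes:
        out[cls.label] = 0
    from .predictions import UNKNOWN

    out[UNKNOWN] = 0
    for r in results:
        out[r.category] = out.get(r.category, 0) + 1
    return out
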