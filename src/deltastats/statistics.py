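"""Binomial and composed Δ-statistics, Z-classification, DFOIL, Partitioned D.

A binomial Δ-statistic is ``n(L) − n(R)`` for one pattern from each side of an
equal probability set — a pair (or quadruple) of allelic patterns whose
probabilities coincide under the null hypothesis of no gene flow, purely by
the symmetry of the species tree.  Sums and differences of binomials yield the
composed statistics; after cancelling shared patterns the positive-coefficient
patterns form ``L`` and the negative ones ``R`` (the sets must be disjoint),
and the scaled statistic is ``(n(L) − n(R)) / (n(L) + n(R))``.

Twenty preferred scaled statistics are exposed as fixed panels for the three
five-leaf tree shapes: symmetric S = (((1,2),(3,4)),5), asymmetric
A = ((((1,2),3),4),5) and quasisymmetric Q = (((1,2),3),(4,5)).  Statistics
built on singleton patterns additionally require the synchronization
assumption (equal mutation opportunity per unit time across populations) and
can be dropped for ancient samples.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from scipy.stats import norm

from .patterns import PATTERNS, PatternCounts

__all__ = [
    "BINOMIALS",
    "PANELS",
    "PANEL_DIVIDER",
    "TREES",
    "StatisticResult",
    "StatisticPanel",
    "parse_composition",
    "compose",
    "evaluate",
    "compute_panel",
    "dfoil_panel",
    "partitioned_d",
    "z_critical",
]

TREES = ("S", "A", "Q")

# name -> (left pattern, right pattern); orientation fixed by the preferred
# statistics' printed numerators.  Singleton-based rows (S7, S8, A4, Q7, Q8)
# require the synchronization assumption.
BINOMIALS: Dict[str, Tuple[str, str]] = {
    "S1": ("BABAA", "BAABA"),
    "S2": ("ABBAA", "ABABA"),
    "S3": ("BABAA", "ABBAA"),
    "S4": ("BAABA", "ABABA"),
    "S5": ("BAAAB", "ABAAB"),
    "S6": ("AABAB", "AAABB"),
    "S7": ("BAAAA", "ABAAA"),
    "S8": ("AABAA", "AAABA"),
    "A1": ("BABAA", "ABBAA"),
    "A2": ("BAABA", "ABABA"),
    "A3": ("BAAAB", "ABAAB"),
    "A4": ("BAAAA", "ABAAA"),
    "Q1": ("BAABA", "BAAAB"),
    "Q2": ("ABABA", "ABAAB"),
    "Q3": ("BAABA", "ABABA"),
    "Q4": ("BAAAB", "ABAAB"),
    "Q5": ("BABAA", "ABBAA"),
    "Q6": ("AABBA", "AABAB"),
    "Q7": ("BAAAA", "ABAAA"),
    "Q8": ("AAABA", "AAAAB"),
}

SINGLETON_BINOMIALS = frozenset({"S7", "S8", "A4", "Q7", "Q8"})

#: Panel composition names per tree, in the canonical printed order.
PANELS: Dict[str, Tuple[str, ...]] = {
    "S": ("S1-6", "S2-6", "S3-5", "S4-5", "S5+7", "S6+8", "S3+4-5+7", "S1+2-6+8"),
    "A": ("A1-2", "A1-3", "A2-3", "A1+2-3+4"),
    "Q": ("Q1-6", "Q2-6", "Q3-5", "Q4-5", "Q5+7", "Q6+8", "Q3+4-5+7", "Q1+2-6+8"),
}

#: Index of the divider: statistics at or beyond it require synchronization.
PANEL_DIVIDER: Dict[str, int] = {"S": 4, "A": 3, "Q": 4}

_COMPOSITION_RE = re.compile(r"^(?:Δ|d|D)?([SAQ])((?:[+-]?\d+)+)\*?$")


def parse_composition(name: str) -> Dict[str, int]:
    """Parse a composition name like ``"S1-6"`` or ``"S3+4-5+7"`` or ``"S-3"``.

    Returns a mapping binomial-name -> signed coefficient.  A leading index
    without sign is positive; repeated indices accumulate (coefficients with
    magnitude > 1 are legal).
    """
    m = _COMPOSITION_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse composition name: {name!r}")
    tree, body = m.group(1), m.group(2)
    coeffs: Dict[str, int] = {}
    for sign, idx in re.findall(r"([+-]?)(\d+)", body):
        key = f"{tree}{idx}"
        if key not in BINOMIALS:
            raise ValueError(f"unknown binomial statistic {key!r} in {name!r}")
        coeffs[key] = coeffs.get(key, 0) + (-1 if sign == "-" else 1)
    return {k: v for k, v in coeffs.items() if v != 0}


def _net_pattern_coeffs(coeffs: Dict[str, int]) -> Dict[str, int]:
    trees = {k[0] for k in coeffs}
    if len(trees) > 1:
        raise ValueError(f"composition mixes binomials from different trees: {sorted(coeffs)}")
    net: Dict[str, int] = {}
    for binom, c in coeffs.items():
        left, right = BINOMIALS[binom]
        net[left] = net.get(left, 0) + c
        net[right] = net.get(right, 0) - c
    return {p: c for p, c in net.items() if c != 0}


def compose(
    composition, counts: PatternCounts
) -> Tuple[float, float]:
    """Weighted ``(n(L), n(R))`` for a composition on the given counts.

    ``composition`` is a name string or a parsed coefficient mapping.  Shared
    patterns cancel before the split into L (positive net coefficient) and R
    (negative), so L and R are disjoint by construction.
    """
    if isinstance(composition, str):
        composition = parse_composition(composition)
    net = _net_pattern_coeffs(composition)
    nl = sum(c * counts[p] for p, c in net.items() if c > 0)
    nr = sum(-c * counts[p] for p, c in net.items() if c < 0)
    return float(nl), float(nr)


def z_critical(alpha: float = 0.01) -> float:
    """Two-sided normal critical value Φ⁻¹(1 − α/2)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(norm.ppf(1.0 - alpha / 2.0))


@dataclass
class StatisticResult:
    """One evaluated scaled Δ-statistic."""

    name: str
    n_left: float
    n_right: float
    alpha: float

    def __post_init__(self) -> None:
        if self.n_left < 0 or self.n_right < 0:
            raise ValueError("pattern counts must be non-negative")

    @property
    def unscaled(self) -> float:
        return self.n_left - self.n_right

    @property
    def scaled(self) -> float:
        tot = self.n_left + self.n_right
        return 0.0 if tot == 0 else (self.n_left - self.n_right) / tot

    @property
    def z(self) -> float:
        tot = self.n_left + self.n_right
        return 0.0 if tot == 0 else (self.n_left - self.n_right) / math.sqrt(tot)

    @property
    def wald_radius(self) -> float:
        """Radius of the (1−α) Wald interval for the scaled statistic."""
        tot = self.n_left + self.n_right
        if tot == 0:
            return 0.0
        return z_critical(self.alpha) * math.sqrt(
            4.0 * self.n_left * self.n_right / tot**3
        )

    @property
    def classification(self) -> str:
        """``'+'``, ``'-'`` or ``'0'``; n(L)=n(R)=0 is 0 by convention."""
        zc = z_critical(self.alpha)
        z = self.z
        if z >= zc:
            return "+"
        if z <= -zc:
            return "-"
        return "0"


def evaluate(
    composition, counts: PatternCounts, alpha: float = 0.01, name: str | None = None
) -> StatisticResult:
    """Evaluate one composition into a :class:`StatisticResult`."""
    if name is None:
        name = composition if isinstance(composition, str) else "custom"
    nl, nr = compose(composition, counts)
    z_critical(alpha)  # validates alpha
    return StatisticResult(name=name, n_left=nl, n_right=nr, alpha=alpha)


@dataclass
class StatisticPanel:
    """Ordered results of one tree's preferred statistics."""

    tree: str
    include_singletons: bool
    results: List[StatisticResult]
    alpha: float

    @property
    def signature(self) -> str:
        from .predictions import format_signature

        signs = [r.classification for r in self.results]
        div = PANEL_DIVIDER[self.tree] if self.include_singletons else None
        return format_signature(signs, div)

    @property
    def classifications(self) -> Tuple[str, ...]:
        return tuple(r.classification for r in self.results)


def compute_panel(
    counts: PatternCounts,
    tree: str,
    include_singletons: bool = True,
    alpha: float = 0.01,
) -> StatisticPanel:
    """All preferred statistics of one tree shape, in the printed order.

    With ``include_singletons=False`` only the statistics left of the divider
    (those free of the synchronization assumption) are evaluated.
    """
    if tree not in TREES:
        raise ValueError(f"unknown tree shape {tree!r}; expected one of {TREES}")
    names = PANELS[tree]
    if not include_singletons:
        names = names[: PANEL_DIVIDER[tree]]
    results = [evaluate(n, counts, alpha=alpha) for n in names]
    return StatisticPanel(tree=tree, include_singletons=include_singletons,
                          results=results, alpha=alpha)


# DFOIL and Partitioned D as composed special cases (tree-S leaf order).
DFOIL_COMPOSITIONS: Dict[str, Tuple[str, str]] = {
    "DFO": ("S1-2-6-8", "S3-4-6-8"),
    "DIL": ("S2-1-6-8", "S4-3-6-8"),
    "DFI": ("S3-4-5-7", "S1-2-5-7"),
    "DOL": ("S4-3-5-7", "S2-1-5-7"),
}

PARTITIONED_D_COMPOSITIONS: Dict[str, str] = {
    "D12": "S5",
    "D1": "S-3",
    "D2": "S-4",
}


def dfoil_panel(counts: PatternCounts, alpha: float = 0.01) -> List[StatisticResult]:
    """The four DFOIL statistics (DFO, DIL, DFI, DOL) from pattern counts.

    Each statistic has two equivalent printed compositions; both are expanded
    and must agree identically (they differ by the linear relation
    ΔS1+ΔS4 = ΔS2+ΔS3, which cancels).
    """
    out = []
    for name, (comp_a, comp_b) in DFOIL_COMPOSITIONS.items():
        la, ra = compose(comp_a, counts)
        lb, rb = compose(comp_b, counts)
        if (la, ra) != (lb, rb):  # pragma: no cover - structural identity
            raise AssertionError(f"{name}: compositions {comp_a} and {comp_b} disagree")
        out.append(StatisticResult(name=name, n_left=la, n_right=ra, alpha=alpha))
    return out


def partitioned_d(counts: PatternCounts, alpha: float = 0.01) -> List[StatisticResult]:
    """Partitioned-D statistics (D12, D1, D2) = (ΔS5*, −ΔS3*, −ΔS4*)."""
    return [
        evaluate(comp, counts, alpha=alpha, name=name)
        for name, comp in PARTITIONED_D_COMPOSITIONS.items()
    ]
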