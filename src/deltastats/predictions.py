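"""Predicted signatures of unidirectional gene-flow events on trees S, A, Q.

Each admixture scenario "x->y" (a new branch stemming from branch ``x`` that
admixes into branch ``y``) leaves a characteristic tuple of {+,-,0} expected
classifications — a *signature* — across the preferred statistic panel of its
tree.  The tables below encode those predictions as literal data, one row per
event with a nonzero signature (32 for S, 18 for A, 34 for Q); any
unidirectional event not listed has the all-zero signature.  The right-hand
side of each signature (after the ``|`` divider) relies on the
synchronization assumption; *collapsed* tables project onto the left-hand
side only, merging events whose projections coincide, for use with ancient
samples.

Events that share a signature are grouped into an ambiguity class and
reported together; the pair x->y / y->x is abbreviated x<->y when both
members fall in the same class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .statistics import PANELS, PANEL_DIVIDER, TREES, StatisticPanel

__all__ = [
    "Signature",
    "PredictionTable",
    "MatchResult",
    "prediction_table",
    "enumerate_nonzero_events",
    "match_signature",
    "dfoil_prediction",
    "format_signature",
    "parse_signature",
]

NOTHING = "Nothing"
UNKNOWN = "Unknown scenario"


def _canon(sign: str) -> str:
    return {"−": "-", "+": "+", "-": "-", "0": "0"}[sign]


def format_signature(signs: Sequence[str], divider: int | None) -> str:
    s = [_canon(x) for x in signs]
    if divider is None or divider >= len(s):
        return "(" + "".join(s) + ")"
    return "(" + "".join(s[:divider]) + "|" + "".join(s[divider:]) + ")"


def parse_signature(text: str) -> Tuple[str, ...]:
    """Parse ``"(++-0|+-00)"`` (unicode minus/divider tolerated) into signs."""
    body = text.strip().strip("()")
    body = body.replace("|", "").replace("∣", "")
    signs = tuple(_canon(c) for c in body)
    if not signs or any(c not in "+-0" for c in signs):
        raise ValueError(f"malformed signature: {text!r}")
    return signs


Signature = Tuple[str, ...]


def _norm_event(event: str) -> str:
    return event.replace("→", "->").replace("↔", "<->").replace(" ", "")


def _expand_bidirectional(event: str) -> List[str]:
    event = _norm_event(event)
    if "<->" in event:
        a, b = event.split("<->")
        return [f"{a}->{b}", f"{b}->{a}"]
    return [event]


# --- Full prediction tables ------------------------------------------------
# One row per unidirectional event with a nonzero expected signature, in the
# panel order of statistics.PANELS.  Sign tuples are written with the divider
# for readability only.

_FULL_S: List[Tuple[str, str]] = [
    ("1->3", "(+++0|--00)"),
    ("3->1", "(+0++|--00)"),
    ("1->4", "(--0+|-+00)"),
    ("4->1", "(-0++|-+00)"),
    ("2->3", "(++-0|+-00)"),
    ("3->2", "(0+--|+-00)"),
    ("2->4", "(--0-|++00)"),
    ("4->2", "(0---|++00)"),
    ("12345->1", "(00--|+0+0)"),
    ("34->2", "(00--|+000)"),
    ("2->34", "(00--|+000)"),
    ("1234->1", "(00--|+000)"),
    ("5->1", "(00--|+0-0)"),
    ("1->5", "(00--|00-0)"),
    ("12345->2", "(00++|-0-0)"),
    ("34->1", "(00++|-000)"),
    ("1->34", "(00++|-000)"),
    ("1234->2", "(00++|-000)"),
    ("5->2", "(00++|-0+0)"),
    ("2->5", "(00++|00+0)"),
    ("12345->3", "(--00|0+0+)"),
    ("12->4", "(--00|0+00)"),
    ("4->12", "(--00|0+00)"),
    ("1234->3", "(--00|0+00)"),
    ("5->3", "(--00|0+0-)"),
    ("3->5", "(--00|000-)"),
    ("12345->4", "(++00|0-0-)"),
    ("12->3", "(++00|0-00)"),
    ("3->12", "(++00|0-00)"),
    ("1234->4", "(++00|0-00)"),
    ("5->4", "(++00|0-0+)"),
    ("4->5", "(++00|000+)"),
]

_FULL_A: List[Tuple[str, str]] = [
    ("1->3", "(++0|0)"),
    ("3->1", "(++0|0)"),
    ("123->2", "(++0|0)"),
    ("2->3", "(--0|0)"),
    ("3->2", "(--0|0)"),
    ("123->1", "(--0|0)"),
    ("1->4", "(-0+|0)"),
    ("4->1", "(--+|0)"),
    ("2->4", "(+0-|0)"),
    ("4->2", "(++-|0)"),
    ("1->5", "(0--|-)"),
    ("5->1", "(---|-)"),
    ("1234->1", "(---|0)"),
    ("12345->1", "(---|+)"),
    ("2->5", "(0++|+)"),
    ("5->2", "(+++|+)"),
    ("1234->2", "(+++|0)"),
    ("12345->2", "(+++|-)"),
]

_FULL_Q: List[Tuple[str, str]] = [
    ("1->4", "(+++0|--0-)"),
    ("4->1", "(+0++|--+0)"),
    ("1->5", "(--0+|-+0+)"),
    ("5->1", "(-0++|-++0)"),
    ("2->4", "(++-0|+-0-)"),
    ("4->2", "(0+--|+--0)"),
    ("2->5", "(--0-|++0+)"),
    ("5->2", "(0---|++-0)"),
    ("2->45", "(00--|+000)"),
    ("45->2", "(00--|+0-0)"),
    ("1->3", "(00--|00-0)"),
    ("3->1", "(00--|00-0)"),
    ("123->2", "(00--|00-0)"),
    ("12345->2", "(00--|-0-0)"),
    ("1->45", "(00++|-000)"),
    ("45->1", "(00++|-0+0)"),
    ("2->3", "(00++|00+0)"),
    ("3->2", "(00++|00+0)"),
    ("123->1", "(00++|00+0)"),
    ("12345->1", "(00++|+0+0)"),
    ("5->12", "(--00|0+00)"),
    ("12->5", "(--00|0+0+)"),
    ("4->3", "(--00|000-)"),
    ("3->4", "(--00|0-0-)"),
    ("4->12", "(++00|0-00)"),
    ("12->4", "(++00|0-0-)"),
    ("5->3", "(++00|000+)"),
    ("3->5", "(++00|0+0+)"),
    ("123->5", "(0000|0+0+)"),
    ("5->123", "(0000|0+0+)"),
    ("12345->4", "(0000|0+0+)"),
    ("123->4", "(0000|0-0-)"),
    ("4->123", "(0000|0-0-)"),
    ("12345->5", "(0000|0-0-)"),
]

_FULL_TABLES: Dict[str, List[Tuple[str, str]]] = {"S": _FULL_S, "A": _FULL_A, "Q": _FULL_Q}


@dataclass
class AmbiguityClass:
    """Events sharing one signature; ``label`` follows the x<->y* convention."""

    signature: Signature
    events: Tuple[str, ...]  # unidirectional members, table order
    label: str

    @property
    def merged_events(self) -> Tuple[str, ...]:
        """Members with x->y / y->x pairs merged into x<->y shorthand.

        Within a pair the internal branch is written first, and for a pair of
        terminal branches the lower-numbered leaf comes first (34<->2, 1<->5).
        """
        out: List[str] = []
        seen = set()
        for ev in self.events:
            if ev in seen:
                continue
            a, b = ev.split("->")
            rev = f"{b}->{a}"
            if rev in self.events:
                first, second = sorted((a, b), key=lambda x: (len(x) == 1, int(x)))
                out.append(f"{first}<->{second}")
                seen.update({ev, rev})
            else:
                out.append(ev)
                seen.add(ev)
        return tuple(out)


@dataclass
class MatchResult:
    """Outcome of matching an observed signature against a table."""

    category: str  # "Nothing", "Unknown scenario", or an ambiguity-class label
    events: Tuple[str, ...]  # unidirectional events consistent with the signature
    signature: Signature


class PredictionTable:
    """Signature predictions for one tree shape (full or collapsed)."""

    def __init__(self, tree: str, include_singletons: bool = True):
        if tree not in TREES:
            raise ValueError(f"unknown tree shape {tree!r}")
        self.tree = tree
        self.include_singletons = include_singletons
        self.n_statistics = (
            len(PANELS[tree]) if include_singletons else PANEL_DIVIDER[tree]
        )
        rows: List[Tuple[str, Signature]] = []
        for event, sig_text in _FULL_TABLES[tree]:
            signs = parse_signature(sig_text)
            if not include_singletons:
                signs = signs[: PANEL_DIVIDER[tree]]
            if all(s == "0" for s in signs):
                continue  # zero-signature events drop out of the collapsed table
            rows.append((event, signs))
        self.rows = rows
        self._classes = self._group()

    def _group(self) -> List[AmbiguityClass]:
        by_sig: Dict[Signature, List[str]] = {}
        for event, sig in self.rows:
            by_sig.setdefault(sig, []).append(event)
        classes = []
        for sig, events in by_sig.items():
            cls = AmbiguityClass(signature=sig, events=tuple(events), label="")
            merged = cls.merged_events
            label = merged[0] + ("*" if len(merged) > 1 else "")
            classes.append(
                AmbiguityClass(signature=sig, events=tuple(events), label=label)
            )
        return classes

    @property
    def ambiguity_classes(self) -> List[AmbiguityClass]:
        return list(self._classes)

    def events(self) -> List[str]:
        return [e for e, _ in self.rows]

    def signature_of(self, event: str) -> Signature:
        """Signature of a (possibly bidirectional) event; zero if unlisted.

        A bidirectional shorthand x<->y is the union of the signs of x->y and
        y->x where they agree; conflicting nonzero signs raise ``ValueError``.
        """
        members = _expand_bidirectional(event)
        sigs = []
        lookup = dict(self.rows)
        zero = tuple("0" for _ in range(self.n_statistics))
        for m in members:
            sigs.append(lookup.get(m, zero))
        if len(sigs) == 1:
            return sigs[0]
        merged = []
        for a, b in zip(*sigs):
            if a == "0":
                merged.append(b)
            elif b == "0" or a == b:
                merged.append(a)
            else:
                raise ValueError(f"event {event}: conflicting signs {a}/{b}")
        return tuple(merged)

    def match(self, observed) -> MatchResult:
        return match_signature(observed, self)

    def to_rows(self) -> List[Dict[str, str]]:
        """Serializable rows (event, signature, class label) for TSV dumps."""
        label_of = {}
        for cls in self._classes:
            for ev in cls.events:
                label_of[ev] = cls.label
        div = PANEL_DIVIDER[self.tree] if self.include_singletons else None
        return [
            {
                "event": event,
                "signature": format_signature(sig, div),
                "class": label_of[event],
            }
            for event, sig in self.rows
        ]


_TABLE_CACHE: Dict[Tuple[str, bool], PredictionTable] = {}


def prediction_table(tree: str, include_singletons: bool = True) -> PredictionTable:
    key = (tree, include_singletons)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = PredictionTable(tree, include_singletons)
    return _TABLE_CACHE[key]


def enumerate_nonzero_events(tree: str) -> List[str]:
    """Distinct unidirectional events with nonzero full signature (32/18/34)."""
    return prediction_table(tree, include_singletons=True).events()


def match_signature(observed, table: PredictionTable) -> MatchResult:
    """Classify an observed signature: Nothing / a known class / unknown.

    ``observed`` may be a :class:`~deltastats.statistics.StatisticPanel`, a
    signature string, or a sign tuple.  Matching is exact equality on signs.
    """
    if isinstance(observed, StatisticPanel):
        if observed.tree != table.tree:
            raise ValueError(
                f"panel tree {observed.tree!r} does not match table tree {table.tree!r}"
            )
        signs: Signature = observed.classifications
    elif isinstance(observed, str):
        signs = parse_signature(observed)
    else:
        signs = tuple(_canon(s) for s in observed)
    if len(signs) != table.n_statistics:
        raise ValueError(
            f"signature length {len(signs)} does not match table "
            f"({table.n_statistics} statistics)"
        )
    if all(s == "0" for s in signs):
        return MatchResult(category=NOTHING, events=(), signature=signs)
    for cls in table.ambiguity_classes:
        if cls.signature == signs:
            return MatchResult(category=cls.label, events=cls.events, signature=signs)
    return MatchResult(category=UNKNOWN, events=(), signature=signs)


# --- DFOIL -----------------------------------------------------------------
# Expected DFOIL sign tuples (DFO, DIL, DFI, DOL) per tree-S event, for
# comparison runs.  Rows were derived with this package's coalescent simulator
# under the default scenario geometry (see docs/methods.md) and anchored on
# the published facts that 1->3 produces (+++0) and that DFOIL is blind to
# gene flow from terminal branches into 5.  Events not listed predict (0000).

_DFOIL_TABLE: Dict[str, str] = {
    "1->3": "(+++0)",
    "3->1": "(+0++)",
    "1->4": "(--0+)",
    "4->1": "(-0++)",
    "2->3": "(++-0)",
    "3->2": "(0+--)",
    "2->4": "(--0-)",
    "4->2": "(0---)",
    "12345->1": "(00--)",
    "34->2": "(00--)",
    "2->34": "(00--)",
    "1234->1": "(00--)",
    "5->1": "(00--)",
    "1->5": "(0000)",
    "12345->2": "(00++)",
    "34->1": "(00++)",
    "1->34": "(00++)",
    "1234->2": "(00++)",
    "5->2": "(00++)",
    "2->5": "(0000)",
    "12345->3": "(--00)",
    "12->4": "(--00)",
    "4->12": "(--00)",
    "1234->3": "(--00)",
    "5->3": "(--00)",
    "3->5": "(0000)",
    "12345->4": "(++00)",
    "12->3": "(++00)",
    "3->12": "(++00)",
    "1234->4": "(++00)",
    "5->4": "(++00)",
    "4->5": "(0000)",
}


def dfoil_prediction(event: str) -> Signature:
    """Expected DFOIL 4-signature for a tree-S gene-flow event."""
    event = _norm_event(event)
    if "<->" in event:
        raise ValueError("dfoil_prediction expects a unidirectional event")
    text = _DFOIL_TABLE.get(event)
    if text is None:
        return ("0", "0", "0", "0")
    return parse_signature(text)
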