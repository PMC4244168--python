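"""Degenerate motif compilation, domain-restricted scanning and
conservation statistics.

Several RT lineages carry short diagnostic motifs: retrons a VTG in the
"Y" region of domain 7 and an NAxxH in region "X"; DGRs an
(I/V/L)GxxxSQ in domain 4; and the active site in domain 5 is a Y-x-D-D
tetrad whose variants (YADD, YIDD, YVDD, YRDD, FADD ...) are themselves
group-diagnostic.  Patterns are written in a small PROSITE-like
mini-language:

    residue letters       ``N``  ``Q``
    residue classes       ``[IVL]``
    wildcard              ``x`` (matches any standard residue, never ``X``)
    repeats               ``x(3)`` == ``xxx``

``(I/V/L)GxxxSQ`` in prose is ``[IVL]Gx(3)SQ`` here.  An uppercase ``X``
in a pattern is accepted as a wildcard (prose convention); the ambiguity
character in a *sequence* never matches anything.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core import AMINO_ACIDS, ProteinRecord
from .domains import DomainMap

_STANDARD = frozenset(AMINO_ACIDS)


class PatternError(ValueError):
    """Malformed motif pattern; carries the column of the offending token."""

    def __init__(self, spec: str, column: int, message: str):
        super().__init__(f"pattern {spec!r}, column {column}: {message}")
        self.column = column


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif.

    ``elements`` is the expanded element list: a frozenset of allowed
    residues per position, or ``None`` for a wildcard.  ``restriction``
    names the DomainMap region to scan (a domain name, ``region_X`` or
    ``region_Y``); ``None`` scans the whole sequence.
    """

    name: str
    spec: str
    elements: tuple[frozenset | None, ...]
    restriction: str | None = None

    def __post_init__(self) -> None:
        n_fixed = sum(1 for e in self.elements if e is not None)
        if n_fixed < 2:
            raise PatternError(self.spec, 0,
                               "pattern needs at least 2 non-wildcard elements")

    def __len__(self) -> int:
        return len(self.elements)

    def matches_at(self, seq: str, pos: int) -> bool:
        if pos < 0 or pos + len(self.elements) > len(seq):
            return False
        for off, elem in enumerate(self.elements):
            ch = seq[pos + off]
            if elem is None:
                if ch not in _STANDARD:  # wildcard still rejects 'X'
                    return False
            elif ch not in elem:
                return False
        return True


_TOKEN = re.compile(r"\[([A-WYZ]+)\]|([A-WYZ])|([xX])|\((\d+)\)")


def compile_pattern(spec: str, restriction: str | None = None,
                    name: str | None = None) -> MotifPattern:
    """Compile a mini-language pattern string into a :class:`MotifPattern`."""
    elements: list[frozenset | None] = []
    pos = 0
    while pos < len(spec):
        m = _TOKEN.match(spec, pos)
        if m is None:
            raise PatternError(spec, pos, f"unexpected character {spec[pos]!r}")
        cls, res, wild, rep = m.groups()
        if rep is not None:
            n = int(rep)
            if n < 1:
                raise PatternError(spec, pos, "repeat count must be >= 1")
            if not elements:
                raise PatternError(spec, pos, "repeat with nothing to repeat")
            elements.extend([elements[-1]] * (n - 1))
        elif cls is not None:
            bad = set(cls) - _STANDARD
            if bad:
                raise PatternError(spec, pos, f"invalid residues {sorted(bad)}")
            elements.append(frozenset(cls))
        elif res is not None:
            if res not in _STANDARD:
                raise PatternError(spec, pos, f"invalid residue {res!r}")
            elements.append(frozenset(res))
        else:  # wildcard (x or prose-style X)
            elements.append(None)
        pos = m.end()
    return MotifPattern(name or spec, spec, tuple(elements), restriction)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    pattern_name: str
    start: int  # 0-based within the full (ungapped) sequence
    matched: str


@dataclass(frozen=True)
class ScanResult:
    """Outcome of one restricted scan: ``ok`` with hits (possibly none), or
    ``region-absent`` when the pattern's window is missing from the map."""

    status: str  # "ok" | "region-absent"
    hits: tuple[MotifHit, ...] = ()

    @property
    def found(self) -> bool:
        return self.status == "ok" and bool(self.hits)


def scan(seq: ProteinRecord, dmap: DomainMap, pattern: MotifPattern) -> ScanResult:
    """All matching positions of ``pattern`` inside its restriction window,
    left to right.  Overlapping hits are all reported."""
    if pattern.restriction is None:
        window = (0, len(seq))
    else:
        window = dmap.region(pattern.restriction)
        if window is None:
            return ScanResult("region-absent")
    ws, we = window
    hits = []
    L = len(pattern)
    for p in range(ws, we - L + 1):
        if pattern.matches_at(seq.sequence, p):
            hits.append(MotifHit(seq.id, pattern.name, p, seq.sequence[p:p + L]))
    return ScanResult("ok", tuple(hits))


# ---------------------------------------------------------------------------
# active site

ACTIVE_SITE_VARIANTS = ("YADD", "YIDD", "YVDD", "YMDD", "YRDD", "FADD")
_PRIMARY = compile_pattern("[YF]xDD", restriction="5", name="active-site")
_FALLBACK = compile_pattern("xxDD", restriction="5", name="active-site-dd")


@dataclass(frozen=True)
class ActiveSiteCall:
    sequence_id: str
    tetrad: str | None  # 4 residues at the catalytic site, or None
    variant: str        # YADD/YIDD/YVDD/YMDD/YRDD/FADD/other/absent

    def __post_init__(self) -> None:
        if self.tetrad is None and self.variant != "absent":
            raise ValueError("variant must be 'absent' when no tetrad found")
        if self.tetrad is not None:
            expect = self.tetrad if self.tetrad in ACTIVE_SITE_VARIANTS else "other"
            if self.variant != expect:
                raise ValueError(
                    f"variant {self.variant!r} inconsistent with tetrad {self.tetrad!r}"
                )


def classify_tetrad(tetrad: str) -> str:
    return tetrad if tetrad in ACTIVE_SITE_VARIANTS else "other"


def call_active_site(seq: ProteinRecord, dmap: DomainMap) -> ActiveSiteCall:
    """Catalytic tetrad in domain 5: the leftmost ``[YF]xDD`` match, falling
    back to the leftmost ``xxDD``, else absent."""
    if dmap.region("5") is None:
        return ActiveSiteCall(seq.id, None, "absent")
    for pattern in (_PRIMARY, _FALLBACK):
        res = scan(seq, dmap, pattern)
        if res.found:
            tetrad = res.hits[0].matched
            return ActiveSiteCall(seq.id, tetrad, classify_tetrad(tetrad))
    return ActiveSiteCall(seq.id, None, "absent")


# ---------------------------------------------------------------------------
# conservation statistics

@dataclass(frozen=True)
class ConservationStats:
    """Per-group motif conservation.

    ``whole_motif_fraction``: share of member sequences with at least one
    full hit (region-absent members count in the denominator).
    ``per_position``: for each fixed pattern position, the share of
    *anchored* members whose residue satisfies that element; ``None`` for
    wildcard positions.  A member is anchored at the window position
    maximising the number of satisfied fixed elements (leftmost on ties).
    """

    pattern_name: str
    n_members: int
    n_with_hit: int
    n_anchored: int
    per_position: tuple[float | None, ...]

    @property
    def whole_motif_fraction(self) -> float:
        return self.n_with_hit / self.n_members


def _anchor_position(seq: str, window: tuple[int, int],
                     pattern: MotifPattern) -> int | None:
    ws, we = window
    best_pos, best_score = None, -1
    for p in range(ws, we - len(pattern) + 1):
        score = 0
        for off, elem in enumerate(pattern.elements):
            if elem is not None and seq[p + off] in elem:
                score += 1
        if score > best_score:
            best_pos, best_score = p, score
    return best_pos


def conservation_stats(members: list[tuple[ProteinRecord, DomainMap]],
                       pattern: MotifPattern) -> ConservationStats:
    """Whole-motif and per-position conservation over a group."""
    if not members:
        raise ValueError("conservation_stats needs a non-empty group")
    n_with_hit = 0
    n_anchored = 0
    pos_hits = [0] * len(pattern)
    for rec, dmap in members:
        res = scan(rec, dmap, pattern)
        if res.found:
            n_with_hit += 1
        if res.status == "region-absent":
            continue
        window = ((0, len(rec)) if pattern.restriction is None
                  else dmap.region(pattern.restriction))
        anchor = _anchor_position(rec.sequence, window, pattern)
        if anchor is None:
            continue
        n_anchored += 1
        for off, elem in enumerate(pattern.elements):
            if elem is not None and rec.sequence[anchor + off] in elem:
                pos_hits[off] += 1
    per_position = tuple(
        (pos_hits[i] / n_anchored if n_anchored else 0.0)
        if elem is not None else None
        for i, elem in enumerate(pattern.elements)
    )
    return ConservationStats(pattern.name, len(members), n_with_hit,
                             n_anchored, per_position)


def first_position_variant_fraction(
        members: list[tuple[ProteinRecord, DomainMap]],
        pattern: MotifPattern, alternatives: str) -> float:
    """Fraction of members matching ``pattern`` with its first fixed element
    replaced by ``alternatives`` (e.g. the I/L first-position variants of the
    retron VTG).  A sequence matching the original first element does not
    count toward the variant."""
    first_fixed = next(i for i, e in enumerate(pattern.elements) if e is not None)
    elements = list(pattern.elements)
    original = elements[first_fixed]
    elements[first_fixed] = frozenset(alternatives) - original
    variant = MotifPattern(pattern.name + "-variant", pattern.spec,
                           tuple(elements), pattern.restriction)
    n = sum(1 for rec, dmap in members if scan(rec, dmap, variant).found)
    return n / len(members)
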