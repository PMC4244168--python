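"""RT domain architecture: coordinates for domains 0-7 and derived regions.

The RT fold is organised as a series of conserved sequence blocks, numbered
0 through 7, with an insertion 2a found in some lineages.  Domain 5 carries
the catalytic Y-x-D-D tetrad; region "X" lies between domains 2 and 3 and
region "Y" inside domain 7 — both host lineage-diagnostic motifs.  Because
no absolute coordinates exist for arbitrary proteins, coordinates are
assigned by transfer: a query is globally aligned against curated reference
anchors and the best anchor's hand-assigned boundaries are projected
through the alignment.

All coordinates are 0-based half-open on the ungapped protein sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core import ProteinRecord

logger = logging.getLogger(__name__)

DOMAIN_ORDER = ("0", "1", "2", "2a", "3", "4", "5", "6", "7")
REGION_X = "region_X"
REGION_Y = "region_Y"

#: global alignment scoring for anchor transfer and nearest-representative
#: identity: BLOSUM62, affine gaps (open 10, extend 1)
GAP_OPEN = 10.0
GAP_EXTEND = 1.0
FLOOR_SCORE = 40.0


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class DomainMap:
    """Per-sequence domain coordinates.

    ``intervals`` maps domain names (subset of :data:`DOMAIN_ORDER`) to
    0-based half-open (start, end) pairs; absent domains are simply missing.
    ``region_y`` is an interval inside domain 7; ``region_x`` — between the
    end of domain 2/2a and the start of domain 3 — is derived on demand.
    ``active_site`` is the index of the first residue of the Y-x-D-D tetrad
    inside domain 5.
    """

    intervals: dict[str, tuple[int, int]]
    region_y: tuple[int, int] | None = None
    active_site: int | None = None

    def __post_init__(self) -> None:
        prev_end, prev_name = None, None
        for name in DOMAIN_ORDER:
            if name not in self.intervals:
                continue
            s, e = self.intervals[name]
            if not (0 <= s < e):
                raise ValueError(f"domain {name}: bad interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"domain {name} starts at {s}, before end {prev_end} of "
                    f"domain {prev_name}: intervals must be ordered 0<1<2<2a<3<4<5<6<7"
                )
            prev_end, prev_name = e, name
        extra = set(self.intervals) - set(DOMAIN_ORDER)
        if extra:
            raise ValueError(f"unknown domain names {sorted(extra)}")
        if self.region_y is not None:
            if "7" not in self.intervals:
                raise ValueError("region_Y given but domain 7 absent")
            s7, e7 = self.intervals["7"]
            if not (s7 <= self.region_y[0] < self.region_y[1] <= e7):
                raise ValueError("region_Y must lie within domain 7")
        if self.active_site is not None:
            if "5" not in self.intervals:
                raise ValueError("active_site given but domain 5 absent")
            s5, e5 = self.intervals["5"]
            if not (s5 <= self.active_site < e5):
                raise ValueError("active_site must lie within domain 5")

    @property
    def present(self) -> list[str]:
        return [d for d in DOMAIN_ORDER if d in self.intervals]

    def is_empty(self) -> bool:
        return not self.intervals

    def region_x(self) -> tuple[int, int] | None:
        """Inter-domain region between domain 2 (or 2a) and domain 3."""
        left = self.intervals.get("2a") or self.intervals.get("2")
        right = self.intervals.get("3")
        if left is None or right is None or left[1] >= right[0]:
            return None
        return (left[1], right[0])

    def region(self, name: str) -> tuple[int, int] | None:
        """Look up a scan window: a domain name, ``region_X`` or ``region_Y``."""
        if name == REGION_X:
            return self.region_x()
        if name == REGION_Y:
            return self.region_y
        return self.intervals.get(name)

    def span(self) -> tuple[int, int]:
        """Start of the earliest present domain to end of the latest."""
        if self.is_empty():
            raise ValueError("empty domain map has no span")
        present = self.present
        return (self.intervals[present[0]][0], self.intervals[present[-1]][1])

    def shift(self, offset: int) -> "DomainMap":
        return DomainMap(
            {d: (s + offset, e + offset) for d, (s, e) in self.intervals.items()},
            region_y=None if self.region_y is None
            else (self.region_y[0] + offset, self.region_y[1] + offset),
            active_site=None if self.active_site is None
            else self.active_site + offset,
        )


EMPTY_MAP = DomainMap({})


@dataclass(frozen=True)
class ReferenceAnchor:
    """A curated reference protein with hand-assigned domain coordinates."""

    record: ProteinRecord
    domain_map: DomainMap

    def __post_init__(self) -> None:
        s, e = self.domain_map.span()
        if e > len(self.record):
            raise ValueError(
                f"anchor {self.record.id}: domain map extends past sequence end"
            )


def annotate_domains(query: ProteinRecord, anchors: list[ReferenceAnchor],
                     floor_score: float = FLOOR_SCORE,
                     aligner: Align.PairwiseAligner | None = None) -> DomainMap:
    """Assign domain coordinates to ``query`` by anchored transfer.

    The query is globally aligned against every anchor; the best-scoring
    anchor (ties broken by anchor id) donates its boundaries, projected
    through the alignment.  Boundary columns that land in query gaps snap
    rightward for starts and leftward for ends; a domain whose projected
    interval is empty is reported absent.  If no anchor reaches
    ``floor_score`` an all-absent map is returned with a warning.
    """
    if not anchors:
        raise ValueError("at least one reference anchor is required")
    if aligner is None:
        aligner = make_aligner()
    best = None
    for anchor in sorted(anchors, key=lambda a: a.record.id):
        aln = aligner.align(anchor.record.sequence, query.sequence)[0]
        if best is None or aln.score > best[0]:
            best = (aln.score, anchor, aln)
    score, anchor, aln = best
    if score < floor_score:
        logger.warning(
            "query %s: best anchor score %.1f below floor %.1f; "
            "no domains assigned", query.id, score, floor_score,
        )
        return EMPTY_MAP

    # anchor position -> query position (-1 where the anchor aligns to a gap)
    a_idx, q_idx = aln.indices
    a2q = [-1] * len(anchor.record)
    for a, q in zip(a_idx, q_idx):
        if a >= 0 and q >= 0:
            a2q[a] = int(q)

    def transfer(interval):
        s, e = interval
        hits = [a2q[p] for p in range(s, min(e, len(a2q))) if a2q[p] >= 0]
        if not hits:
            return None
        return (hits[0], hits[-1] + 1)

    intervals = {}
    for name, interval in anchor.domain_map.intervals.items():
        got = transfer(interval)
        if got is not None:
            intervals[name] = got
    region_y = (transfer(anchor.domain_map.region_y)
                if anchor.domain_map.region_y is not None else None)
    if region_y is not None and "7" in intervals:
        s7, e7 = intervals["7"]
        region_y = (max(region_y[0], s7), min(region_y[1], e7))
        if region_y[0] >= region_y[1]:
            region_y = None
    else:
        region_y = None
    active = None
    if anchor.domain_map.active_site is not None and "5" in intervals:
        q = a2q[anchor.domain_map.active_site]
        s5, e5 = intervals["5"]
        if s5 <= q < e5:
            active = q
    return DomainMap(intervals, region_y=region_y, active_site=active)


def extract_rt_region(query: ProteinRecord, dmap: DomainMap) -> ProteinRecord:
    """Cut the RT 0-7 region: earliest present domain start to latest end."""
    if dmap.is_empty():
        raise ValueError(f"{query.id}: cannot extract RT region from an "
                         "all-absent domain map")
    s, e = dmap.span()
    if e > len(query):
        raise ValueError(f"{query.id}: domain map exceeds sequence length")
    return ProteinRecord(query.id, query.sequence[s:e], query.description)


# ---------------------------------------------------------------------------
# anchor fixtures on disk: gapped/ungapped FASTA + interval TSV

def write_anchor_tsv(anchors: list[ReferenceAnchor], path) -> None:
    rows = []
    for a in anchors:
        for d, (s, e) in a.domain_map.intervals.items():
            rows.append({"anchor_id": a.record.id, "feature": d, "start": s, "end": e})
        if a.domain_map.region_y is not None:
            s, e = a.domain_map.region_y
            rows.append({"anchor_id": a.record.id, "feature": REGION_Y,
                         "start": s, "end": e})
        if a.domain_map.active_site is not None:
            p = a.domain_map.active_site
            rows.append({"anchor_id": a.record.id, "feature": "active_site",
                         "start": p, "end": p + 1})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_anchors(fasta_path, tsv_path) -> list[ReferenceAnchor]:
    from .io import read_fasta

    records = {r.id: r for r in read_fasta(fasta_path, aligned=False)}
    df = pd.read_csv(tsv_path, sep="\t", dtype={"feature": str})
    anchors = []
    for aid, grp in df.groupby("anchor_id", sort=False):
        if aid not in records:
            raise ValueError(f"anchor {aid!r} has intervals but no sequence")
        intervals, region_y, active = {}, None, None
        for _, row in grp.iterrows():
            feat, s, e = row["feature"], int(row["start"]), int(row["end"])
            if feat == REGION_Y:
                region_y = (s, e)
            elif feat == "active_site":
                active = s
            else:
                intervals[feat] = (s, e)
        anchors.append(ReferenceAnchor(
            records[aid], DomainMap(intervals, region_y=region_y, active_site=active)
        ))
    return anchors


def write_domain_report(maps: dict[str, DomainMap], path) -> None:
    """TSV report (id, domain, start, end), 1-based inclusive for humans."""
    rows = []
    for rid, dmap in maps.items():
        for d in dmap.present:
            s, e = dmap.intervals[d]
            rows.append({"id": rid, "domain": d, "start": s + 1, "end": e})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
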