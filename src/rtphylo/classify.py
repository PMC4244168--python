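"""Assign an unlabeled RT sequence to a group.

Two independent lines of evidence are combined: the nearest labeled
representative by global-alignment percent identity, and the group
signature (required motifs, allowed active-site tetrads, expected absent
domains).  The decision matrix:

    nearest and signature agree        -> that group, high confidence
    nearest only (signature silent)    -> nearest group, medium
    signature only (no usable nearest) -> signature group, medium
    conflict, or no evidence           -> "UNC", low

A signature is *informative* — able to place a sequence on its own — only
when it requires at least one motif pattern or names a distinctive
active-site set (one not containing the canonical YADD); an allowed-variant
list containing YADD cannot discriminate and is treated as corroboration.
Likewise expected-absent domains corroborate but never decide, since
absence is weak evidence on fragments.  A failed own-group signature is
treated as silent, not as a conflict: diagnostic motifs decay, so their
absence is weak evidence, whereas a *different* group's full signature
matching is a genuine conflict.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .core import ProteinRecord
from .domains import DomainMap, ReferenceAnchor, annotate_domains, make_aligner
from .io import UNCLASSIFIED
from .motifs import MotifPattern, call_active_site, compile_pattern, scan

logger = logging.getLogger(__name__)

#: a query with no representative above this percent identity is unplaceable
MIN_NEAREST_IDENTITY = 20.0
CANONICAL_TETRAD = "YADD"


@dataclass(frozen=True)
class GroupSignature:
    group: str
    patterns: tuple[MotifPattern, ...] = ()
    active_site_variants: frozenset[str] = frozenset()
    absent_domains: frozenset[str] = frozenset()

    @property
    def informative(self) -> bool:
        return bool(self.patterns) or (
            bool(self.active_site_variants)
            and CANONICAL_TETRAD not in self.active_site_variants)

    def matches(self, query: ProteinRecord, dmap: DomainMap) -> bool:
        """All required patterns hit and the active-site call is allowed."""
        for pattern in self.patterns:
            if not scan(query, dmap, pattern).found:
                return False
        if self.active_site_variants:
            call = call_active_site(query, dmap)
            if call.variant not in self.active_site_variants:
                return False
        return True

    def absences_agree(self, dmap: DomainMap) -> bool:
        if dmap.is_empty():
            return False
        return all(d not in dmap.intervals for d in self.absent_domains)


class SignatureTable:
    """group label -> :class:`GroupSignature`; ships with the package."""

    def __init__(self, signatures: dict[str, GroupSignature]):
        self.signatures = signatures

    def __getitem__(self, group: str) -> GroupSignature:
        return self.signatures.get(group, GroupSignature(group))

    def informative_signatures(self) -> list[GroupSignature]:
        return [s for s in self.signatures.values() if s.informative]

    @classmethod
    def from_tsv(cls, path) -> "SignatureTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        sigs = {}
        for _, row in df.iterrows():
            patterns = []
            for part in filter(None, row.get("patterns", "").split(";")):
                spec, _, region = part.partition("@")
                patterns.append(compile_pattern(spec, restriction=region or None))
            sigs[row["group"]] = GroupSignature(
                group=row["group"],
                patterns=tuple(patterns),
                active_site_variants=frozenset(
                    filter(None, row.get("active_site_variants", "").split(","))),
                absent_domains=frozenset(
                    filter(None, row.get("absent_domains", "").split(","))),
            )
        return cls(sigs)

    @classmethod
    def default(cls) -> "SignatureTable":
        ref = importlib.resources.files("rtphylo.data").joinpath("signatures.tsv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class GroupAssignment:
    id: str
    group: str
    nearest_id: str | None
    nearest_identity: float | None  # percent
    signature_verdict: str          # consistent | inconsistent | uninformative
    confidence: str                 # high | medium | low

    def __post_init__(self) -> None:
        if self.confidence == "high" and self.signature_verdict != "consistent":
            raise ValueError("high confidence requires nearest-label and "
                             "signature agreement")


def alignment_identity(aligner: Align.PairwiseAligner,
                       a: ProteinRecord, b: ProteinRecord) -> float:
    """Percent identity over mutually aligned (non-gap) columns of the
    global pairwise alignment; 'X' never matches."""
    aln = aligner.align(a.sequence, b.sequence)[0]
    ai, bi = aln.indices
    both = (ai >= 0) & (bi >= 0)
    n_aligned = int(both.sum())
    if n_aligned == 0:
        return 0.0
    matches = sum(
        1 for x, y in zip(ai[both], bi[both])
        if a.sequence[x] == b.sequence[y] and a.sequence[x] != "X")
    return 100.0 * matches / n_aligned


def assign_group(query: ProteinRecord,
                 representatives: list[ProteinRecord],
                 labels: dict[str, str],
                 signatures: SignatureTable,
                 anchors: list[ReferenceAnchor],
                 min_identity: float = MIN_NEAREST_IDENTITY,
                 aligner: Align.PairwiseAligner | None = None,
                 dmap: DomainMap | None = None) -> GroupAssignment:
    """Classify one query against labeled representatives.

    Deterministic: representative ties are broken by lexicographic id, and
    permuting the representative list cannot change the result.
    """
    if aligner is None:
        aligner = make_aligner()
    if dmap is None:
        dmap = annotate_domains(query, anchors, aligner=aligner)

    nearest_id, nearest_ident = None, -1.0
    for rep in sorted(representatives, key=lambda r: r.id):
        ident = alignment_identity(aligner, query, rep)
        if ident > nearest_ident:
            nearest_id, nearest_ident = rep.id, ident
    nearest_group = labels.get(nearest_id) if nearest_id is not None else None
    nearest_ok = nearest_id is not None and nearest_ident >= min_identity

    # which informative signatures does the query satisfy?
    sig_groups = {s.group for s in signatures.informative_signatures()
                  if s.matches(query, dmap)}

    if nearest_ok and nearest_group in sig_groups:
        return GroupAssignment(query.id, nearest_group, nearest_id,
                               nearest_ident, "consistent", "high")
    if nearest_ok and not sig_groups:
        own = signatures[nearest_group]
        verdict = "uninformative"
        if own.absent_domains and not own.absences_agree(dmap):
            verdict = "inconsistent"  # corroboration failed, still proximity call
        return GroupAssignment(query.id, nearest_group, nearest_id,
                               nearest_ident, verdict, "medium")
    if not nearest_ok and len(sig_groups) == 1:
        # signature-only placement: proximity contributes nothing
        return GroupAssignment(query.id, next(iter(sig_groups)), nearest_id,
                               nearest_ident if nearest_id else None,
                               "consistent", "medium")
    if nearest_ok and sig_groups and nearest_group not in sig_groups:
        logger.info("query %s: nearest label %s conflicts with signature(s) %s",
                    query.id, nearest_group, sorted(sig_groups))
        return GroupAssignment(query.id, UNCLASSIFIED, nearest_id,
                               nearest_ident, "inconsistent", "low")
    return GroupAssignment(query.id, UNCLASSIFIED, nearest_id,
                           nearest_ident if nearest_id else None,
                           "uninformative", "low")


def classify_all(queries: list[ProteinRecord],
                 representatives: list[ProteinRecord],
                 labels: dict[str, str],
                 signatures: SignatureTable,
                 anchors: list[ReferenceAnchor],
                 **kwargs) -> list[GroupAssignment]:
    aligner = make_aligner()
    return [assign_group(q, representatives, labels, signatures, anchors,
                         aligner=aligner, **kwargs) for q in queries]


def write_assignments(assignments: list[GroupAssignment], path) -> None:
    pd.DataFrame([a.__dict__ for a in assignments]).to_csv(
        path, sep="\t", index=False)
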