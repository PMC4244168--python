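"""Fragment filtering and identity-based dereplication.

Annotated RT pulls from genome databases are full of near-duplicates and
truncated fragments.  The pipeline drops proteins shorter than 200 aa as
probable fragments, computes an alignment-based percent-identity matrix and
greedily reduces the set so that every retained pair shares at most 85%
identity.  Both thresholds are parameters; the defaults are the study
conditions.

Identity convention: the denominator is the number of mutually ungapped
columns (not the alignment length, not the shorter sequence), and ``X``
never matches anything, including ``X``.  Pairs with no overlapping columns
get identity 0 with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GAP_CODE, X_CODE, Msa, ProteinRecord

logger = logging.getLogger(__name__)

MIN_LENGTH_AA = 200
IDENTITY_THRESHOLD = 85.0


def length_filter(records: list[ProteinRecord], min_len: int = MIN_LENGTH_AA
                  ) -> list[ProteinRecord]:
    """Keep records of length >= ``min_len`` residues, preserving order.

    Sequences shorter than the cutoff are discarded as probable fragments;
    each discard is logged.
    """
    kept = []
    for rec in records:
        if len(rec) >= min_len:
            kept.append(rec)
        else:
            logger.info("discarding %s: length %d < %d (probable fragment)",
                        rec.id, len(rec), min_len)
    return kept


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix over alignment rows.

    ``overlap[i, j]`` counts the mutually ungapped columns behind each
    entry; zero-overlap pairs have identity 0 by definition.
    """

    ids: list[str]
    values: np.ndarray   # percent in [0, 100]
    overlap: np.ndarray  # mutually ungapped column counts

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("identity matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("identities must lie in [0, 100]")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def submatrix(self, ids: list[str]) -> "IdentityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return IdentityMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.overlap[np.ix_(idx, idx)]
        )


def pairwise_identity(msa: Msa) -> IdentityMatrix:
    """Percent identity for every row pair of an alignment.

    identity(i, j) = 100 * (columns where both rows carry the same standard
    residue) / (columns where both rows are ungapped).  ``X`` counts in the
    denominator but never in the numerator.
    """
    if msa.n_rows < 2:
        raise ValueError("pairwise identity needs at least 2 aligned rows")
    codes = msa.codes()
    nongap = (codes != GAP_CODE)
    matchable = nongap & (codes != X_CODE)

    overlap = nongap.astype(np.float64) @ nongap.T.astype(np.float64)
    matches = np.zeros_like(overlap)
    for r in range(20):  # one-hot per residue keeps memory flat
        m = (matchable & (codes == r)).astype(np.float64)
        matches += m @ m.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ident = np.where(overlap > 0, 100.0 * matches / overlap, 0.0)
    np.fill_diagonal(ident, np.where(np.diag(overlap) > 0, np.diag(ident), 0.0))

    n_zero = int((overlap == 0).sum() - (np.diag(overlap) == 0).sum()) // 2
    if n_zero:
        logger.warning(
            "%d sequence pairs share no overlapping columns; identity set to 0",
            n_zero,
        )
    return IdentityMatrix(msa.ids, ident, overlap.astype(np.int64))


@dataclass
class DereplicationResult:
    representatives: list[str]
    membership: dict[str, str]  # removed id -> representative id
    threshold: float

    def clusters(self) -> dict[str, list[str]]:
        out = {rep: [] for rep in self.representatives}
        for member, rep in self.membership.items():
            out[rep].append(member)
        return out


def dereplicate(msa: Msa, threshold: float = IDENTITY_THRESHOLD,
                identity: IdentityMatrix | None = None) -> DereplicationResult:
    """Greedy keep-first reduction so all retained pairs are <= ``threshold``
    percent identical.

    Rows are visited in input order; a row is kept if its identity to every
    already-kept representative is <= threshold (a pair at exactly the
    threshold is retained), otherwise it is assigned to the first kept
    representative exceeding the threshold.
    """
    im = identity if identity is not None else pairwise_identity(msa)
    if im.ids != msa.ids:
        raise ValueError("identity matrix ids do not match alignment")
    kept_idx: list[int] = []
    membership: dict[str, str] = {}
    for i, rid in enumerate(im.ids):
        owner = None
        for k in kept_idx:
            if im.values[k, i] > threshold:
                owner = im.ids[k]
                break
        if owner is None:
            kept_idx.append(i)
        else:
            membership[rid] = owner
            logger.info("dereplicated %s -> %s (%.2f%% identity)",
                        rid, owner, im.values[im.ids.index(owner), i])
    return DereplicationResult([im.ids[k] for k in kept_idx], membership, threshold)


def write_clusters(result: DereplicationResult, identity: IdentityMatrix, path) -> None:
    """TSV report: representative, member ids, max within-cluster identity."""
    rows = []
    for rep, members in result.clusters().items():
        if members:
            mx = max(identity.get(rep, m) for m in members)
        else:
            mx = float("nan")
        rows.append({
            "representative": rep,
            "members": ",".join(members),
            "max_within_identity": round(mx, 2) if members else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
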