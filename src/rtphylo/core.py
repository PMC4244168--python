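"""Core sequence containers shared by every pipeline stage.

Two containers cover the whole pipeline: :class:`ProteinRecord` for an
ungapped amino-acid sequence and :class:`Msa` for an aligned set of rows.
Coordinates are 0-based, half-open everywhere; 1-based inclusive appears
only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = "X"
GAP = "-"

_RESIDUE_SET = frozenset(AMINO_ACIDS + AMBIGUOUS)
_GAPPED_SET = _RESIDUE_SET | {GAP}

# integer codes for vectorised column arithmetic
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE[AMBIGUOUS] = 20
_CODE[GAP] = 21
X_CODE = 20
GAP_CODE = 21
_DECODE = np.array(list(AMINO_ACIDS + AMBIGUOUS + GAP))

_ENCODE_LUT = np.full(128, -1, dtype=np.int8)
for _ch, _c in _CODE.items():
    _ENCODE_LUT[ord(_ch)] = _c


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a unique identifier.

    The sequence is ungapped and drawn from the 20 standard residues plus
    the ambiguity character ``X``.  ``X`` never counts as a match anywhere
    downstream (identity, motifs).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - _RESIDUE_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(20 standard residues plus 'X'; gaps not allowed)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def check_unique_ids(records) -> None:
    """Raise ``ValueError`` on the first duplicated record id."""
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


@dataclass(frozen=True)
class AlignedRecord:
    """A single gapped row of an alignment."""

    id: str
    sequence: str  # may contain '-'
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.sequence) - _GAPPED_SET
        if bad:
            raise ValueError(
                f"row {self.id!r}: invalid characters {sorted(bad)!r} "
                "(gap character is '-'; '.' is rejected)"
            )

    def ungapped(self) -> ProteinRecord:
        return ProteinRecord(self.id, self.sequence.replace(GAP, ""), self.description)


@dataclass
class Msa:
    """An aligned, column-addressable set of sequences.

    Invariants: all rows have equal length; ungapping any row reproduces
    the underlying :class:`ProteinRecord`.
    """

    rows: list[AlignedRecord]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        lengths = {len(r.sequence) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        check_unique_ids(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, rid: str) -> AlignedRecord:
        for r in self.rows:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def ungapped_records(self) -> list[ProteinRecord]:
        return [r.ungapped() for r in self.rows]

    def codes(self) -> np.ndarray:
        """Integer-coded matrix (n_rows, n_cols); residues 0-19, X=20, gap=21."""
        if self._codes is None:
            buf = np.frombuffer(
                "".join(r.sequence for r in self.rows).encode("ascii"), dtype=np.uint8
            )
            codes = _ENCODE_LUT[buf].reshape(self.n_rows, self.n_cols)
            self._codes = codes.astype(np.int8)
        return self._codes

    def take_columns(self, cols: np.ndarray) -> "Msa":
        """New alignment restricted to (or resampled over) ``cols``."""
        codes = self.codes()[:, cols]
        rows = [
            AlignedRecord(r.id, "".join(_DECODE[codes[i]]), r.description)
            for i, r in enumerate(self.rows)
        ]
        return Msa(rows)

    def subset(self, ids) -> "Msa":
        wanted = set(ids)
        return Msa([r for r in self.rows if r.id in wanted])
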