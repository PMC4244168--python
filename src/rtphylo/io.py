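"""Readers and writers for all external formats.

FASTA (ungapped sequences and gapped alignments) goes through Biopython,
tabular metadata through pandas, Newick through the :mod:`rtphylo.phylogeny`
tree wrapper.  All readers validate hard: duplicate ids, ragged alignments
and missing columns are errors, not warnings.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignedRecord, Msa, ProteinRecord

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNC"


# ---------------------------------------------------------------------------
# controlled vocabulary

def _load_vocab() -> pd.DataFrame:
    ref = importlib.resources.files("rtphylo.data").joinpath("rt_groups.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


_VOCAB = _load_vocab()
GROUP_LABELS: frozenset[str] = frozenset(_VOCAB["label"])
#: label -> top-level lineage
GROUP_LINEAGE: dict[str, str] = dict(zip(_VOCAB["label"], _VOCAB["lineage"]))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, aligned: bool = False):
    """Read a FASTA file.

    Parameters
    ----------
    path : path-like
    aligned : bool
        If True the file is a gapped alignment and an :class:`Msa` is
        returned (equal row lengths enforced); otherwise a list of ungapped
        :class:`ProteinRecord` in file order.

    Raises
    ------
    ValueError
        on duplicate ids or, when ``aligned``, on ragged rows.
    """
    path = Path(path)
    seen: set[str] = set()
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip()
        if aligned:
            rows.append(AlignedRecord(rec.id, seq, desc))
        else:
            rows.append(ProteinRecord(rec.id, seq, desc))
    if not rows:
        raise ValueError(f"{path}: no sequences found")
    if aligned:
        return Msa(rows)
    return rows


def write_fasta(records, path) -> None:
    """Write ProteinRecords, AlignedRecords or an Msa to FASTA."""
    if isinstance(records, Msa):
        records = records.rows
    out = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# metadata / genome-count tables

@dataclass
class MetadataTable:
    """Per-sequence labels keyed by id (group label, phylum, provenance)."""

    table: pd.DataFrame  # index: id; columns: group_label, phylum, initial_dataset, length_aa

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate metadata ids: {dups}")

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, rid: str) -> str:
        return self.table.at[rid, "group_label"]

    def phylum_of(self, rid: str) -> str:
        return self.table.at[rid, "phylum"]

    def labels(self) -> dict[str, str]:
        return dict(self.table["group_label"])

    def __len__(self) -> int:
        return len(self.table)


def read_metadata(path) -> MetadataTable:
    """Read the per-sequence metadata TSV (columns id, group_label, phylum,
    optionally initial_dataset, length_aa).

    Labels outside the controlled vocabulary are mapped to ``UNC`` with a
    logged warning; a missing required column is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "group_label", "phylum"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    unknown = ~df["group_label"].isin(GROUP_LABELS)
    if unknown.any():
        bad = sorted(df.loc[unknown, "group_label"].unique())
        logger.warning(
            "%s: %d rows with group labels outside the controlled vocabulary "
            "%s mapped to %s", path, int(unknown.sum()), bad, UNCLASSIFIED,
        )
        df.loc[unknown, "group_label"] = UNCLASSIFIED
    if "initial_dataset" not in df.columns:
        df["initial_dataset"] = False
    df["initial_dataset"] = df["initial_dataset"].astype(bool)
    df = df.set_index("id", verify_integrity=True)
    return MetadataTable(df)


def write_metadata(meta: MetadataTable, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="id")


def read_genome_counts(path) -> dict[str, int]:
    """Read the per-phylum genome-count TSV (columns phylum, n_genomes)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"phylum", "n_genomes"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["phylum"].duplicated().any():
        raise ValueError(f"{path}: duplicate phylum rows")
    counts = dict(zip(df["phylum"], df["n_genomes"].astype(int)))
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"{path}: negative genome counts")
    return counts


def write_genome_counts(counts: dict[str, int], path) -> None:
    pd.DataFrame(
        {"phylum": list(counts), "n_genomes": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick (delegates to the tree wrapper) and JSON reports

def read_newick(path):
    from .phylogeny import SupportTree

    return SupportTree.read(path)


def write_newick(tree, path) -> None:
    tree.write(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
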