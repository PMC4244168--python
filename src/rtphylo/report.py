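"""Dataset composition, per-phylum diversity and alignment statistics.

Reports mirror the survey-style summaries of an RT repertoire study:
percentage of each group in the dereplicated dataset, RT-per-genome
diversity ratios by phylum, the phylum x group contingency table, and the
count of parsimony-informative alignment columns.  Rounding is half-up to
the printed precision (two decimals for ratios, one for percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core import GAP_CODE, X_CODE, Msa
from .io import MetadataTable


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (2.5 -> 3), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def composition(labels, ndigits: int = 1) -> dict[str, float]:
    """Percentage of each group in the dataset, half-up rounded.

    ``labels`` may be a MetadataTable, a mapping id -> group, or a
    group -> count mapping.
    """
    if isinstance(labels, MetadataTable):
        counts = labels.table["group_label"].value_counts().to_dict()
    elif isinstance(labels, dict) and labels and \
            all(isinstance(v, (int, np.integer)) for v in labels.values()):
        counts = dict(labels)
    elif isinstance(labels, dict):
        counts = pd.Series(list(labels.values())).value_counts().to_dict()
    else:
        counts = pd.Series(list(labels)).value_counts().to_dict()
    total = sum(counts.values())
    if total == 0:
        raise ValueError("composition of an empty label set")
    return {g: round_half_up(100.0 * n / total, ndigits)
            for g, n in sorted(counts.items())}


def diversity_ratio(n_rt: int, n_genomes: int) -> float:
    """Dereplicated RT sequences per completely sequenced genome, to 2
    decimals."""
    if n_genomes <= 0:
        raise ValueError("diversity ratio needs a positive genome count")
    if n_rt < 0:
        raise ValueError("negative RT count")
    return round_half_up(n_rt / n_genomes, 2)


@dataclass(frozen=True)
class PhylumSummary:
    phylum: str
    n_rt_derep: int
    n_genomes: int
    ratio: float


def phylum_summaries(metadata: MetadataTable,
                     genome_counts: dict[str, int]) -> list[PhylumSummary]:
    """Normalized sequence diversity (RTs <=85% identity per genome) by
    phylum, for the ids present in ``metadata`` (pass the dereplicated
    table)."""
    tallies = metadata.table["phylum"].value_counts().to_dict()
    out = []
    for phylum in sorted(genome_counts):
        n_rt = int(tallies.get(phylum, 0))
        out.append(PhylumSummary(phylum, n_rt, genome_counts[phylum],
                                 diversity_ratio(n_rt, genome_counts[phylum])))
    return out


def informative_positions(msa: Msa) -> int:
    """Parsimony-informative columns: at least two distinct non-gap, non-X
    residues, each occurring in at least two rows."""
    if msa.n_rows < 4:
        raise ValueError("informative positions need at least 4 rows")
    codes = msa.codes()
    count = 0
    for col in codes.T:
        col = col[(col != GAP_CODE) & (col != X_CODE)]
        if col.size == 0:
            continue
        _, freqs = np.unique(col, return_counts=True)
        if (freqs >= 2).sum() >= 2:
            count += 1
    return count


@dataclass
class DistributionMatrix:
    """Phylum x group contingency table with percentages."""

    counts: pd.DataFrame   # rows: phylum, columns: group
    row_pct: pd.DataFrame  # % within phylum
    col_pct: pd.DataFrame  # % within group
    restricted: list[str]  # groups present in exactly one phylum


def distribution_matrix(assignments: dict[str, str],
                        metadata: MetadataTable) -> DistributionMatrix:
    """Cross-tabulate group assignments against phyla.

    Zero cells are retained; a group whose members all fall in a single
    phylum is flagged restricted.
    """
    rows = []
    for rid, group in assignments.items():
        rows.append({"group": group, "phylum": metadata.phylum_of(rid)})
    df = pd.DataFrame(rows)
    counts = pd.crosstab(df["phylum"], df["group"])
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    col_pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    restricted = [g for g in counts.columns
                  if int((counts[g] > 0).sum()) == 1]
    return DistributionMatrix(counts, row_pct, col_pct, restricted)


def write_reports(path_prefix, *, composition_pct=None, summaries=None,
                  matrix: DistributionMatrix | None = None) -> None:
    """Write the JSON/TSV report files next to ``path_prefix``."""
    from .io import write_json

    if composition_pct is not None:
        write_json(composition_pct, f"{path_prefix}_composition.json")
    if summaries is not None:
        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
            f"{path_prefix}_phylum_summary.tsv", sep="\t", index=False)
    if matrix is not None:
        matrix.counts.to_csv(f"{path_prefix}_distribution.tsv", sep="\t")
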