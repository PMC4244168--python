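"""End-to-end orchestration: filter -> derep -> domains -> motifs -> tree ->
collapse -> monophyly -> classify -> reports.

Every stage writes its output before the next starts and never mutates a
prior stage's file; a run manifest records the path, SHA-256 checksum and
row/leaf counts of every artifact, so a rerun with the same config and seed
can be verified checksum-for-checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import SignatureTable, classify_all, write_assignments
from .core import Msa
from .derep import (IDENTITY_THRESHOLD, MIN_LENGTH_AA, dereplicate,
                    length_filter, pairwise_identity, write_clusters)
from .domains import annotate_domains, make_aligner, read_anchors, \
    write_domain_report
from .io import (MetadataTable, read_fasta, read_genome_counts, read_metadata,
                 write_fasta, write_json)
from .motifs import conservation_stats
from .phylogeny import (COLLAPSE_BOOTSTRAP, COLLAPSE_LOCAL,
                        DEFAULT_BOOTSTRAP_REPS, bootstrap_support, collapse,
                        test_monophyly)
from .report import (composition, distribution_matrix, phylum_summaries,
                     write_reports)

logger = logging.getLogger(__name__)

#: per-stage seed offsets: stage-level reproducibility when rerun in isolation
SEED_OFFSET_SIMULATE = 0
SEED_OFFSET_BOOTSTRAP = 1000

STAGES = ("filter", "derep", "domains", "motifs", "tree", "collapse",
          "monophyly", "classify", "report")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the global seed for one pipeline run."""

    alignment: str              # gapped FASTA MSA of the input sequences
    metadata: str               # per-sequence TSV (id, group_label, phylum, ...)
    genome_counts: str          # per-phylum TSV (phylum, n_genomes)
    anchors_fasta: str          # reference anchors, ungapped FASTA
    anchors_tsv: str            # reference anchor domain intervals
    outdir: str
    signatures: str | None = None  # defaults to the shipped signature table
    min_len: int = MIN_LENGTH_AA
    identity_threshold: float = IDENTITY_THRESHOLD
    collapse_local: float = COLLAPSE_LOCAL
    collapse_bootstrap: float = COLLAPSE_BOOTSTRAP
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.identity_threshold <= 100):
            raise ValueError(
                f"identity threshold {self.identity_threshold} outside (0, 100]")
        for name in ("collapse_local", "collapse_bootstrap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.min_len < 0 or self.bootstrap_reps < 0:
            raise ValueError("min_len and bootstrap_reps must be >= 0")
        for name in ("alignment", "metadata", "genome_counts",
                     "anchors_fasta", "anchors_tsv"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.signatures is not None and not Path(self.signatures).exists():
            raise FileNotFoundError(f"signatures: {self.signatures} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys {sorted(extra)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": dataclasses.asdict(config), "stages": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {
            str(p.name): _sha256(p) for p in paths}

    msa = read_fasta(config.alignment, aligned=True)
    meta = read_metadata(config.metadata)
    genome_counts = read_genome_counts(config.genome_counts)
    anchors = read_anchors(config.anchors_fasta, config.anchors_tsv)
    signatures = (SignatureTable.from_tsv(config.signatures)
                  if config.signatures else SignatureTable.default())

    # 1. fragment filter (on ungapped lengths)
    kept = length_filter(msa.ungapped_records(), config.min_len)
    kept_ids = [r.id for r in kept]
    msa = msa.subset(kept_ids)
    p_filter = outdir / "filtered.fasta"
    write_fasta(kept, p_filter)
    record("filter", p_filter)

    # 2. dereplication at <= identity_threshold % identity
    identity = pairwise_identity(msa)
    derep = dereplicate(msa, config.identity_threshold, identity=identity)
    derep_msa = msa.subset(derep.representatives)
    p_clusters = outdir / "derep_clusters.tsv"
    p_derep = outdir / "derep.fasta"
    write_clusters(derep, identity, p_clusters)
    write_fasta(derep_msa, p_derep)
    record("derep", p_clusters, p_derep)

    records = {r.id: r for r in derep_msa.ungapped_records()}
    meta_derep = MetadataTable(meta.table.loc[derep.representatives].copy())

    # 3. domain annotation by anchored transfer
    aligner = make_aligner()
    maps = {rid: annotate_domains(rec, anchors, aligner=aligner)
            for rid, rec in records.items()}
    p_domains = outdir / "domains.tsv"
    write_domain_report(maps, p_domains)
    record("domains", p_domains)

    # 4. per-group motif conservation for every signature pattern
    motif_report = {}
    for group in sorted(set(meta_derep.table["group_label"])):
        members = [(records[rid], maps[rid]) for rid in meta_derep.ids
                   if meta_derep.group_of(rid) == group]
        sig = signatures[group]
        stats = {}
        for pattern in sig.patterns:
            cs = conservation_stats(members, pattern)
            stats[pattern.name] = {
                "whole_motif_fraction": cs.whole_motif_fraction,
                "per_position": [p for p in cs.per_position if p is not None],
                "n_members": cs.n_members,
            }
        motif_report[group] = stats
    p_motifs = outdir / "motifs.json"
    write_json(motif_report, p_motifs)
    record("motifs", p_motifs)

    # 5. distance tree with column-bootstrap supports
    tree = bootstrap_support(derep_msa, config.bootstrap_reps,
                             seed=config.seed + SEED_OFFSET_BOOTSTRAP)
    p_tree = outdir / "tree.nwk"
    tree.write(p_tree)
    record("tree", p_tree)

    # 6. collapse weakly supported clades
    collapsed = collapse(tree, config.collapse_bootstrap)
    p_collapsed = outdir / "tree_collapsed.nwk"
    collapsed.write(p_collapsed)
    record("collapse", p_collapsed)

    # 7. group monophyly on the collapsed tree
    mono_rows = []
    for group in sorted(set(meta_derep.table["group_label"])):
        ids = [rid for rid in meta_derep.ids if meta_derep.group_of(rid) == group]
        if not ids or len(ids) == len(records):
            continue
        ok, sup = test_monophyly(collapsed, ids)
        mono_rows.append({"group": group, "is_monophyletic": ok,
                          "support": "" if sup is None else round(sup, 3)})
    p_mono = outdir / "monophyly.tsv"
    import pandas as pd
    pd.DataFrame(mono_rows).to_csv(p_mono, sep="\t", index=False)
    record("monophyly", p_mono)

    # 8. classify non-initial sequences against the labeled initial set
    initial = [rid for rid in meta_derep.ids
               if meta_derep.table.at[rid, "initial_dataset"]
               and meta_derep.group_of(rid) != "UNC"]
    if not initial:
        initial = [rid for rid in meta_derep.ids
                   if meta_derep.group_of(rid) != "UNC"]
    queries = [records[rid] for rid in meta_derep.ids if rid not in set(initial)]
    reps = [records[rid] for rid in initial]
    labels = {rid: meta_derep.group_of(rid) for rid in initial}
    assignments = classify_all(queries, reps, labels, signatures, anchors)
    p_assign = outdir / "assignments.tsv"
    write_assignments(assignments, p_assign)
    record("classify", p_assign)

    # 9. composition / diversity reports
    final_labels = dict(labels)
    final_labels.update({a.id: a.group for a in assignments})
    comp = composition(final_labels)
    summaries = phylum_summaries(meta_derep, genome_counts)
    matrix = distribution_matrix(final_labels, meta_derep)
    prefix = outdir / "report"
    write_reports(prefix, composition_pct=comp, summaries=summaries,
                  matrix=matrix)
    paths = [Path(f"{prefix}_composition.json"),
             Path(f"{prefix}_phylum_summary.tsv"),
             Path(f"{prefix}_distribution.tsv")]
    record("report", *paths)

    p_manifest = outdir / "manifest.json"
    write_json(manifest, p_manifest)
    return manifest


def write_truth(truth, outdir) -> dict[str, Path]:
    """Write a SyntheticTruth bundle as pipeline-ready input files."""
    from .domains import write_anchor_tsv
    from .io import write_genome_counts, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": outdir / "sequences.fasta",
        "alignment": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.tsv",
        "genome_counts": outdir / "genome_counts.tsv",
        "tree_true": outdir / "tree_true.nwk",
        "anchors_fasta": outdir / "anchors.fasta",
        "anchors_tsv": outdir / "anchors.tsv",
    }
    write_fasta(truth.records, paths["sequences"])
    write_fasta(truth.msa, paths["alignment"])
    write_metadata(truth.metadata, paths["metadata"])
    write_genome_counts(truth.genome_counts, paths["genome_counts"])
    truth.tree.write(paths["tree_true"])
    write_fasta([a.record for a in truth.group_ancestors], paths["anchors_fasta"])
    write_anchor_tsv(truth.group_ancestors, paths["anchors_tsv"])
    return paths
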