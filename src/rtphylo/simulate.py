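"""Synthetic RT-family generator with planted, fully known truth.

Every pipeline stage is exercised against data whose group labels, domain
coordinates, motifs, alignment and tree are known by construction.  The
generator plants a set of groups on a star of group ancestors around a
shared random root sequence; each group then diversifies along a random
ultrametric coalescent-style tree.

Substitution model: sites evolve independently; the number of events on a
branch of length b (expected substitutions/site) is Poisson(b) and each
event replaces the residue uniformly over the 19 alternatives.  Under this
chain the probability that two sequences at distance t agree at a site is

    P(t) = 1/20 + (19/20) * exp(-20 t / 19)

which the tests use as the closed-form identity expectation.  Diagnostic
motif positions are exempt from the clock: after simulation each fixed
motif position in each leaf is retained (ancestral residue) with
probability ``motif_retention_prob`` and otherwise replaced by a uniform
random different residue, so per-position conservation is exactly
Bernoulli(p).  Active-site tetrads get their own retention (default 1.0).

No indels are simulated: within a group all sequences are collinear, and
the true alignment differs between groups only by the gap blocks of
deliberately absent domains (the Abi-style layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AMINO_ACIDS, AlignedRecord, Msa, ProteinRecord
from .domains import DomainMap, ReferenceAnchor
from .io import MetadataTable
from .motifs import compile_pattern
from .phylogeny import SupportTree

import pandas as pd
from skbio import TreeNode

_N_AA = 20

# ---------------------------------------------------------------------------
# layout

#: master segment layout: (segment name, length).  Domain segments are the
#: RT blocks 0..7; "lead"/"tail" are unannotated flanks and "X" the
#: inter-domain region between 2a and 3.
DEFAULT_LAYOUT: tuple[tuple[str, int], ...] = (
    ("lead", 15), ("0", 40), ("1", 35), ("2", 30), ("2a", 20), ("X", 18),
    ("3", 25), ("4", 30), ("5", 35), ("6", 25), ("7", 30), ("tail", 15),
)
#: region Y: trailing part of domain 7 (offset from domain-7 start, length)
REGION_Y_OFFSET, REGION_Y_LEN = 18, 12
#: offset of the catalytic tetrad within domain 5
ACTIVE_SITE_OFFSET = 10

DOMAIN_SEGMENTS = ("0", "1", "2", "2a", "3", "4", "5", "6", "7")


@dataclass(frozen=True)
class PlantedMotif:
    """A concrete motif instance written into a group ancestor.

    ``spec`` is the mini-language pattern the instance satisfies;
    ``region`` the layout segment it sits in ("X", a domain name, or
    ``region_Y``); ``offset`` its position within that region.  Only the
    pattern's fixed (non-wildcard) positions are protected from mutation.
    """

    spec: str
    region: str
    instance: str
    offset: int = 0
    retention: float | None = None  # None -> SimConfig.motif_retention_prob


@dataclass(frozen=True)
class GroupSpec:
    name: str
    size: int
    motifs: tuple[PlantedMotif, ...] = ()
    active_site_variant: str = "YADD"
    active_site_retention: float = 1.0
    absent_domains: tuple[str, ...] = ()
    phylum: str = "PhylumA"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    groups: tuple[GroupSpec, ...]
    within_group_divergence: float = 0.2   # expected subs/site, ancestor->leaf
    between_group_divergence: float = 1.0  # subs/site, root->group ancestor
    motif_retention_prob: float = 0.95
    layout: tuple[tuple[str, int], ...] = DEFAULT_LAYOUT
    phyla_genomes: dict[str, int] = field(
        default_factory=lambda: {"PhylumA": 50, "PhylumB": 40})
    seed: int = 0
    #: members per group flagged as the labeled "initial dataset" (these act
    #: as classification representatives in pipeline runs)
    n_initial_per_group: int = 4

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        if any(g.size < 1 for g in self.groups):
            raise ValueError("group sizes must be >= 1")
        if self.within_group_divergence < 0 or self.between_group_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if not (0.0 <= self.motif_retention_prob <= 1.0):
            raise ValueError("motif_retention_prob must lie in [0, 1]")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        lengths = dict(self.layout)
        for g in self.groups:
            for m in g.motifs:
                region_len = (REGION_Y_LEN if m.region == "region_Y"
                              else lengths.get(m.region))
                if region_len is None:
                    raise ValueError(f"group {g.name}: motif region {m.region!r} "
                                     "not in layout")
                if m.offset + len(m.instance) > region_len:
                    raise ValueError(
                        f"group {g.name}: motif {m.spec!r} does not fit in "
                        f"region {m.region!r}")
                pat = compile_pattern(m.spec)
                if len(pat) != len(m.instance) or not pat.matches_at(m.instance, 0):
                    raise ValueError(
                        f"group {g.name}: instance {m.instance!r} does not "
                        f"satisfy pattern {m.spec!r}")
            for d in g.absent_domains:
                if d not in DOMAIN_SEGMENTS:
                    raise ValueError(f"group {g.name}: unknown domain {d!r}")


# ---------------------------------------------------------------------------
# truth bundle

@dataclass
class SyntheticTruth:
    """Everything the generator knows about one dataset."""

    records: list[ProteinRecord]
    msa: Msa
    tree: SupportTree
    metadata: MetadataTable
    domain_maps: dict[str, DomainMap]
    group_ancestors: list[ReferenceAnchor]  # one per group, usable as anchors
    genome_counts: dict[str, int]
    config: SimConfig

    def labels(self) -> dict[str, str]:
        return self.metadata.labels()

    def members(self, group: str) -> list[str]:
        return [rid for rid, g in self.labels().items() if g == group]


# ---------------------------------------------------------------------------
# generator internals

def _segment_starts(layout) -> dict[str, tuple[int, int]]:
    coords, pos = {}, 0
    for name, length in layout:
        coords[name] = (pos, pos + length)
        pos += length
    return coords


def _mutate(codes: np.ndarray, branch: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(branch) substitution events/site, uniform over 19 alternatives."""
    out = codes.copy()
    k = rng.poisson(branch, size=out.shape)
    while (mask := k > 0).any():
        jumps = rng.integers(1, _N_AA, size=int(mask.sum()))
        out[mask] = (out[mask] + jumps) % _N_AA
        k[mask] -= 1
    return out


def _coalescent_topology(n: int, depth: float, rng: np.random.Generator
                         ) -> tuple[TreeNode, float]:
    """Random ultrametric tree on n leaves: uniform pair joins, join heights
    uniform in (0, depth), every leaf at distance ``depth`` from the top.
    Returns (root TreeNode, height of the root node)."""
    nodes: list[tuple[TreeNode, float]] = [
        (TreeNode(name=str(i)), 0.0) for i in range(n)]
    if n == 1:
        return nodes[0]
    heights = np.sort(rng.uniform(0.0, depth, size=n - 1))
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length, b.length = float(h - ha), float(h - hb)
        parent = TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, float(h)))
    return nodes[0]


def generate(config: SimConfig) -> SyntheticTruth:
    """Generate one labeled dataset; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    coords = _segment_starts(config.layout)
    n_cols = sum(length for _, length in config.layout)
    root_codes = rng.integers(0, _N_AA, size=n_cols)

    aa = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    msa_rows: list[AlignedRecord] = []
    meta_rows = []
    domain_maps: dict[str, DomainMap] = {}
    anchors: list[ReferenceAnchor] = []
    tree_root = TreeNode()

    for group in config.groups:
        ancestor = _mutate(root_codes, config.between_group_divergence, rng)

        # column mask: present master columns for this group
        mask = np.ones(n_cols, dtype=bool)
        for d in group.absent_domains:
            s, e = coords[d]
            mask[s:e] = False

        # plant motifs and the active-site tetrad (master coordinates)
        planted: list[tuple[np.ndarray, np.ndarray, float]] = []
        for m in group.motifs:
            if m.region == "region_Y":
                base = coords["7"][0] + REGION_Y_OFFSET
            else:
                base = coords[m.region][0]
            start = base + m.offset
            sites = np.arange(start, start + len(m.instance))
            inst = np.array([AMINO_ACIDS.index(c) for c in m.instance])
            fixed = np.array([e is not None
                              for e in compile_pattern(m.spec).elements])
            ancestor[sites] = inst
            if not mask[sites].all():
                raise ValueError(f"group {group.name}: motif {m.spec!r} placed "
                                 "in an absent domain")
            p = (config.motif_retention_prob if m.retention is None
                 else m.retention)
            planted.append((sites[fixed], inst[fixed], p))
        if "5" not in group.absent_domains:
            s5 = coords["5"][0] + ACTIVE_SITE_OFFSET
            sites = np.arange(s5, s5 + 4)
            inst = np.array([AMINO_ACIDS.index(c)
                             for c in group.active_site_variant])
            ancestor[sites] = inst
            planted.append((sites, inst, group.active_site_retention))

        # ungapped group coordinates -> DomainMap shared by all members
        upos = np.cumsum(mask) - 1  # master col -> ungapped position
        def to_ungapped(interval):
            s, e = interval
            return (int(upos[s]), int(upos[e - 1]) + 1)
        intervals = {d: to_ungapped(coords[d]) for d in DOMAIN_SEGMENTS
                     if d not in group.absent_domains}
        region_y = None
        if "7" not in group.absent_domains:
            s7 = coords["7"][0]
            region_y = to_ungapped((s7 + REGION_Y_OFFSET,
                                    s7 + REGION_Y_OFFSET + REGION_Y_LEN))
        active = None
        if "5" not in group.absent_domains:
            active = int(upos[coords["5"][0] + ACTIVE_SITE_OFFSET])
        gmap = DomainMap(intervals, region_y=region_y, active_site=active)

        anc_seq = "".join(aa[ancestor[mask]])
        anchors.append(ReferenceAnchor(
            ProteinRecord(f"{group.name}_ancestor", anc_seq,
                          f"synthetic ancestor of {group.name}"), gmap))

        # diversify along an ultrametric coalescent-style tree
        top, height = _coalescent_topology(
            group.size, config.within_group_divergence, rng)
        top.length = config.within_group_divergence - height
        leaf_codes: dict[TreeNode, np.ndarray] = {}
        stack: list[tuple[TreeNode, np.ndarray]] = [(top, ancestor)]
        while stack:
            node, parent_seq = stack.pop(0)
            evolved = _mutate(parent_seq, node.length, rng)
            if node.is_tip():
                leaf_codes[node] = evolved
            else:
                stack.extend((c, evolved) for c in node.children)

        # rename leaves, apply motif retention, emit records
        leaves = sorted(leaf_codes, key=lambda t: int(t.name))
        for k, leaf in enumerate(leaves):
            rid = f"{group.name}_{k:02d}"
            leaf.name = rid
            codes = leaf_codes[leaf]
            for sites, inst, p in planted:
                keep = rng.random(len(sites)) < p
                codes[sites[keep]] = inst[keep]
                lost = ~keep
                if lost.any():
                    jumps = rng.integers(1, _N_AA, size=int(lost.sum()))
                    codes[sites[lost]] = (inst[lost] + jumps) % _N_AA
            row = np.where(mask, codes, -1)
            msa_rows.append(AlignedRecord(
                rid, "".join("-" if c < 0 else aa[c] for c in row)))
            seq = "".join(aa[codes[mask]])
            records.append(ProteinRecord(rid, seq, f"synthetic {group.name}"))
            domain_maps[rid] = gmap
            meta_rows.append({
                "id": rid, "group_label": group.name, "phylum": group.phylum,
                "initial_dataset": k < min(config.n_initial_per_group, group.size),
                "length_aa": len(seq)})

        # attach to the global star of group ancestors
        top.length += config.between_group_divergence
        tree_root.append(top)

    meta = MetadataTable(
        pd.DataFrame(meta_rows).set_index("id", verify_integrity=True))
    truth = SyntheticTruth(
        records=records,
        msa=Msa(msa_rows),
        tree=SupportTree(tree_root),
        metadata=meta,
        domain_maps=domain_maps,
        group_ancestors=anchors,
        genome_counts=dict(config.phyla_genomes),
        config=config,
    )
    return truth


def expected_identity(distance: float) -> float:
    """Closed-form expected % identity between two sequences separated by
    ``distance`` expected substitutions/site under the generator's chain."""
    return 100.0 * (1.0 / _N_AA + (_N_AA - 1) / _N_AA
                    * np.exp(-_N_AA * distance / (_N_AA - 1)))


# ---------------------------------------------------------------------------
# standard study conditions

def benchmark_groups() -> tuple[GroupSpec, ...]:
    """Eight groups with the diagnostic signatures of the named lineages."""
    return (
        GroupSpec("group_II", 12, active_site_variant="YADD", phylum="PhylumA"),
        GroupSpec("retron", 12, motifs=(
            PlantedMotif("VTG", "region_Y", "VTG", offset=2),
            PlantedMotif("NAxxH", "X", "NAQLH", offset=4),
        ), active_site_variant="YADD", phylum="PhylumA"),
        GroupSpec("DGR", 12, motifs=(
            PlantedMotif("[IVL]Gx(3)SQ", "4", "IGAVMSQ", offset=8),
        ), active_site_variant="YVDD", phylum="PhylumB"),
        GroupSpec("Abi", 12, absent_domains=("0", "2a", "7"),
                  active_site_variant="YRDD", phylum="PhylumB"),
        GroupSpec("CRISPR-RT", 12, active_site_variant="FADD", phylum="PhylumA"),
        GroupSpec("G2L4", 12, active_site_variant="YIDD", phylum="PhylumB"),
        GroupSpec("UG10", 12, active_site_variant="YVDD", phylum="PhylumA"),
        GroupSpec("UG2", 12, active_site_variant="YADD", phylum="PhylumB"),
    )


# ---------------------------------------------------------------------------
# truth recovery

@dataclass(frozen=True)
class RecoveryReport:
    """How well pipeline outputs recover the planted truth."""

    classification_accuracy: float | None = None
    monophyly: dict[str, bool] | None = None
    domain_boundary_mae: float | None = None
    derep_max_identity_ok: bool | None = None
    derep_coverage_ok: bool | None = None

    @property
    def all_monophyletic(self) -> bool | None:
        if self.monophyly is None:
            return None
        return all(self.monophyly.values())


def truth_compare(truth: SyntheticTruth, *, assignments: dict[str, str] | None = None,
                  tree: SupportTree | None = None,
                  domain_maps: dict[str, DomainMap] | None = None,
                  derep=None, identity=None) -> RecoveryReport:
    """Score pipeline outputs against the generator truth.

    Any subset of outputs may be supplied; ids must be drawn from the
    generated dataset.
    """
    true_labels = truth.labels()

    accuracy = None
    if assignments is not None:
        unknown = set(assignments) - set(true_labels)
        if unknown:
            raise ValueError(f"assignments for unknown ids {sorted(unknown)[:5]}")
        if not assignments:
            raise ValueError("empty assignment set")
        accuracy = float(np.mean(
            [assignments[rid] == true_labels[rid] for rid in assignments]))

    monophyly = None
    if tree is not None:
        from .phylogeny import test_monophyly
        leaf_names = tree.leaf_names
        if not leaf_names <= set(true_labels):
            raise ValueError("tree contains leaves outside the generated dataset")
        monophyly = {}
        for group in sorted({true_labels[l] for l in leaf_names}):
            members = [l for l in leaf_names if true_labels[l] == group]
            if 0 < len(members) < len(leaf_names):
                monophyly[group] = test_monophyly(tree, members)[0]

    mae = None
    if domain_maps is not None:
        errs = []
        for rid, dmap in domain_maps.items():
            if rid not in truth.domain_maps:
                raise ValueError(f"domain map for unknown id {rid!r}")
            true_map = truth.domain_maps[rid]
            for d, (s, e) in dmap.intervals.items():
                if d in true_map.intervals:
                    ts, te = true_map.intervals[d]
                    errs.extend([abs(s - ts), abs(e - te)])
        mae = float(np.mean(errs)) if errs else None

    max_ok = cov_ok = None
    if derep is not None:
        if identity is None:
            raise ValueError("derep check needs the identity matrix")
        reps = derep.representatives
        sub = identity.submatrix(reps)
        off_diag = sub.values[~np.eye(len(reps), dtype=bool)]
        max_ok = bool(off_diag.size == 0 or off_diag.max() <= derep.threshold)
        cov_ok = set(reps) | set(derep.membership) == set(identity.ids)

    return RecoveryReport(accuracy, monophyly, mae, max_ok, cov_ok)


def benchmark_config(seed: int = 42) -> SimConfig:
    """The fixed benchmark: 8 groups x 12 sequences, within-group divergence
    0.2 subs/site, between-group 1.0, motif retention 0.95."""
    return SimConfig(groups=benchmark_groups(), within_group_divergence=0.2,
                     between_group_divergence=1.0, motif_retention_prob=0.95,
                     phyla_genomes={"PhylumA": 50, "PhylumB": 40}, seed=seed)
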