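"""Motif mini-language, restricted scanning, active-site calls and
conservation statistics."""

import numpy as np
import pytest

from rtphylo.core import ProteinRecord
from rtphylo.domains import DomainMap
from rtphylo.motifs import (PatternError, call_active_site, compile_pattern,
                            conservation_stats, first_position_variant_fraction,
                            scan)

AA = "ACDEFGHIKLMNPQRSTVWY"


# -- compilation ------------------------------------------------------------

def test_naxxh_compiles_to_five_elements():
    pat = compile_pattern("NAxxH")
    assert len(pat) == 5
    assert pat.elements[0] == frozenset("N")
    assert pat.elements[2] is None and pat.elements[3] is None
    assert pat.elements[4] == frozenset("H")


def test_dgr_motif_compiles_class_first():
    pat = compile_pattern("[IVL]Gx(3)SQ")
    assert len(pat) == 7
    assert pat.elements[0] == frozenset("IVL")
    assert pat.elements[2] is pat.elements[3] is pat.elements[4] is None
    assert pat.elements[5:] == (frozenset("S"), frozenset("Q"))


def test_uppercase_x_is_prose_wildcard():
    assert compile_pattern("NAXXH").elements == compile_pattern("NAxxH").elements


def test_lone_wildcard_is_rejected():
    with pytest.raises(PatternError):
        compile_pattern("x")


def test_malformed_pattern_reports_column():
    with pytest.raises(PatternError) as err:
        compile_pattern("NA*H")
    assert err.value.column == 2


def test_invalid_class_residue_rejected():
    with pytest.raises(PatternError):
        compile_pattern("[BJ]DD")


# -- scanning ---------------------------------------------------------------

def _seq_with_windows(seq):
    """Full sequence as domain 7, region Y = [10, 20)."""
    return ProteinRecord("q", seq), DomainMap({"7": (0, len(seq))},
                                              region_y=(10, 20))


def test_planted_match_inside_region_y_found():
    seq, dmap = _seq_with_windows("A" * 12 + "VTG" + "A" * 10)
    pat = compile_pattern("VTG", restriction="region_Y")
    res = scan(seq, dmap, pat)
    assert res.status == "ok"
    assert [h.start for h in res.hits] == [12]
    assert res.hits[0].matched == "VTG"


def test_match_outside_restricted_window_not_reported():
    seq, dmap = _seq_with_windows("VTG" + "A" * 22)  # only before region Y
    pat = compile_pattern("VTG", restriction="region_Y")
    assert scan(seq, dmap, pat).hits == ()
    # the unrestricted scan does see it
    assert scan(seq, dmap, compile_pattern("VTG")).hits[0].start == 0


def test_region_absent_outcome():
    seq = ProteinRecord("q", "VTGAAAA")
    pat = compile_pattern("VTG", restriction="region_Y")
    res = scan(seq, DomainMap({"5": (0, 7)}), pat)
    assert res.status == "region-absent"
    assert not res.found


def test_wildcard_does_not_match_ambiguity_character():
    seq = ProteinRecord("q", "NAXXHNAGGH")
    pat = compile_pattern("NAxxH")
    res = scan(seq, DomainMap({}), pat)
    assert [h.start for h in res.hits] == [5]


def naive_sliding_scan(seq, window, pattern):
    """Independent oracle: check the pattern at every window offset."""
    ws, we = window
    hits = []
    for p in range(ws, we - len(pattern) + 1):
        ok = True
        for off, elem in enumerate(pattern.elements):
            ch = seq[p + off]
            if elem is None:
                if ch not in AA:
                    ok = False
                    break
            elif ch not in elem:
                ok = False
                break
        if ok:
            hits.append(p)
    return hits


@pytest.mark.parametrize("seed", range(20))
def test_scanner_equals_naive_oracle_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    pat = compile_pattern("[IVL]Gx(3)SQ", restriction="4")
    n = int(rng.integers(60, 120))
    seq = "".join(rng.choice(list(AA + "X"), size=n))
    # plant a couple of instances to guarantee hits
    for pos in rng.choice(max(n - 7, 1), size=2, replace=False):
        seq = seq[:pos] + "VGAAASQ" + seq[pos + 7:]
    window = (5, n - 3)
    rec = ProteinRecord("q", seq)
    dmap = DomainMap({"4": window})
    got = [h.start for h in scan(rec, dmap, pat).hits]
    assert got == naive_sliding_scan(seq, window, pat)


def test_restriction_never_adds_hits(benchmark_truth):
    pat_restricted = compile_pattern("NAxxH", restriction="region_X")
    pat_full = compile_pattern("NAxxH")
    for rec in benchmark_truth.records[::9]:
        dmap = benchmark_truth.domain_maps[rec.id]
        restricted = {h.start for h in scan(rec, dmap, pat_restricted).hits}
        full = {h.start for h in scan(rec, dmap, pat_full).hits}
        assert restricted <= full


# -- active site ------------------------------------------------------------

@pytest.mark.parametrize("segment, tetrad, variant", [
    ("QYADDLL", "YADD", "YADD"),
    ("QYIDDLL", "YIDD", "YIDD"),   # the G2L4 hallmark
    ("QFADDLL", "FADD", "FADD"),   # Y -> F substitution
    ("QYRDDLL", "YRDD", "YRDD"),
    ("QQADDLL", "QADD", "other"),  # only the DD dyad left
    ("QQAQQLL", None, "absent"),
])
def test_active_site_calls(segment, tetrad, variant):
    seq = ProteinRecord("q", "MMM" + segment + "KKK")
    dmap = DomainMap({"5": (3, 3 + len(segment))})
    call = call_active_site(seq, dmap)
    assert call.tetrad == tetrad
    assert call.variant == variant


def test_active_site_absent_domain5():
    call = call_active_site(ProteinRecord("q", "YADD"), DomainMap({}))
    assert call.variant == "absent"


def test_leftmost_tetrad_wins():
    seq = ProteinRecord("q", "YIDDAAYADD")
    dmap = DomainMap({"5": (0, 10)})
    assert call_active_site(seq, dmap).tetrad == "YIDD"


# -- conservation -----------------------------------------------------------

def _members(n_with, n_without):
    pat_seq = "A" * 4 + "NAQLH" + "A" * 4
    bare_seq = "A" * 13
    members = []
    for i in range(n_with):
        members.append((ProteinRecord(f"w{i}", pat_seq),
                        DomainMap({"2": (0, 2), "3": (13, 13 + 1)})))
    for i in range(n_without):
        members.append((ProteinRecord(f"o{i}", bare_seq),
                        DomainMap({"2": (0, 2), "3": (13, 13 + 1)})))
    # widen domain 3 so region X = (2, 13) covers the motif
    fixed = []
    for rec, _ in members:
        fixed.append((rec, DomainMap({"2": (0, 2), "3": (12, 13)})))
    return fixed


def test_whole_motif_fraction_all_carriers():
    pat = compile_pattern("NAxxH", restriction="region_X")
    stats = conservation_stats(_members(10, 0), pat)
    assert stats.whole_motif_fraction == 1.0


def test_whole_motif_fraction_half_carriers():
    pat = compile_pattern("NAxxH", restriction="region_X")
    stats = conservation_stats(_members(5, 5), pat)
    assert stats.whole_motif_fraction == 0.5


def test_empty_group_is_error():
    with pytest.raises(ValueError):
        conservation_stats([], compile_pattern("VTG"))


def test_per_position_fraction_tracks_retention_probability():
    """With per-site retention p, each fixed position's conservation is a
    Binomial(n, p) proportion; check the pooled estimate lies in the 95%
    band around p."""
    from rtphylo.simulate import (GroupSpec, PlantedMotif, SimConfig, generate)

    p = 0.8
    n = 60
    config = SimConfig(
        groups=(GroupSpec("retron", n, motifs=(
            PlantedMotif("NAxxH", "X", "NAQLH", offset=4),)),),
        within_group_divergence=0.05, between_group_divergence=0.0,
        motif_retention_prob=p, seed=11)
    truth = generate(config)
    pat = compile_pattern("NAxxH", restriction="region_X")
    members = [(r, truth.domain_maps[r.id]) for r in truth.records]
    stats = conservation_stats(members, pat)
    fixed = [f for f in stats.per_position if f is not None]
    assert len(fixed) == 3  # N, A, H
    half_width = 1.96 * np.sqrt(p * (1 - p) / (n * len(fixed)))
    assert abs(np.mean(fixed) - p) < half_width + 1.0 / n


def test_whole_motif_fraction_bounded_by_per_position_minimum(benchmark_truth):
    pat = compile_pattern("NAxxH", restriction="region_X")
    members = [(r, benchmark_truth.domain_maps[r.id])
               for r in benchmark_truth.records
               if benchmark_truth.labels()[r.id] == "retron"]
    stats = conservation_stats(members, pat)
    fixed = [f for f in stats.per_position if f is not None]
    assert stats.whole_motif_fraction <= min(fixed) + 1e-12


def test_first_position_variant_counting():
    """A sequence counts toward VTG only on exact V; I/L in first position
    with TG following counts toward the variant fraction instead."""
    dmap = DomainMap({"7": (0, 9)}, region_y=(0, 9))
    members = [
        (ProteinRecord("v", "AAVTGAAAA"), dmap),
        (ProteinRecord("i", "AAITGAAAA"), dmap),
        (ProteinRecord("l", "AALTGAAAA"), dmap),
        (ProteinRecord("n", "AAGTGAAAA"), dmap),
    ]
    pat = compile_pattern("VTG", restriction="region_Y")
    exact = conservation_stats(members, pat).whole_motif_fraction
    variant = first_position_variant_fraction(members, pat, "VIL")
    assert exact == 0.25
    assert variant == 0.5


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st

_element = st.one_of(
    st.sampled_from(list(AA)),                                   # residue
    st.just("x"),                                                # wildcard
    st.builds(lambda s: "[" + "".join(sorted(set(s))) + "]",
              st.text(alphabet=AA, min_size=1, max_size=4)),     # class
)


@given(st.lists(_element, min_size=2, max_size=8), st.data())
@settings(derandomize=True, max_examples=60, deadline=None)
def test_compiled_pattern_matches_its_own_realisations(parts, data):
    """Any sequence built by choosing one allowed residue per element
    matches at the planted position."""
    spec = "".join(parts)
    if sum(1 for p in parts if p != "x") < 2:
        return
    pat = compile_pattern(spec)
    assert len(pat) == len(parts)
    realised = "".join(
        data.draw(st.sampled_from(sorted(e))) if e is not None
        else data.draw(st.sampled_from(list(AA)))
        for e in pat.elements)
    seq = "MK" + realised + "KM"
    hits = scan(ProteinRecord("q", seq), DomainMap({}), pat).hits
    assert 2 in {h.start for h in hits}
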