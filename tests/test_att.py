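"""att direct-repeat detection, element delineation and circularization,
checked against brute-force string-splicing oracles."""

import numpy as np
import pytest

import oracles
from icemob._seq import revcomp, rotations_equal
from icemob.att import (AttParams, UnresolvableMultipartite,
                        delineate_monopartite, disambiguate_integrated_plasmid,
                        excise, find_att_pairs, group_interleaved,
                        resolve_multipartite)
from icemob.genome_io import locate_anchors
from icemob.model import GeneFeature, GenomeRecord, Replicon

CORE = 17


def _delineate_mono(genome, anchors, seeds):
    rep = genome.replicons[0]
    pairs = find_att_pairs(rep, anchors, seeds)
    assert len(pairs) == 1
    return delineate_monopartite(pairs[0], genome)


def test_monopartite_recovery_and_roundtrip(rng):
    """Planted exact repeats give bp-exact boundaries; excision +
    re-integration reproduces the replicon byte-for-byte."""
    for _ in range(25):
        genome, anchors, seeds, truth = oracles.build_monopartite_case(rng)
        el = _delineate_mono(genome, anchors, seeds)
        fr = el.fragments[0]
        assert (fr.start, fr.end) == truth["fragment"]
        pair = el.att_pairs[0]
        assert pair.attL == truth["attL"] and pair.attR == truth["attR"]
        assert pair.core.core_sequence == truth["core"]
        assert len(el.circular_sequence) == fr.length - CORE
        scar = excise(truth["original"], el)
        rebuilt = oracles.mono_reintegrate(scar, el.circular_sequence,
                                           truth["attL"][0], CORE)
        assert rebuilt == truth["original"]


def test_tripartite_resolution_and_circle(rng):
    """Three interleaved pairs resolve into alpha/beta/gamma fragments whose
    circle equals the independent string-splice reconstruction."""
    for _ in range(12):
        genome, anchors, seeds, truth = oracles.build_tripartite_case(rng)
        rep = genome.replicons[0]
        pairs = find_att_pairs(rep, anchors, seeds)
        assert len(pairs) == 3
        (group,) = group_interleaved(pairs)
        el = resolve_multipartite(group, genome, seeds)
        assert el.partite_count == 3
        got = sorted((f.start, f.end) for f in el.fragments)
        assert got == sorted(truth["fragments"].values())
        oracle_circle = oracles.circle_by_splicing(truth["original"],
                                                   truth["join_order"], CORE)
        # the reconstruction may open the circle at a different core
        assert rotations_equal(el.circular_sequence, oracle_circle)
        assert len(el.circular_sequence) == \
            sum(e - s for s, e in truth["fragments"].values()) - 3 * CORE
        roles = {f.role: f.length for f in el.fragments}
        assert roles["alpha"] >= roles["beta"] >= roles["gamma"]
        # scar: each fragment collapses to its left core
        scar = excise(truth["original"], el)
        assert scar == oracles.scar_by_splicing(
            truth["original"], truth["fragments"].values(), CORE)


def test_tripartite_missing_pair_unresolvable(rng):
    """Corrupting one att pair leaves a join graph that must be rejected."""
    genome, anchors, seeds, truth = oracles.build_tripartite_case(
        rng, corrupt_pair=2)
    rep = genome.replicons[0]
    pairs = find_att_pairs(rep, anchors, seeds)
    assert len(pairs) == 2
    (group,) = group_interleaved(pairs)
    with pytest.raises(UnresolvableMultipartite):
        resolve_multipartite(group, genome, seeds)


def test_single_pair_passthrough(rng):
    genome, anchors, seeds, _ = oracles.build_monopartite_case(rng)
    rep = genome.replicons[0]
    pairs = find_att_pairs(rep, anchors, seeds)
    el = resolve_multipartite(pairs, genome, seeds)
    assert el.partite_count == 1


def test_pair_requires_enclosed_seed(rng):
    """A repeat pair enclosing no mobility gene is not reported."""
    genome, anchors, _, truth = oracles.build_monopartite_case(rng)
    rep = genome.replicons[0]
    outside = truth["fragment"][1] + 200
    assert find_att_pairs(rep, anchors, [(outside, outside + 30)]) == []
    assert find_att_pairs(rep, anchors, []) == []


def test_reverse_complement_mirrors_delineation(rng):
    """RC-ing the replicon yields mirror coordinates and the same circle
    up to rotation/strand."""
    genome, anchors, seeds, truth = oracles.build_monopartite_case(rng)
    el = _delineate_mono(genome, anchors, seeds)
    rep = genome.replicons[0]
    L = len(rep)
    flipped = GenomeRecord(
        "case_rc", [Replicon("rep", revcomp(rep.sequence))],
        [GeneFeature(f.locus_id, "rep", L - f.end, L - f.start,
                     "-" if f.strand == "+" else "+", f.kind, f.product,
                     f.protein, f.trna_isotype) for f in genome.features])
    anchors_rc = locate_anchors(flipped)
    seeds_rc = [(L - e, L - s) for s, e in seeds]
    el_rc = _delineate_mono(flipped, anchors_rc, seeds_rc)
    fr, fr_rc = el.fragments[0], el_rc.fragments[0]
    assert (fr_rc.start, fr_rc.end) == (L - fr.end, L - fr.start)
    assert rotations_equal(el_rc.circular_sequence,
                           revcomp(el.circular_sequence))


def test_seed_order_invariance(rng):
    genome, anchors, seeds, _ = oracles.build_tripartite_case(rng)
    rep = genome.replicons[0]
    seeds2 = list(reversed(seeds))
    p1 = find_att_pairs(rep, anchors, seeds)
    p2 = find_att_pairs(rep, anchors, seeds2)
    assert [(p.attL, p.attR) for p in p1] == [(p.attL, p.attR) for p in p2]


def test_fragment_shorter_than_two_cores_rejected():
    seq = "A" * 50 + "ACGTACGTACGTACGTA" + "ACGTACGTACGTACGTA" + "C" * 50
    genome = GenomeRecord("g", [Replicon("rep", seq)], [])
    from icemob.model import AttCore, AttSitePair
    pair = AttSitePair("rep", (50, 67), (66, 83), AttCore(seq[50:67]), None)
    with pytest.raises(ValueError):
        delineate_monopartite(pair, genome)


def test_requested_fragment_length_is_exact():
    """A planted element with a requested 65,889-bp fragment is recovered
    with exactly that length."""
    from icemob.simulate import ElementSpec, SimulationConfig, simulate_mobilome
    spec = ElementSpec("BIG", 0, "ICE", [("tRNA-Phe", 50_000)],
                       divergence=0.08, fragment_lengths=[65_889])
    cfg = SimulationConfig(seed=4, n_genomes=1, chromosome_length=200_000,
                           n_core_families=2, n_accessory_per_genome=1,
                           elements=[spec])
    (genome,), truth = simulate_mobilome(cfg)
    s, e = truth["elements"]["BIG"]["fragments"][0]
    assert e - s == 65_889
    from icemob.homology import search_panel
    from icemob.panel import default_panel
    hits = search_panel(genome, default_panel())
    anchors = locate_anchors(genome, hits=hits)
    feats = {f.locus_id: f for f in genome.features}
    seeds = [(feats[h.query_locus].start, feats[h.query_locus].end)
             for h in hits if h.role_category.startswith(("integrase",
                                                          "t4ss", "relax",
                                                          "backbone"))]
    pairs = find_att_pairs(genome.replicons[0], anchors, seeds)
    el = delineate_monopartite(pairs[0], genome)
    assert (el.fragments[0].start, el.fragments[0].end) == (s, e)
    assert len(el.circular_sequence) == 65_889 - CORE


@pytest.mark.parametrize("repabc,att,expected", [
    (True, False, "flag_assembly_artifact"),
    (True, True, "keep_as_element"),
    (False, False, "keep_as_element"),
])
def test_integrated_plasmid_disambiguation(repabc, att, expected):
    assert disambiguate_integrated_plasmid(repabc, att) == expected
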