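"""Panel search, MOB relaxase typing, conjugation clusters, integrases."""

import numpy as np
import pytest

import oracles
from icemob._seq import mutate_cds, mutate_protein, random_protein
from icemob.homology import (align_pair, classify_relaxases,
                             detect_conjugation_clusters, detect_integrases,
                             parse_hmm_table, search_panel)
from icemob.model import GeneFeature, GenomeRecord, HomologyHit, Replicon
from icemob.panel import ReferencePanel, default_panel


def test_identical_sequences_full_identity(panel):
    ex = panel.get("REF_TRBB")
    hits = search_panel([("q1", ex.protein)], panel)
    top = hits[0]
    assert top.exemplar_id == "REF_TRBB"
    assert top.percent_identity == pytest.approx(100.0)
    assert top.query_coverage == pytest.approx(1.0)


def test_fifty_percent_nucleotide_cutoff(panel, rng):
    """A trbB homolog just under the 50% identity cutoff is not reported;
    just over, it is."""
    ex = panel.get("REF_TRBB")
    low, _ = mutate_cds(ex.nucleotide, 0.55, rng)  # ~45% identity
    hi, _ = mutate_cds(ex.nucleotide, 0.40, rng)  # ~60% identity
    hits_low = [h for h in search_panel([("q", low)], panel, min_identity=50,
                                        min_coverage=0.5, seq_type="nucleotide")
                if h.exemplar_id == "REF_TRBB"]
    hits_hi = [h for h in search_panel([("q", hi)], panel, min_identity=50,
                                       min_coverage=0.5, seq_type="nucleotide")
               if h.exemplar_id == "REF_TRBB"]
    assert hits_low == []
    assert hits_hi and hits_hi[0].percent_identity >= 50


def test_reported_identity_tracks_simulated_divergence(panel, rng):
    """A cargo gene emitted at a 70% nucleotide identity target is reported
    within +/-3 points of the identity measured by an exhaustive alignment
    oracle."""
    ex = panel.get("REF_NIFH")
    mutant, realized = mutate_cds(ex.nucleotide, 0.30, rng)
    hits = [h for h in search_panel([("q", mutant)], panel, min_identity=30,
                                    min_coverage=0.5, seq_type="nucleotide")
            if h.exemplar_id == "REF_NIFH"]
    assert hits
    ungapped = 100.0 * sum(a == b for a, b in zip(mutant, ex.nucleotide)) \
        / len(mutant)
    assert abs(100 * (1 - realized) - 70.0) <= 1.0
    assert abs(hits[0].percent_identity - ungapped) <= 3.0
    assert abs(hits[0].percent_identity - 70.0) <= 3.0


def test_identity_symmetry(rng):
    for _ in range(5):
        a = random_protein(rng, 60)
        b = mutate_protein(a, 0.3, rng)
        ra = align_pair(a, b, "protein")
        rb = align_pair(b, a, "protein")
        assert ra[0] == pytest.approx(rb[0], abs=1e-9)


def test_local_score_matches_exhaustive_dp(rng):
    """Best local alignment score equals a Gotoh DP oracle on short
    proteins."""
    sub = oracles.blosum62_fn()
    for _ in range(8):
        a = random_protein(rng, int(rng.integers(20, 60)))
        b = mutate_protein(a, float(rng.uniform(0.1, 0.6)), rng)
        got = align_pair(a, b, "protein")
        want = oracles.local_align_score(a, b, sub, -11.0, -1.0)
        assert got[3] == pytest.approx(want)


def _hit(locus, ex, role, score, evalue, ident=90.0):
    return HomologyHit(locus, ex, role, ident, 0.9, 0.9, score, evalue)


def test_relaxase_family_rules():
    """Threshold 33; best full-sequence e-value breaks family ties; MOB_P
    subtype 1 recognised; one family per locus; input-order invariant."""
    hits = [
        _hit("l1", "REF_MOBP1", "relaxase:MOB_P1", 50.0, 1e-40),
        _hit("l2", "REF_MOBQ", "relaxase:MOB_Q", 32.0, 1e-10),
        _hit("l3", "REF_MOBP1", "relaxase:MOB_P1", 60.0, 1e-40),
        _hit("l3", "REF_MOBQ", "relaxase:MOB_Q", 70.0, 1e-35),
    ]
    calls = classify_relaxases(hits, bit_threshold=33)
    by = {c.query_locus: c for c in calls}
    assert by["l1"].family == "MOB_P" and by["l1"].subtype == "P1"
    assert "l2" not in by  # score below threshold
    assert by["l3"].family == "MOB_P"  # better e-value despite lower score
    calls_rev = classify_relaxases(list(reversed(hits)), bit_threshold=33)
    assert calls == calls_rev


def test_relaxase_from_hmm_table(tmp_path):
    table = tmp_path / "scan.tbl"
    table.write_text(
        "# hmmscan tblout\n"
        "MOBP1  PF0001  locusA  -  1e-50  120.0  0.1 other fields\n"
        "MOBQ   PF0002  locusA  -  1e-20  80.0   0.1 other fields\n"
        "MOBF   PF0003  locusB  -  1e-5   20.0   0.1 other fields\n"
        "badline\n")
    with pytest.warns(UserWarning):
        rows = parse_hmm_table(str(table))
    calls = classify_relaxases(rows, bit_threshold=33)
    assert len(calls) == 1
    (c,) = calls
    assert (c.query_locus, c.family, c.subtype) == ("locusA", "MOB_P", "P1")
    assert c.decision_basis == "hmm_table"


def _genome_with(loci):
    """loci: list of (locus, start, end, strand)."""
    feats = [GeneFeature(l, "chr", s, e, st, "CDS", product=l, protein="M" * 60)
             for l, s, e, st in loci]
    return GenomeRecord("g", [Replicon("chr", "A" * 200_000)], feats)


def test_trb_cluster_typed(panel):
    roles = ["t4ss_trb:msi031"] + [f"t4ss_trb:trb{x}" for x in "BCDEJLFGI"] + \
        ["t4ss_trb:msi021"]
    loci = [(f"t{i}", 1000 * i, 1000 * i + 600, "+") for i in range(len(roles))]
    genome = _genome_with(loci)
    hits = [_hit(l, f"REF_{r.split(':')[1].upper()}", r, 100, 1e-30)
            for (l, _, _, _), r in zip(loci, roles)]
    (cl,) = detect_conjugation_clusters(genome, hits)
    assert cl.cluster_type == "trb_T4SS"
    assert cl.completeness == pytest.approx(1.0)


def test_traacd_cluster_divergent_orientation():
    loci = [("c1", 1000, 1400, "-"), ("a1", 1520, 2400, "+"),
            ("r1", 2450, 2700, "+"), ("d1", 2750, 3050, "+")]
    genome = _genome_with(loci)
    hits = [_hit("c1", "REF_TRAC", "relaxosome:traC", 90, 1e-20),
            _hit("a1", "REF_TRAA", "relaxosome:traA", 95, 1e-30),
            _hit("r1", "REF_RDFS", "rdf:rdfS", 60, 1e-10),
            _hit("d1", "REF_TRAD", "relaxosome:traD", 55, 1e-10)]
    (cl,) = detect_conjugation_clusters(genome, hits)
    assert cl.cluster_type == "traACD"
    assert cl.completeness == pytest.approx(1.0)
    assert "divergent" in cl.orientation_notes
    assert "RDF" in cl.orientation_notes
    # same orientation -> no traACD call
    genome2 = _genome_with([("c1", 1000, 1400, "+")] + loci[1:])
    clusters = detect_conjugation_clusters(genome2, hits)
    assert all(c.cluster_type != "traACD" for c in clusters)


def test_lone_vird4_is_t4cp_only():
    genome = _genome_with([("v1", 5000, 6200, "+")])
    hits = [_hit("v1", "REF_VIRD4", "t4cp:virD4", 80, 1e-25)]
    (cl,) = detect_conjugation_clusters(genome, hits)
    assert cl.cluster_type == "T4CP_only"


def test_cluster_window_splits_distant_loci():
    genome = _genome_with([("a", 1000, 1600, "+"), ("b", 50_000, 50_600, "+")])
    hits = [_hit("a", "REF_TRAG", "t4cp:traG", 80, 1e-25),
            _hit("b", "REF_VIRD4", "t4cp:virD4", 80, 1e-25)]
    clusters = detect_conjugation_clusters(genome, hits, locus_window=10_000)
    assert len(clusters) == 2


def test_integrase_classes(panel, rng):
    ex = panel.get("REF_INTS")
    hits = search_panel([("i1", ex.protein)], panel)
    calls = detect_integrases(hits)
    assert calls and calls[0].int_class == "tyrosine"
    assert calls[0].int_family == "intS"
    ser = panel.get("REF_INTSER")
    calls2 = detect_integrases(search_panel([("i2", ser.protein)], panel))
    assert calls2[0].int_class == "serine"
    # planted intM at ~80% amino-acid identity keeps its family
    mut = mutate_protein(panel.get("REF_INTM").protein, 0.20, rng)
    calls3 = detect_integrases(search_panel([("i3", mut)], panel))
    assert calls3[0].int_family == "intM"


def test_empty_inputs(panel):
    assert search_panel([], panel) == []
    with pytest.raises(ValueError):
        search_panel([("q", "MKV")], ReferencePanel([]))


def test_panel_fasta_round_trip(tmp_path, panel):
    p = tmp_path / "panel.faa"
    panel.write_fasta(p)
    back = ReferencePanel.read_fasta(p)
    assert {(e.exemplar_id, e.role_label) for e in back.entries} == \
        {(e.exemplar_id, e.role_label) for e in panel.entries}
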