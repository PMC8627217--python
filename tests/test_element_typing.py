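"""Element classification rules, symbiosis flag, QS profiling, redundancy
collapse and motif scanning."""

import numpy as np
import pandas as pd
import pytest

from icemob.element_typing import (ElementContext, build_motif, classify_element,
                                   collapse_redundant, flag_symbiosis,
                                   profile_qs_locus, scan_motif)
from icemob.model import (ConjugationCluster, HomologyHit, IntegraseCall,
                          RelaxaseCall, Replicon)


def _ctx(element_id="e", plasmid=False, att="resolved", roles=(),
         relaxase=None, integrase=False, cluster_types=()):
    hits = [HomologyHit(f"l{i}", f"X{i}", r, 90, 0.9, 0.9, 100 + i)
            for i, r in enumerate(roles)]
    clusters = [ConjugationCluster(f"c{i}", t, [f"l{i}"], 1.0, "chr", 0, 10)
                for i, t in enumerate(cluster_types)]
    return ElementContext(
        element_id=element_id, is_plasmid_replicon=plasmid,
        att_status=None if plasmid else att, hits=hits,
        relaxases=[RelaxaseCall("lr", relaxase, None, 50, "panel_search")]
        if relaxase else [],
        integrases=[IntegraseCall("li", "tyrosine", "intS", 80)]
        if integrase else [],
        clusters=clusters)


def test_ice_requires_att_integrase_relaxase_t4ss():
    ctx = _ctx(relaxase="MOB_P", integrase=True, cluster_types=("trb_T4SS",))
    assert classify_element(ctx).mge_class == "ICE"
    assert classify_element(ctx).t4ss_type == "trb"


def test_ime_lacks_t4ss():
    ctx = _ctx(relaxase="MOB_F", integrase=True, cluster_types=("traACD",))
    assert classify_element(ctx).mge_class == "IME"
    # a lone MOB gene with integrase and att is still an IME
    ctx2 = _ctx(relaxase="MOB_F", integrase=True)
    assert classify_element(ctx2).mge_class == "IME"


def test_plasmid_classes():
    conj = _ctx(plasmid=True, relaxase="MOB_P", cluster_types=("trb_T4SS",))
    assert classify_element(conj).mge_class == "conjugative_plasmid"
    mob = _ctx(plasmid=True, relaxase="MOB_Q", roles=("t4cp:virD4",),
               cluster_types=("T4CP_only",))
    assert classify_element(mob).mge_class == "mobilizable_plasmid"
    bare = _ctx(plasmid=True)
    assert classify_element(bare).mge_class == "unclassified"


def test_repabc_no_att_flags_artifact():
    ctx = _ctx(att="att_not_found", roles=("rep:repA", "rep:repB", "rep:repC"),
               relaxase="MOB_P", integrase=True, cluster_types=("trb_T4SS",))
    cls = classify_element(ctx)
    assert cls.flagged_assembly_artifact
    assert cls.mge_class == "unclassified"
    # att evidence wins over repABC
    ctx2 = _ctx(att="resolved", roles=("rep:repA",), relaxase="MOB_P",
                integrase=True, cluster_types=("trb_T4SS",))
    assert classify_element(ctx2).mge_class == "ICE"
    # att-less but no repABC: kept as element
    ctx3 = _ctx(att="att_not_found", relaxase="MOB_P", integrase=True,
                cluster_types=("trb_T4SS",))
    assert classify_element(ctx3).mge_class == "ICE"


def test_marker_genes_recorded():
    ctx = _ctx(relaxase="MOB_P", integrase=True, cluster_types=("trb_T4SS",),
               roles=("exclusion:trbK", "marker:Rep_3"))
    cls = classify_element(ctx)
    assert cls.trbK_present and cls.rep3_duf2840_present


def test_symbiosis_rule():
    full = ("sym:nodA", "sym:nodB", "sym:nodC", "sym:nodI", "sym:nodJ",
            "sym:nifH", "sym:fixN")
    assert flag_symbiosis(_ctx(roles=full))
    assert not flag_symbiosis(_ctx(roles=("sym:nodC",)))
    assert not flag_symbiosis(_ctx(roles=full[:-1]))  # no fix genes


def test_classification_total_on_benchmark(benchmark):
    """Every element and plasmid replicon gets exactly one class, and the
    confusion matrix against truth is diagonal."""
    res = benchmark["result"]
    assert set(res.classifications) == \
        {el.element_id for el in res.all_elements()}
    report = benchmark["report"]
    for key, n in report["confusion"].items():
        a, b = key.split("->")
        assert a == b, f"off-diagonal confusion {key}: {n}"


def test_benchmark_qs_profile_matches_truth(benchmark):
    """ICE1: traR1 remnant, traI2 frameshift pseudogene, the rest intact."""
    res = benchmark["result"]
    truth = benchmark["truth"]
    eid = next(e for e in res.qs_profiles
               if e.startswith("SYN01") and res.classifications[e].is_ICESym)
    prof = res.qs_profiles[eid]
    status = {(c.role, c.status) for c in prof.copies}
    want = set()
    for entry in truth["elements"]["ICE1"]["qs"]:
        st = entry["status"]
        if st in ("frameshift", "premature_stop", "truncation"):
            st = "pseudogene"
        elif st != "remnant":
            st = "intact"
        want.add((entry["role"], st))
    assert status == want
    (fs,) = [c for c in prof.copies if c.status == "pseudogene"]
    assert fs.role == "traI2" and fs.basis == "frameshift"
    (rm,) = [c for c in prof.copies if c.status == "remnant"]
    assert rm.role == "traR1"
    assert any(p.basis == "frameshift" for p in res.pseudogenes)


def test_planted_frameshift_flips_intact_copy(benchmark, panel):
    """Deleting one base inside an intact QS copy turns it into a
    frameshift pseudogene on re-profiling."""
    res = benchmark["result"]
    truth = benchmark["truth"]
    genomes = {g.genome_id: g for g in benchmark["genomes"]}
    eid = next(e for e in res.qs_profiles
               if e.startswith("SYN04") and res.classifications[e].is_ICESym)
    el = [x for x in res.elements if x.element_id == eid][0]
    prof = res.qs_profiles[eid]
    target = next(c for c in prof.copies
                  if c.role == "traI1" and c.status == "intact")
    g = genomes["SYN04"]
    rep = g.replicons[0]
    frag = el.fragments[0]
    cut = frag.start + (target.start + target.end) // 2
    mutated = rep.sequence[:cut] + rep.sequence[cut + 1:]
    import copy
    g2 = copy.deepcopy(g)
    g2.replicons[0].sequence = mutated
    hits = [h for h in res.hits["SYN04"]]
    prof2, _ = profile_qs_locus(el, hits, g2, panel)
    got = next(c for c in prof2.copies if c.role == "traI1")
    assert got.status == "pseudogene" and got.basis == "frameshift"


def test_collapse_redundant_groups():
    """Identical accessory content modulo IS -> one group; an extra non-IS
    cluster -> separate groups; representative is the longest member."""
    mat = pd.DataFrame(
        {"A": [1, 1, 1, 0, 0], "B": [1, 1, 1, 1, 0], "C": [1, 1, 1, 0, 1]},
        index=["c1", "c2", "c3", "is1", "c4"])
    lengths = {"A": 50_000, "B": 60_000, "C": 55_000}
    groups = collapse_redundant(lengths, mat, is_clusters=["is1"])
    sig = {tuple(g.member_element_ids): g.representative_element_id
           for g in groups}
    assert sig == {("A", "B"): "B", ("C",): "C"}
    # without IS exemption, A and B separate
    groups2 = collapse_redundant(lengths, mat, is_clusters=[])
    assert all(len(g.member_element_ids) == 1 for g in groups2)


def test_redundancy_on_simulated_elements():
    """Simulated twin ICEs differing only by IS copies collapse together."""
    from icemob.pangenome import cluster_orthologs, presence_absence
    from icemob.simulate import redundancy_config, simulate_mobilome
    genomes, truth = simulate_mobilome(redundancy_config(seed=13))
    units, unit_of, lengths = {}, {}, {}
    is_loci = set()
    for gid, g in zip(truth["elements"], genomes):
        e = truth["elements"][gid]
        s, t = e["fragments"][0]
        feats = {f.locus_id: f for f in g.features
                 if f.kind == "CDS" and s <= f.start and f.end <= t}
        units[gid] = {l: f.protein for l, f in feats.items()}
        for l in feats:
            unit_of[l] = gid
        lengths[gid] = t - s
        for r in e["gene_records"]:
            if r["role"] == "is:tnpA" and r["locus"]:
                is_loci.add(r["locus"])
    cs = cluster_orthologs(units, 40.0)
    mat = presence_absence(cs, unit_of, counts=True)
    is_clusters = [cid for cid, loci in cs.clusters.items()
                   if any(l in is_loci for l in loci)]
    groups = collapse_redundant(lengths, mat, is_clusters)
    members = sorted(tuple(g.member_element_ids) for g in groups)
    assert members == [("RED_A", "RED_B"), ("RED_C",)]


def test_motif_build_scan():
    training = ["ATATCCCGGGAT", "ATATCCCGGGTT", "ATAACCCGGGAT"]
    model = build_motif("nodbox", training)
    # each training sequence scores at least the threshold on itself
    rep = Replicon("r", "G" * 40 + training[0] + "C" * 40)
    hits = scan_motif(model, rep)
    fwd = [h for h in hits if h.strand == "+"]
    assert any(h.start == 40 and h.end == 52 for h in fwd)
    # reverse-strand instance found with mirrored coordinates
    from icemob._seq import revcomp
    rep2 = Replicon("r", "G" * 30 + revcomp(training[0]) + "C" * 30)
    hits2 = scan_motif(model, rep2)
    assert any(h.strand == "-" and h.start == 30 and h.end == 42 for h in hits2)
    with pytest.raises(ValueError):
        build_motif("bad", ["ACGT", "ACG"])
    with pytest.raises(ValueError):
        build_motif("bad", ["ACGT"])
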