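"""End-to-end orchestration: io -> homology -> delineate -> classify ->
pangenome -> recombination, plus truth-based evaluation.

Every stage is a plain function over in-memory objects; ``run_pipeline``
chains them and writes deterministic TSV/FASTA/GFF3/JSON outputs with a
MANIFEST of checksums.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import att as attmod
from . import element_typing as et
from . import genome_io as gio
from . import homology as hom
from . import pangenome as pg
from . import recombination as rec
from .model import DelineatedElement, ElementFragment, GenomeRecord
from .panel import ReferencePanel, default_panel

SEED_CATEGORIES = ("relaxase", "backbone_relaxase", "t4ss_trb", "t4ss_vir",
                   "t4cp", "relaxosome", "integrase_tyrosine", "integrase_serine")


@dataclass
class PipelineConfig:
    out_dir: str = "icemob_results"
    panel_path: Optional[str] = None
    seed: int = 0
    min_identity: float = 30.0
    min_coverage: float = 0.6
    locus_window: int = 10_000
    min_core: int = 15
    max_span: int = 900_000
    candidate_margin: int = 2_000
    cluster_identity: float = 40.0
    cluster_identity_permissive: float = 25.0
    backbone_prevalence: float = 0.95
    recomb_window: int = 1000
    recomb_alpha: float = 0.05
    ani_fragment: int = 1020
    ani_cutoff: float = 95.0
    run_ani: bool = True
    run_core_sweep: bool = False
    verbosity: int = 1

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PipelineResult:
    genomes: list[GenomeRecord]
    panel: ReferencePanel
    hits: dict = field(default_factory=dict)  # genome_id -> [HomologyHit]
    relaxases: dict = field(default_factory=dict)
    integrases: dict = field(default_factory=dict)
    conj_clusters: dict = field(default_factory=dict)
    elements: list = field(default_factory=list)  # DelineatedElement
    replicon_elements: list = field(default_factory=list)  # plasmid pseudo-elements
    element_genome: dict = field(default_factory=dict)
    contexts: dict = field(default_factory=dict)
    classifications: dict = field(default_factory=dict)
    qs_profiles: dict = field(default_factory=dict)
    pseudogenes: list = field(default_factory=list)
    element_matrix: Optional[pd.DataFrame] = None
    element_clusters: dict = field(default_factory=dict)
    backbone: Optional[object] = None
    redundancy: list = field(default_factory=list)
    genome_matrix: Optional[pd.DataFrame] = None
    mobilome: Optional[object] = None
    core_sweep: Optional[pd.DataFrame] = None
    ani: list = field(default_factory=list)
    genospecies: list = field(default_factory=list)
    accessory_tree: Optional[str] = None
    edges: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def all_elements(self):
        return self.elements + self.replicon_elements

    def say(self, verbosity, msg):
        self.log.append(msg)
        if verbosity:
            print(f"[icemob] {msg}")


# ---------------------------------------------------------------------------
# stage: io

def load_genomes(input_dir: str) -> list[GenomeRecord]:
    genomes = []
    gbs = sorted(glob.glob(os.path.join(input_dir, "*.gb*")))
    for gb in gbs:
        genomes.append(gio.read_genome(None, gb))
    for fna in sorted(glob.glob(os.path.join(input_dir, "*.fna"))):
        stem = fna[:-4]
        gff, faa = stem + ".gff3", stem + ".faa"
        if os.path.exists(gff) and os.path.exists(faa):
            genomes.append(gio.read_genome(fna, gff, faa))
    if not genomes:
        raise FileNotFoundError(f"no annotated genomes under {input_dir}")
    return genomes


# ---------------------------------------------------------------------------
# stage: homology

def stage_homology(result: PipelineResult, cfg: PipelineConfig) -> None:
    for g in result.genomes:
        hits = hom.search_panel(g, result.panel, cfg.min_identity, cfg.min_coverage)
        result.hits[g.genome_id] = hits
        result.relaxases[g.genome_id] = hom.classify_relaxases(hits)
        result.integrases[g.genome_id] = hom.detect_integrases(hits)
        result.conj_clusters[g.genome_id] = hom.detect_conjugation_clusters(
            g, hits, cfg.locus_window)
        result.say(cfg.verbosity,
                   f"{g.genome_id}: {len(hits)} panel hits, "
                   f"{len(result.relaxases[g.genome_id])} relaxases, "
                   f"{len(result.conj_clusters[g.genome_id])} conjugation loci")


# ---------------------------------------------------------------------------
# stage: delineate

def _seed_intervals(genome, hits, replicon_id):
    feats = {f.locus_id: f for f in genome.features}
    seeds = set()
    for h in hits:
        if h.role_category not in SEED_CATEGORIES:
            continue
        f = feats.get(h.query_locus)
        if f is not None and f.replicon_id == replicon_id:
            seeds.add((f.start, f.end))
    return sorted(seeds)


def stage_delineate(result: PipelineResult, cfg: PipelineConfig) -> None:
    params = attmod.AttParams(min_core=cfg.min_core, max_span=cfg.max_span)
    for g in result.genomes:
        hits = result.hits[g.genome_id]
        anchors = gio.locate_anchors(g, hits=hits)
        n_el = 0
        for rep in g.replicons:
            if rep.source_class == "plasmid":
                el = DelineatedElement(
                    element_id=rep.id,
                    fragments=[ElementFragment(rep.id, 0, len(rep), "mono",
                                               "other", "other")],
                    partite_count=1, circular_sequence=rep.sequence,
                    attP_cores=[], integration_site_label="plasmid",
                    att_status="plasmid")
                result.replicon_elements.append(el)
                result.element_genome[rep.id] = g.genome_id
                continue
            seeds = _seed_intervals(g, hits, rep.id)
            if not seeds:
                continue
            pairs = attmod.find_att_pairs(rep, anchors, seeds, params)
            covered = []
            for grp in attmod.group_interleaved(pairs):
                try:
                    if len(grp) == 1:
                        el = attmod.delineate_monopartite(
                            grp[0], g,
                            f"{g.genome_id}.{grp[0].anchor.label}.{n_el}")
                    else:
                        el = attmod.resolve_multipartite(
                            grp, g, seeds,
                            f"{g.genome_id}.multi.{n_el}")
                except (attmod.UnresolvableMultipartite, ValueError) as exc:
                    result.say(cfg.verbosity, f"{g.genome_id}: {exc}")
                    continue
                n_el += 1
                result.elements.append(el)
                result.element_genome[el.element_id] = g.genome_id
                covered.extend((f.start, f.end) for f in el.fragments)
            # mobility-gene clusters not enclosed by any att pair
            for cl in result.conj_clusters[g.genome_id]:
                if cl.replicon_id != rep.id:
                    continue
                if any(s <= cl.start and cl.end <= e for s, e in covered):
                    continue
                start = max(0, cl.start - cfg.candidate_margin)
                end = min(len(rep), cl.end + cfg.candidate_margin)
                el = DelineatedElement(
                    element_id=f"{g.genome_id}.candidate.{n_el}",
                    fragments=[ElementFragment(rep.id, start, end, "mono",
                                               "other", "other")],
                    partite_count=1, circular_sequence=None, attP_cores=[],
                    integration_site_label="unknown",
                    att_status="att_not_found")
                n_el += 1
                result.elements.append(el)
                result.element_genome[el.element_id] = g.genome_id
        result.say(cfg.verbosity, f"{g.genome_id}: {n_el} integrated "
                                  f"element candidates")


# ---------------------------------------------------------------------------
# stage: classify

def _element_loci(element: DelineatedElement, genome: GenomeRecord) -> set[str]:
    loci = set()
    for fr in element.fragments:
        for f in genome.features:
            if (f.replicon_id == fr.replicon_id and f.start >= fr.start
                    and f.end <= fr.end):
                loci.add(f.locus_id)
    return loci


def stage_classify(result: PipelineResult, cfg: PipelineConfig) -> None:
    by_gid = {g.genome_id: g for g in result.genomes}
    for el in result.all_elements():
        gid = result.element_genome[el.element_id]
        g = by_gid[gid]
        loci = _element_loci(el, g)
        hits = [h for h in result.hits[gid] if h.query_locus in loci]
        ctx = et.ElementContext(
            element_id=el.element_id,
            is_plasmid_replicon=(el.att_status == "plasmid"),
            att_status=None if el.att_status == "plasmid" else el.att_status,
            hits=hits,
            relaxases=[r for r in result.relaxases[gid] if r.query_locus in loci],
            integrases=[c for c in result.integrases[gid] if c.query_locus in loci],
            clusters=[c for c in result.conj_clusters[gid]
                      if any(m in loci for m in c.member_loci)])
        result.contexts[el.element_id] = ctx
        cls = et.classify_element(ctx)
        if cls.mge_class in ("ICE", "IME") or ctx.is_plasmid_replicon:
            cls.is_ICESym = (cls.mge_class == "ICE") and et.flag_symbiosis(ctx)
        result.classifications[el.element_id] = cls
        if cls.mge_class in ("ICE", "IME") and el.att_status == "resolved":
            profile, pseudo = et.profile_qs_locus(el, hits, g, result.panel)
            result.qs_profiles[el.element_id] = profile
            result.pseudogenes.extend(pseudo)
    counts = {}
    for cls in result.classifications.values():
        counts[cls.mge_class] = counts.get(cls.mge_class, 0) + 1
    result.say(cfg.verbosity, f"classification tally: {counts}")


# ---------------------------------------------------------------------------
# stage: pangenome

def _mge_elements(result):
    return [el for el in result.all_elements()
            if result.classifications[el.element_id].mge_class
            in ("ICE", "IME", "conjugative_plasmid", "mobilizable_plasmid")]


def stage_pangenome(result: PipelineResult, cfg: PipelineConfig) -> None:
    by_gid = {g.genome_id: g for g in result.genomes}
    # genome-level clustering and mobilome accounting
    units = {}
    for g in result.genomes:
        units[g.genome_id] = {f.locus_id: f.protein for f in g.cds() if f.protein}
    gtable = pg.pairwise_identity_table(
        {l: s for d in units.values() for l, s in d.items()})
    gclusters = pg.cluster_orthologs(units, cfg.cluster_identity_permissive,
                                     table=gtable)
    unit_of = {l: gid for gid, d in units.items() for l in d}
    result.genome_matrix = pg.presence_absence(gclusters, unit_of)
    if cfg.run_core_sweep:
        result.core_sweep = pg.sweep_core_size(units, table=gtable)
    location = _locus_locations(result, by_gid)
    result.mobilome = pg.account_mobilome(gclusters, location)

    # element-level clustering
    mels = _mge_elements(result)
    eunits = {}
    for el in mels:
        g = by_gid[result.element_genome[el.element_id]]
        loci = _element_loci(el, g)
        feats = {f.locus_id: f for f in g.features}
        eunits[el.element_id] = {l: feats[l].protein for l in loci
                                 if feats[l].kind == "CDS" and feats[l].protein}
    if len(eunits) >= 2:
        eclusters = pg.cluster_orthologs(eunits, cfg.cluster_identity)
        result.element_clusters = eclusters.clusters
        e_unit_of = {l: eid for eid, d in eunits.items() for l in d}
        counts_matrix = pg.presence_absence(eclusters, e_unit_of, counts=True)
        result.element_matrix = counts_matrix
        # IS clusters: any member best-hitting the IS transposase role
        is_loci = {h.query_locus for hlist in result.hits.values() for h in hlist
                   if h.role_label == "is:tnpA"}
        is_clusters = [cid for cid, loci in eclusters.clusters.items()
                       if any(l in is_loci for l in loci)]
        lengths = {el.element_id: el.length for el in mels}
        result.redundancy = et.collapse_redundant(lengths, counts_matrix,
                                                  is_clusters)
        reps = [g.representative_element_id for g in result.redundancy]
        trb_units = [el.element_id for el in mels
                     if result.classifications[el.element_id].t4ss_type == "trb"
                     and el.element_id in reps]
        if len(trb_units) >= 2:
            result.backbone = pg.identify_backbone(
                counts_matrix[trb_units], cfg.backbone_prevalence)
        nr_matrix = counts_matrix[[r for r in reps]]
        if result.backbone is not None:
            accessory = nr_matrix.drop(index=result.backbone.cluster_ids)
        else:
            accessory = nr_matrix
        if accessory.shape[1] >= 3:
            result.accessory_tree = pg.gene_content_tree(accessory)
    # ANI / genospecies over chromosomes
    if cfg.run_ani and len(result.genomes) >= 2:
        chroms = {g.genome_id: "".join(r.sequence for r in g.replicons
                                       if r.source_class == "chromosome")
                  for g in result.genomes}
        gids = sorted(chroms)
        for i, a in enumerate(gids):
            for b in gids[i + 1:]:
                try:
                    r = pg.compute_ani(chroms[a], chroms[b], cfg.ani_fragment,
                                       ids=(a, b))
                except ValueError:
                    continue
                result.ani.append(r)
        result.genospecies = pg.partition_genospecies(result.ani, cfg.ani_cutoff)
    result.say(cfg.verbosity,
               f"pangenome: {result.mobilome.n_clusters} clusters, "
               f"MGE fraction {result.mobilome.mge_fraction:.3f}, "
               f"{len(result.genospecies)} genospecies")


def _locus_locations(result, by_gid) -> dict[str, str]:
    location = {}
    for el in result.all_elements():
        cls = result.classifications[el.element_id]
        if cls.mge_class == "ICE":
            cat = "ICESym" if cls.is_ICESym else "ICE"
        elif cls.mge_class == "IME":
            cat = "IME"
        elif cls.mge_class in ("conjugative_plasmid", "mobilizable_plasmid"):
            cat = "plasmid"
        else:
            continue
        g = by_gid[result.element_genome[el.element_id]]
        for locus in _element_loci(el, g):
            location[locus] = cat
    return location


# ---------------------------------------------------------------------------
# stage: recombination network

def element_circle_coordinates(element: DelineatedElement) -> dict:
    """Mapping fragment index -> (offset in circle, fragment start)."""
    offsets = {}
    off = 0
    for i, fr in enumerate(element.fragments):
        offsets[i] = (off, fr.start)
        core_len = element.att_pairs[0].core.length if element.att_pairs else 0
        if element.partite_count > 1:
            fam = fr.right_core_family
            core_len = element.att_pairs[int(fam)].core.length
        off += fr.length - core_len
    return offsets


def backbone_mask(result: PipelineResult) -> dict[str, list[tuple[int, int]]]:
    """Circle-coordinate intervals of backbone-cluster genes per element."""
    if result.backbone is None or result.element_matrix is None:
        return {}
    backbone_ids = set(result.backbone.cluster_ids)
    cluster_of = {}
    for cid, loci in result.element_clusters.items():
        for l in loci:
            cluster_of[l] = cid
    by_gid = {g.genome_id: g for g in result.genomes}
    mask: dict[str, list[tuple[int, int]]] = {}
    for el in result.all_elements():
        if el.circular_sequence is None:
            continue
        g = by_gid[result.element_genome[el.element_id]]
        offs = element_circle_coordinates(el)
        intervals = []
        for i, fr in enumerate(el.fragments):
            off, fstart = offs[i]
            for f in g.features:
                if (f.replicon_id == fr.replicon_id and f.start >= fr.start
                        and f.end <= fr.end
                        and cluster_of.get(f.locus_id) in backbone_ids):
                    intervals.append((off + f.start - fstart,
                                      off + f.end - fstart))
        if intervals:
            mask[el.element_id] = sorted(intervals)
    return mask


def stage_recombine(result: PipelineResult, cfg: PipelineConfig,
                    mask=None, mask_mode: str = "exclude") -> None:
    reps = {g.representative_element_id for g in result.redundancy} \
        if result.redundancy else None
    seqs = {}
    for el in _mge_elements(result):
        if el.circular_sequence is None:
            continue
        if reps is not None and el.element_id not in reps:
            continue
        seqs[el.element_id] = el.circular_sequence
    if len(seqs) >= 2:
        result.edges = rec.build_network(seqs, cfg.recomb_window,
                                         cfg.recomb_alpha, mask=mask,
                                         mask_mode=mask_mode)
    result.say(cfg.verbosity, f"recombination network: {len(result.edges)} edges "
                              f"over {len(seqs)} elements")


# ---------------------------------------------------------------------------
# driver + outputs

_STAGES = [("homology", stage_homology), ("delineate", stage_delineate),
           ("classify", stage_classify), ("pangenome", stage_pangenome),
           ("recombine", stage_recombine)]


def run_pipeline(genomes_or_dir, cfg: Optional[PipelineConfig] = None
                 ) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    if isinstance(genomes_or_dir, (str, os.PathLike)):
        genomes = load_genomes(str(genomes_or_dir))
    else:
        genomes = list(genomes_or_dir)
    panel = (ReferencePanel.read_fasta(cfg.panel_path)
             if cfg.panel_path else default_panel())
    result = PipelineResult(genomes=genomes, panel=panel)
    os.makedirs(cfg.out_dir, exist_ok=True)
    completed = []
    try:
        for name, fn in _STAGES:
            fn(result, cfg)
            completed.append(name)
    finally:
        write_outputs(result, cfg, completed)
    return result


def write_outputs(result: PipelineResult, cfg: PipelineConfig,
                  completed) -> None:
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    paths = []
    if result.classifications:
        els = [el for el in result.all_elements()]
        gio.write_element_outputs(els, out,
                                  list(result.classifications.values()))
        paths += ["elements.gff3", "element_circles.fna", "elements.tsv"]
    if result.element_matrix is not None:
        result.element_matrix.to_csv(os.path.join(out, "element_matrix.tsv"),
                                     sep="\t")
        paths.append("element_matrix.tsv")
        dist = pg.gene_content_distance(result.element_matrix)
        dist.to_csv(os.path.join(out, "element_distances.tsv"), sep="\t")
        pg.write_nexus_distances(dist, os.path.join(out, "element_distances.nex"))
        paths += ["element_distances.tsv", "element_distances.nex"]
    if result.backbone is not None:
        with open(os.path.join(out, "backbone_clusters.txt"), "w") as fh:
            for c in result.backbone.cluster_ids:
                mark = "*" if c in result.backbone.single_copy_subset else ""
                fh.write(f"{c}{mark}\n")
        paths.append("backbone_clusters.txt")
    if result.accessory_tree:
        with open(os.path.join(out, "accessory_nj.nwk"), "w") as fh:
            fh.write(result.accessory_tree + "\n")
        paths.append("accessory_nj.nwk")
    if result.ani:
        with open(os.path.join(out, "ani.tsv"), "w") as fh:
            fh.write("genome_a\tgenome_b\tani\tn_fragments\n")
            for r in result.ani:
                fh.write(f"{r.genome_a}\t{r.genome_b}\t{r.ani:.3f}\t"
                         f"{r.n_fragments}\n")
        paths.append("ani.tsv")
    if result.edges:
        with open(os.path.join(out, "recombination_edges.tsv"), "w") as fh:
            fh.write("query\tsubject\tadditive_length\tquery_fraction\n")
            for e in sorted(result.edges, key=lambda e: (e.query_id, e.subject_id)):
                fh.write(f"{e.query_id}\t{e.subject_id}\t{e.additive_length}\t"
                         f"{e.query_fraction:.4f}\n")
        rec.network_to_sif(result.edges, os.path.join(out, "recombination.sif"))
        paths += ["recombination_edges.tsv", "recombination.sif"]
    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write("\n".join(result.log) + "\n")
    paths.append("run.log")
    with open(os.path.join(out, "MANIFEST"), "w") as fh:
        fh.write(f"# completed stages: {','.join(completed)}\n")
        for p in sorted(paths):
            full = os.path.join(out, p)
            if os.path.exists(full):
                digest = hashlib.sha256(open(full, "rb").read()).hexdigest()
                fh.write(f"{digest}  {p}\n")


# ---------------------------------------------------------------------------
# evaluation against simulator truth

def evaluate(result: PipelineResult, truth: dict) -> dict:
    """Per-class precision/recall, boundary exactness, att recovery,
    confusion matrix and recombination recall against a truth dictionary."""
    truth_els = {eid: t for eid, t in truth["elements"].items()
                 if not t.get("is_artifact") and t["partite"] != 0}
    truth_plasmids = {eid: t for eid, t in truth["elements"].items()
                      if t["class"].endswith("_plasmid")}
    pred = [(el, result.classifications[el.element_id])
            for el in result.all_elements()]

    matches = {}  # truth id -> predicted element
    boundary_exact = 0
    for eid, t in truth_els.items():
        t_frags = sorted((t["replicon"], f[0], f[1]) for f in t["fragments"])
        for el, cls in pred:
            if el.att_status == "plasmid":
                continue
            if result.element_genome.get(el.element_id) != t["genome"]:
                continue
            p_frags = sorted((f.replicon_id, f.start, f.end)
                             for f in el.fragments)
            if _frags_overlap(t_frags, p_frags):
                matches[eid] = (el, cls)
                if p_frags == t_frags:
                    boundary_exact += 1
                break
    confusion: dict[tuple, int] = {}
    class_of_truth = {"ICE": "ICE", "IME": "IME"}
    for eid, t in truth_els.items():
        true_class = class_of_truth.get(t["class"], t["class"])
        got = matches.get(eid)
        pred_class = got[1].mge_class if got else "missed"
        confusion[(true_class, pred_class)] = confusion.get(
            (true_class, pred_class), 0) + 1
    for eid, t in truth_plasmids.items():
        got = result.classifications.get(eid)
        pred_class = got.mge_class if got else "missed"
        confusion[(t["class"], pred_class)] = confusion.get(
            (t["class"], pred_class), 0) + 1
    matched_pred_ids = {m[0].element_id for m in matches.values()} | \
        set(truth_plasmids)
    n_pred_mge = sum(1 for el, cls in pred
                     if cls.mge_class in ("ICE", "IME", "conjugative_plasmid",
                                          "mobilizable_plasmid"))
    correct = sum(1 for (a, b), n in confusion.items() if a == b for _ in range(n))
    n_truth = len(truth_els) + len(truth_plasmids)
    recall = correct / n_truth if n_truth else 1.0
    precision = correct / n_pred_mge if n_pred_mge else 1.0
    att_pairs_truth = sum(len(t.get("att_pairs", [])) for t in truth_els.values())
    att_recovered = 0
    for eid, t in truth_els.items():
        got = matches.get(eid)
        if not got:
            continue
        pred_pairs = {((p.attL[0], p.attL[1]), (p.attR[0], p.attR[1]))
                      for p in got[0].att_pairs}
        for tp_pair in t.get("att_pairs", []):
            key = (tuple(tp_pair["attL"]), tuple(tp_pair["attR"]))
            if key in pred_pairs:
                att_recovered += 1
    # recombination recall: an edge between the right pair overlapping truth
    ev_found = 0
    truth_events = truth.get("recombination_events", [])
    name_map = {eid: m[0].element_id for eid, m in matches.items()}
    for ev in truth_events:
        dst_pred = name_map.get(ev["dst"])
        src_pred = name_map.get(ev["src"], ev["src"])
        hit = False
        for e in result.edges:
            if {e.query_id, e.subject_id} == {dst_pred, src_pred} and \
                    e.query_id == dst_pred:
                for s in e.segments:
                    if s.start < ev["dst_rel"][1] and ev["dst_rel"][0] < s.end:
                        hit = True
        ev_found += bool(hit)
    artifacts_flagged = sum(
        1 for el, cls in pred if cls.flagged_assembly_artifact)
    n_truth_artifacts = sum(1 for t in truth["elements"].values()
                            if t.get("is_artifact"))
    return {
        "n_truth_elements": n_truth,
        "n_predicted_mge": n_pred_mge,
        "precision": precision,
        "recall": recall,
        "boundary_exact": boundary_exact,
        "boundary_exact_fraction": boundary_exact / len(truth_els)
        if truth_els else 1.0,
        "att_pairs_truth": att_pairs_truth,
        "att_pairs_recovered": att_recovered,
        "att_recovery_rate": att_recovered / att_pairs_truth
        if att_pairs_truth else 1.0,
        "confusion": {f"{a}->{b}": n for (a, b), n in sorted(confusion.items())},
        "recombination_events": len(truth_events),
        "recombination_recall": ev_found / len(truth_events)
        if truth_events else 1.0,
        "artifacts_flagged": artifacts_flagged,
        "artifacts_truth": n_truth_artifacts,
    }


def _frags_overlap(t_frags, p_frags) -> bool:
    for (trep, ts, te) in t_frags:
        for (prep, ps, pe) in p_frags:
            if trep != prep:
                continue
            inter = min(te, pe) - max(ts, ps)
            if inter > 0.5 * (te - ts):
                return True
    return False


def write_evaluation(report: dict, out_dir: str) -> str:
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "evaluation.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return path
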