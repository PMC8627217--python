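"""Synthetic genomes with planted mobile elements and exact ground truth.

The generator emulates the structure the analysis assumes: multi-replicon
genomes with tRNA/guaA/radC/dusA integration anchors; monopartite and
tripartite ICEs integrated by literal attB -> attL/attR core duplication
(so delineation truth is exact by construction); traACD IMEs; conjugative
and mobilizable plasmids; repABC regions artificially joined to the
chromosome; cargo genes derived from the bundled exemplar panel mutated to
a target nucleotide divergence; quorum-sensing gene duplications with
pseudogenization (frameshift, premature stop, truncation, remnant); IS
copies; and inter-element segment swaps.

Everything is reproducible from ``SimulationConfig.seed``; the truth
dictionary records boundaries, cores, circles, per-gene roles and statuses,
and the recombination-event registry.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import back_translate, mutate_cds, random_dna, random_protein, translate
from .model import GeneFeature, GenomeRecord, Replicon
from .panel import BACKBONE_ROLES, ReferencePanel, default_panel

ANCHOR_CLASSES_16 = [
    "tRNA-Phe", "tRNA-Ser", "tRNA-Met", "tRNA-Arg", "tRNA-Gly", "tRNA-His",
    "tRNA-Pro", "tRNA-Asn", "tRNA-Thr", "tRNA-Trp", "tRNA-Leu", "tRNA-Lys",
    "tRNA-Val", "guaA", "radC", "dusA",
]

_SYM_ROLES = ["sym:nodA", "sym:nodB", "sym:nodC", "sym:nodI", "sym:nodJ",
              "sym:nodD2", "sym:nifH", "sym:nifD", "sym:nifK", "sym:fixN",
              "sym:fixO", "sym:fixQ", "sym:fixP", "sym:fixV", "sym:dctA",
              "sym:queC", "sym:queD", "sym:queE"]

_ROLE_TO_EXEMPLAR = None  # lazy: role_label -> PanelEntry of the default panel


def _panel_role_map() -> dict:
    global _ROLE_TO_EXEMPLAR
    if _ROLE_TO_EXEMPLAR is None:
        panel = default_panel()
        _ROLE_TO_EXEMPLAR = {}
        for e in panel.entries:
            _ROLE_TO_EXEMPLAR.setdefault(e.role_label, e)
        # the ICE relaxase and IME relaxase use the alias exemplars
        _ROLE_TO_EXEMPLAR["backbone_relaxase:rlxS"] = panel.get("REF_RLXS")
    return _ROLE_TO_EXEMPLAR


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ElementSpec:
    element_id: str
    genome: int
    kind: str  # ICE | IME | artifact
    anchors: list  # [(label, background position)]; [] for artifact
    partite: int = 1
    core_length: int = 17
    divergence: float = 0.10  # nucleotide substitution fraction vs exemplars
    integrases: list = field(default_factory=lambda: ["integrase_tyrosine:intY"])
    backbone: bool = True  # 17-gene conserved ICE backbone
    traACD: bool = False
    relaxase_role: Optional[str] = "backbone_relaxase:rlxS"
    symbiosis: bool = False
    qs: Optional[list] = None  # [(role name, status)]
    trbK_set: bool = False  # trbK + Rep_3 + DUF2840 (non-ICESym markers)
    repABC: bool = False
    n_pads: int = 0
    pad_length: int = 6500
    is_copies: int = 0
    n_filler: int = 3
    fragment_lengths: Optional[list] = None  # target lengths incl. both cores
    drop_roles: list = field(default_factory=list)
    corrupt_pair: Optional[int] = None  # break one att pair (negative control)
    artifact_position: Optional[int] = None


@dataclass
class PlasmidSpec:
    plasmid_id: str
    genome: int
    kind: str  # conjugative | mobilizable
    length: int = 40_000
    divergence: float = 0.10


@dataclass
class RecombinationEvent:
    src_element: str
    src_pad: int
    dst_element: str
    dst_pad: int
    length: int


@dataclass
class SimulationConfig:
    seed: int
    n_genomes: int
    chromosome_length: int = 2_000_000
    gc: float = 0.62
    n_core_families: int = 30
    n_accessory_per_genome: int = 10
    core_divergence: float = 0.05
    elements: list = field(default_factory=list)
    plasmids: list = field(default_factory=list)
    extra_anchors: list = field(default_factory=list)  # (genome, label, pos, strand)
    recombination_events: list = field(default_factory=list)

    def validate(self) -> None:
        for e in self.elements:
            if not (0 <= e.divergence <= 0.60):
                raise ValueError(f"{e.element_id}: divergence outside [0, 0.6]")
            if e.fragment_lengths is not None:
                for L in e.fragment_lengths:
                    if L <= 2 * e.core_length:
                        raise ValueError(f"{e.element_id}: fragment length {L} "
                                         f"<= 2x core length")
        for g in range(self.n_genomes):
            positions = []
            for e in self.elements:
                if e.genome == g:
                    positions += [p for _, p in e.anchors]
                    if e.artifact_position is not None:
                        positions.append(e.artifact_position)
            positions += [p for gg, _, p, _ in self.extra_anchors if gg == g]
            if len(positions) != len(set(positions)):
                raise ValueError(f"genome {g}: overlapping planted parts")


# ---------------------------------------------------------------------------
# low-level builders

class _GeneWriter:
    """Accumulates sequence + relative features for one assembly part."""

    def __init__(self, rng, genome_tag, counter):
        self.rng = rng
        self.tag = genome_tag
        self.counter = counter
        self.chunks: list[str] = []
        self.length = 0
        self.features: list[dict] = []
        self.records: list[dict] = []

    def _next_locus(self) -> str:
        self.counter[0] += 1
        return f"{self.tag}_{self.counter[0]:05d}"

    def spacer(self, lo=50, hi=110) -> None:
        n = int(self.rng.integers(lo, hi))
        self.append(random_dna(self.rng, n, 0.55))

    def append(self, seq: str) -> None:
        self.chunks.append(seq)
        self.length += len(seq)

    def trna(self, isotype: str, strand: str = "+", length: int = 76) -> dict:
        seq = random_dna(self.rng, length, 0.58)
        feat = {"start": self.length, "end": self.length + length, "strand": strand,
                "kind": "tRNA", "product": f"tRNA-{isotype}", "isotype": isotype,
                "locus": self._next_locus(), "protein": None}
        self.append(seq)
        self.features.append(feat)
        return feat

    def gene(self, role: Optional[str], divergence: float, strand: str = "+",
             status: str = "intact", aa_len: int = 300,
             product: Optional[str] = None) -> dict:
        """Plant one gene (panel-derived if ``role`` given, else random)."""
        if role is not None:
            ex = _panel_role_map()[role]
            nt, realized = mutate_cds(ex.nucleotide, divergence, self.rng)
            exemplar_id = ex.exemplar_id
        else:
            prot = random_protein(self.rng, aa_len)
            nt = back_translate(self.rng, prot)
            realized, exemplar_id = 0.0, None
        basis = None
        has_feature = True
        if status == "frameshift":
            cut = (len(nt) // 2) // 3 * 3 + 1
            nt = nt[:cut] + nt[cut + 1:]
            basis = "frameshift"
        elif status == "premature_stop":
            cod = (len(nt) // 3) * 2 // 5 * 3
            nt = nt[:cod] + "TAA" + nt[cod + 3:]
            basis = "premature_stop"
        elif status == "truncation":
            keep = (int(len(nt) * 0.6) // 3) * 3
            nt = nt[:keep]
            basis = "truncation"
        elif status == "remnant":
            nt = nt[-100:]
            has_feature = False
            basis = "remnant"
        prot = translate(nt)
        if "*" in prot:
            prot = prot[:prot.index("*")]
        genomic = nt if strand == "+" else _rc(nt)
        rec = {"role": role, "exemplar": exemplar_id, "status": status,
               "basis": basis, "rel_start": self.length,
               "rel_end": self.length + len(genomic),
               "realized_divergence": realized, "strand": strand}
        if has_feature:
            name = (role.split(":", 1)[1] if role else "hypothetical protein")
            feat = {"start": self.length, "end": self.length + len(genomic),
                    "strand": strand, "kind": "CDS",
                    "product": product or name, "isotype": None,
                    "locus": self._next_locus(), "protein": prot}
            self.features.append(feat)
            rec["locus"] = feat["locus"]
        else:
            rec["locus"] = None
        self.append(genomic)
        self.records.append(rec)
        return rec

    def sequence(self) -> str:
        return "".join(self.chunks)


def _rc(seq: str) -> str:
    from ._seq import revcomp
    return revcomp(seq)


def _element_gene_plan(spec: ElementSpec) -> dict:
    """Distribute gene blocks over fragments (1 or 3)."""
    backbone = [r for r in BACKBONE_ROLES if r not in spec.drop_roles]
    duf736_extra = ["marker:DUF736"] if spec.backbone else []
    plan = {i: [] for i in range(spec.partite)}
    if spec.partite == 1:
        frag = plan[0]
        for ig in spec.integrases:
            frag.append(("gene", ig, "intact"))
        if spec.traACD:
            frag.append(("traACD", None, None))
        if spec.backbone:
            frag.extend(("gene", r, "intact") for r in backbone + duf736_extra)
        elif spec.relaxase_role and not spec.traACD:
            frag.append(("gene", spec.relaxase_role, "intact"))
        if spec.trbK_set:
            for r in ("exclusion:trbK", "marker:Rep_3", "marker:DUF2840"):
                frag.append(("gene", r, "intact"))
        if spec.repABC:
            for r in ("rep:repA", "rep:repB", "rep:repC"):
                frag.append(("gene", r, "intact"))
        if spec.qs:
            frag.append(("qs", None, None))
        if spec.symbiosis:
            frag.extend(("gene", r, "intact") for r in _SYM_ROLES)
        for _ in range(spec.n_pads):
            frag.append(("pad", None, None))
        for _ in range(spec.is_copies):
            frag.append(("gene", "is:tnpA", "intact"))
        for _ in range(spec.n_filler):
            frag.append(("filler", None, None))
    else:
        # alpha: backbone + symbiosis + pads; beta: intS/intM + QS; gamma: intG
        alpha, beta, gamma = plan[0], plan[1], plan[2]
        if spec.backbone:
            alpha.extend(("gene", r, "intact") for r in backbone + duf736_extra)
        if spec.symbiosis:
            alpha.extend(("gene", r, "intact") for r in _SYM_ROLES)
        for _ in range(spec.n_pads):
            alpha.append(("pad", None, None))
        for _ in range(spec.n_filler):
            alpha.append(("filler", None, None))
        beta.append(("gene", "integrase_tyrosine:intS", "intact"))
        beta.append(("gene", "integrase_tyrosine:intM", "intact"))
        if spec.qs:
            beta.append(("qs", None, None))
        gamma.append(("gene", "integrase_tyrosine:intG", "intact"))
        gamma.append(("filler", None, None))
    return plan


def _emit_block(writer: _GeneWriter, item, spec: ElementSpec, pads_out: list):
    kind, role, status = item
    d = spec.divergence
    if kind == "gene":
        writer.spacer()
        writer.gene(role, d)
    elif kind == "filler":
        writer.spacer()
        writer.gene(None, d, aa_len=int(writer.rng.integers(120, 300)))
    elif kind == "pad":
        writer.spacer()
        start = writer.length
        while writer.length - start < spec.pad_length - 1100:
            writer.gene(None, d, aa_len=300)
            writer.spacer(40, 80)
        pad = random_dna(writer.rng, spec.pad_length - (writer.length - start), 0.60)
        writer.append(pad)
        pads_out.append((start, writer.length))
    elif kind == "traACD":
        writer.spacer()
        writer.gene("relaxosome:traC", d, strand="-")
        writer.append(random_dna(writer.rng, 120, 0.5))  # oriT-like intergenic
        writer.gene("relaxase:MOB_F_traA", d, strand="+", product="traA")
        writer.spacer(30, 60)
        writer.gene("rdf:rdfS", d, strand="+")
        writer.spacer(30, 60)
        writer.gene("relaxosome:traD", d, strand="+")
    elif kind == "qs":
        writer.spacer()
        for role_name, st in spec.qs:
            writer.gene(f"qs:{role_name}", d, status=st)
            writer.spacer(30, 70)


# ---------------------------------------------------------------------------
# the generator

def simulate_mobilome(config: SimulationConfig, out_dir: Optional[str] = None,
                      panel: Optional[ReferencePanel] = None
                      ) -> tuple[list[GenomeRecord], dict]:
    """Generate genomes + truth.  Writes FASTA/GFF3/protein FASTA + truth
    JSON when ``out_dir`` is given."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    master_rng = np.random.default_rng(ss.spawn(1)[0])
    genome_rngs = [np.random.default_rng(s)
                   for s in np.random.SeedSequence(config.seed + 1).spawn(config.n_genomes)]

    # shared chromosomal gene families
    core_bases, acc_len = [], 220
    for _ in range(config.n_core_families):
        prot = random_protein(master_rng, int(master_rng.integers(150, 350)))
        core_bases.append(back_translate(master_rng, prot))

    genomes: list[GenomeRecord] = []
    truth: dict = {"genomes": {}, "elements": {}, "recombination_events": []}

    for g in range(config.n_genomes):
        rng = genome_rngs[g]
        gid = f"SYN{g + 1:02d}"
        chrom_id = f"{gid}_chr"
        counter = [0]
        parts = []  # (bg position, writer, meta)

        # chromosomal core + accessory genes
        pos = 5_000
        for fam_idx, base in enumerate(core_bases):
            w = _GeneWriter(rng, gid, counter)
            nt, _ = mutate_cds(base, config.core_divergence, rng)
            prot = translate(nt)
            feat = {"start": 0, "end": len(nt), "strand": "+", "kind": "CDS",
                    "product": f"core family {fam_idx}", "isotype": None,
                    "locus": w._next_locus(), "protein": prot}
            w.append(nt)
            w.features.append(feat)
            parts.append((pos, w, {"type": "chromosomal"}))
            pos += 5_500
        for k in range(config.n_accessory_per_genome):
            w = _GeneWriter(rng, gid, counter)
            w.gene(None, 0.0, aa_len=acc_len)
            parts.append((pos, w, {"type": "chromosomal"}))
            pos += 3_000

        for (gg, label, apos, strand) in config.extra_anchors:
            if gg != g:
                continue
            w = _GeneWriter(rng, gid, counter)
            if label.startswith("tRNA-"):
                w.trna(label.split("-", 1)[1], strand=strand)
            else:
                w.gene(f"anchor_gene:{label}", 0.02, strand=strand)
            parts.append((apos, w, {"type": "anchor", "label": label}))

        for spec in [e for e in config.elements if e.genome == g]:
            _build_element_parts(spec, rng, gid, counter, parts, truth, chrom_id)

        # assemble the chromosome
        parts.sort(key=lambda t: t[0])
        bg = random_dna(rng, config.chromosome_length, config.gc)
        pieces, cursor, offset = [], 0, 0
        abs_meta = []
        for bg_pos, w, meta in parts:
            pieces.append(bg[cursor:bg_pos])
            offset += bg_pos - cursor
            cursor = bg_pos
            abs_meta.append((offset, w, meta))
            seq = w.sequence()
            pieces.append(seq)
            offset += len(seq)
        pieces.append(bg[cursor:])
        chrom_seq = list("".join(pieces))

        features, anchors_truth = [], []
        for off, w, meta in abs_meta:
            for f in w.features:
                features.append(GeneFeature(
                    locus_id=f["locus"], replicon_id=chrom_id,
                    start=f["start"] + off, end=f["end"] + off,
                    strand=f["strand"], kind=f["kind"], product=f["product"],
                    protein=f["protein"], trna_isotype=f["isotype"]))
            if meta["type"] in ("anchor", "element_fragment"):
                for f in w.features:
                    if meta["type"] == "anchor" or f is w.features[0]:
                        label = meta.get("label") or meta.get("anchor_label")
                        if label and (f["kind"] == "tRNA"
                                      or f["product"] in ("guaA", "radC", "dusA")):
                            p3 = (f["end"] if f["strand"] == "+" else f["start"]) + off
                            anchors_truth.append({"label": label, "position": p3,
                                                  "strand": f["strand"]})
            if meta["type"] == "element_fragment":
                _register_fragment(meta, off, truth, chrom_id)
            if meta["type"] == "artifact":
                eid = meta["element_id"]
                truth["elements"][eid]["fragments"] = [
                    [off, off + w.length]]
                truth["elements"][eid]["replicon"] = chrom_id

        _patch_core_guards(chrom_seq, truth, g)

        replicons = [Replicon(chrom_id, "".join(chrom_seq), "circular", "chromosome")]

        for pspec in [p for p in config.plasmids if p.genome == g]:
            rep, feats = _build_plasmid(pspec, rng, gid, counter, truth)
            replicons.append(rep)
            features.extend(feats)

        features.sort(key=lambda f: (f.replicon_id, f.start))
        genome = GenomeRecord(gid, replicons, features)
        genomes.append(genome)
        truth["genomes"][gid] = {
            "chromosome": chrom_id,
            "length": len(replicons[0]),
            "anchors": sorted(anchors_truth, key=lambda a: a["position"]),
            "n_features": len(features),
            "features": [[f.locus_id, f.replicon_id, f.start, f.end, f.strand,
                          f.kind] for f in features],
        }

    _apply_recombination(genomes, truth, config.recombination_events)
    _finalize_truth(genomes, truth)

    if out_dir is not None:
        from .genome_io import write_genome
        os.makedirs(out_dir, exist_ok=True)
        for genome in genomes:
            write_genome(genome, out_dir)
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)
    return genomes, truth


def _build_element_parts(spec, rng, gid, counter, parts, truth, chrom_id):
    if spec.kind == "artifact":
        w = _GeneWriter(rng, gid, counter)
        for r in ("rep:repA", "rep:repB", "rep:repC", "backbone_relaxase:rlxS",
                  "t4ss_trb:trbB", "t4ss_trb:trbC", "t4ss_trb:trbD",
                  "t4ss_trb:trbE", "t4ss_trb:trbJ", "t4ss_trb:trbL",
                  "t4ss_trb:trbF"):
            w.spacer()
            w.gene(r, spec.divergence)
        parts.append((spec.artifact_position, w, {"type": "artifact",
                                                  "element_id": spec.element_id}))
        truth["elements"][spec.element_id] = {
            "genome": gid, "class": "artifact", "partite": 0, "anchors": [],
            "core_length": 0, "pads": [], "gene_records": list(w.records),
            "symbiosis": False, "qs": [], "is_artifact": True}
        return

    mc = spec.core_length
    plan = _element_gene_plan(spec)
    n_frag = spec.partite
    # per-fragment anchor writers first: cores are the anchors' last mc bases
    anchor_writers, cores = [], []
    for label, _pos in spec.anchors:
        w = _GeneWriter(rng, gid, counter)
        if label.startswith("tRNA-"):
            w.trna(label.split("-", 1)[1])
        else:
            w.gene(f"anchor_gene:{label}", 0.02)
        seq = w.sequence()
        anchor_writers.append(w)
        cores.append(seq[-mc:])
    if len(set(cores)) < len(cores):  # ~4^-17 per pair; rerun with a new seed
        raise RuntimeError("att core collision between anchors; change the seed")

    # fragment i: [anchor_i (attL core = tail)] inner_i [right core]
    # join cycle: frag0 right core = frag1 attL core, etc., wrapping around
    pads_by_frag = {i: [] for i in range(n_frag)}
    frag_meta = []
    for i in range(n_frag):
        w = anchor_writers[i]
        anchor_len = w.length
        for item in plan[i]:
            _emit_block(w, item, spec, pads_by_frag[i])
        w.spacer(20, 40)
        right_core = cores[(i + 1) % n_frag]
        if spec.corrupt_pair is not None and (i + 1) % n_frag == spec.corrupt_pair:
            right_core = random_dna(rng, mc, 0.5)  # broken second copy
        if spec.fragment_lengths is not None:
            target = spec.fragment_lengths[i]
            natural = (w.length - (anchor_len - mc)) + mc
            if natural > target:
                raise ValueError(f"{spec.element_id}: fragment {i} natural size "
                                 f"{natural} exceeds target {target}")
            w.append(random_dna(rng, target - natural, 0.60))
        w.append(right_core)
        frag_start_rel = anchor_len - mc  # attL core overlaps the anchor tail
        for r in w.records:  # record coordinates relative to the fragment
            r["frag_index"] = i
            r["rel_start"] -= frag_start_rel
            r["rel_end"] -= frag_start_rel
        frag_meta.append({
            "type": "element_fragment", "element_id": spec.element_id,
            "frag_index": i, "anchor_label": spec.anchors[i][0],
            "frag_start_rel": frag_start_rel, "frag_len": w.length - frag_start_rel,
            "core_len": mc,
            "pads_rel": [(s - frag_start_rel, e - frag_start_rel)
                         for s, e in pads_by_frag[i]],
        })
        parts.append((spec.anchors[i][1], w, frag_meta[-1]))

    records = [r for w in anchor_writers for r in w.records]
    qs_truth = [{"role": rn, "status": st} for rn, st in (spec.qs or [])]
    truth["elements"][spec.element_id] = {
        "genome": gid, "class": spec.kind, "partite": n_frag,
        "anchors": [a for a, _ in spec.anchors], "core_length": mc,
        "cores": cores, "replicon": chrom_id,
        "fragments": [None] * n_frag,  # filled at assembly
        "pads": [None] * n_frag,
        "gene_records": records,
        "symbiosis": spec.symbiosis, "qs": qs_truth,
        "pseudogenes": [r["locus"] for w in anchor_writers for r in w.records
                        if r["basis"] in ("frameshift", "premature_stop", "truncation")],
        "corrupted_pair": spec.corrupt_pair,
        "is_artifact": False,
    }


def _register_fragment(meta, off, truth, chrom_id):
    e = truth["elements"][meta["element_id"]]
    i = meta["frag_index"]
    s = off + meta["frag_start_rel"]
    e["fragments"][i] = [s, s + meta["frag_len"]]
    # pads as absolute chromosome intervals
    e["pads"][i] = [[s + ps, s + pe] for ps, pe in meta["pads_rel"]]


def _patch_core_guards(chrom_seq: list, truth: dict, genome_index: int) -> None:
    """Make each planted repeat maximal: the base before/after the right
    copy must differ from the corresponding base at the left copy."""
    for eid, e in truth["elements"].items():
        if e.get("is_artifact") or e["fragments"][0] is None:
            continue
        mc = e["core_length"]
        n = e["partite"]
        for i in range(n):
            left_s = e["fragments"][i][0]
            j = i - 1 if n > 1 else 0  # fragment whose RIGHT core pairs with attL i
            right_e = e["fragments"][j % n][1] if n > 1 else e["fragments"][0][1]
            right_s = right_e - mc
            if e.get("corrupted_pair") is not None and i == e["corrupted_pair"]:
                continue
            for la, ra in ((left_s - 1, right_s - 1), (left_s + mc, right_e)):
                if 0 <= ra < len(chrom_seq) and 0 <= la < len(chrom_seq):
                    if chrom_seq[ra] == chrom_seq[la]:
                        for b in "ACGT":
                            if b != chrom_seq[la]:
                                chrom_seq[ra] = b
                                break


def _build_plasmid(pspec, rng, gid, counter, truth):
    w = _GeneWriter(rng, gid, counter)
    w.append(random_dna(rng, 800, 0.60))
    d = pspec.divergence
    for r in ("rep:repA", "rep:repB", "rep:repC"):
        w.spacer()
        w.gene(r, d)
    if pspec.kind == "conjugative":
        for r in BACKBONE_ROLES:
            w.spacer()
            w.gene(r, d)
        for r in ("exclusion:trbK", "marker:Rep_3", "marker:DUF2840"):
            w.spacer()
            w.gene(r, d)
    else:
        w.spacer()
        w.gene("t4cp:virD4", d)
        w.spacer()
        w.gene("relaxase:MOB_Q", d)
    for _ in range(3):
        w.spacer()
        w.gene(None, d, aa_len=200)
    pad = max(0, pspec.length - w.length)
    w.append(random_dna(rng, pad, 0.60))
    rep = Replicon(pspec.plasmid_id, w.sequence(), "circular", "plasmid")
    feats = [GeneFeature(f["locus"], pspec.plasmid_id, f["start"], f["end"],
                         f["strand"], f["kind"], f["product"], f["protein"],
                         f["isotype"]) for f in w.features]
    truth["elements"][pspec.plasmid_id] = {
        "genome": gid, "class": f"{pspec.kind}_plasmid", "partite": 0,
        "anchors": [], "core_length": 0, "replicon": pspec.plasmid_id,
        "fragments": [[0, len(rep)]], "pads": [], "gene_records": list(w.records),
        "symbiosis": False, "qs": [], "is_artifact": False,
    }
    return rep, feats


# ---------------------------------------------------------------------------
# recombination planting

def plant_recombination(genomes: list[GenomeRecord], truth: dict,
                        events: list[RecombinationEvent]) -> None:
    """Overwrite a pad of the destination element with the homologous pad
    segment of the source element; registry updated in ``truth``."""
    _apply_recombination(genomes, truth, events)
    _finalize_truth(genomes, truth)


def _element_pad(truth, element_id, pad_idx):
    e = truth["elements"][element_id]
    pads = [p for frag_pads in e["pads"] for p in frag_pads]
    if pad_idx >= len(pads):
        raise ValueError(f"{element_id}: no pad {pad_idx}")
    return e, pads[pad_idx]


def _apply_recombination(genomes, truth, events):
    by_id = {g.genome_id: g for g in genomes}
    for ev in events:
        src_e, src_pad = _element_pad(truth, ev.src_element, ev.src_pad)
        dst_e, dst_pad = _element_pad(truth, ev.dst_element, ev.dst_pad)
        if ev.length > src_pad[1] - src_pad[0] or ev.length > dst_pad[1] - dst_pad[0]:
            raise ValueError("recombination segment crosses element boundary")
        src_g, dst_g = by_id[src_e["genome"]], by_id[dst_e["genome"]]
        src_rep = src_g.replicon(src_e["replicon"])
        dst_rep = dst_g.replicon(dst_e["replicon"])
        segment = src_rep.sequence[src_pad[0]:src_pad[0] + ev.length]
        s = dst_pad[0]
        dst_rep.sequence = (dst_rep.sequence[:s] + segment +
                            dst_rep.sequence[s + ev.length:])
        # features: drop destination genes in the span, clone source genes
        span = (s, s + ev.length)
        dst_g.features = [f for f in dst_g.features
                          if not (f.replicon_id == dst_rep.id
                                  and f.start >= span[0] and f.end <= span[1])]
        shift = s - src_pad[0]
        for f in src_g.features:
            if (f.replicon_id == src_rep.id and f.start >= src_pad[0]
                    and f.end <= src_pad[0] + ev.length):
                dst_g.features.append(GeneFeature(
                    f.locus_id + "_xfer", dst_rep.id, f.start + shift,
                    f.end + shift, f.strand, f.kind, f.product, f.protein,
                    f.trna_isotype))
        dst_g.features.sort(key=lambda f: (f.replicon_id, f.start))
        src_frag = [fr for fr in src_e["fragments"] if fr[0] <= src_pad[0] < fr[1]][0]
        dst_frag = [fr for fr in dst_e["fragments"] if fr[0] <= dst_pad[0] < fr[1]][0]
        truth["recombination_events"].append({
            "src": ev.src_element, "dst": ev.dst_element, "length": ev.length,
            "src_abs": [src_pad[0], src_pad[0] + ev.length],
            "dst_abs": [span[0], span[1]],
            "src_rel": [src_pad[0] - src_frag[0], src_pad[0] + ev.length - src_frag[0]],
            "dst_rel": [span[0] - dst_frag[0], span[1] - dst_frag[0]],
        })


def _finalize_truth(genomes, truth):
    """(Re)derive circles, att pairs and feature tables from the final
    sequences (recombination events may have rewritten both)."""
    by_id = {g.genome_id: g for g in genomes}
    for g in genomes:
        gt = truth["genomes"].get(g.genome_id)
        if gt is not None:
            gt["n_features"] = len(g.features)
            gt["features"] = [[f.locus_id, f.replicon_id, f.start, f.end,
                               f.strand, f.kind] for f in g.features]
    for eid, e in truth["elements"].items():
        if e.get("is_artifact") or e["partite"] == 0:
            continue
        seq = by_id[e["genome"]].replicon(e["replicon"]).sequence
        mc = e["core_length"]
        frags = e["fragments"]
        circle = "".join(seq[s:t - mc] for s, t in frags)
        e["circle"] = circle
        e["length"] = len(circle)
        pairs = []
        if e.get("corrupted_pair") is None:
            for i in range(e["partite"]):
                j = (i - 1) % e["partite"] if e["partite"] > 1 else 0
                attl = [frags[i][0], frags[i][0] + mc]
                attr = [frags[j][1] - mc, frags[j][1]]
                if attr[0] < attl[0]:
                    attl, attr = attr, attl
                pairs.append({"attL": attl, "attR": attr, "core": e["cores"][i]})
        e["att_pairs"] = sorted(pairs, key=lambda p: p["attL"][0])


# ---------------------------------------------------------------------------
# scenarios

def default_benchmark_scenario(seed: int = 1) -> SimulationConfig:
    """The standard five-genome benchmark: 4 monopartite ICEs (2 ICESyms),
    1 tripartite ICESym, 2 IMEs, 1 conjugative + 1 mobilizable plasmid,
    1 repABC-no-att assembly artifact, 2 recombination events, QS
    duplications with one frameshift pseudogene and a traR1 remnant."""
    qs_ice1 = [("traR1", "remnant"), ("traI1", "intact"), ("traI2", "frameshift"),
               ("traR2", "intact"), ("qseM", "intact"), ("qseC", "intact"),
               ("fseA", "intact")]
    qs_ice4 = [("traR1", "intact"), ("traR2", "intact"), ("traI1", "intact"),
               ("qseM", "intact"), ("qseC", "intact"), ("fseA", "intact")]
    qs_tri = [("traR1", "intact"), ("traR2", "intact"), ("traI1", "intact"),
              ("qseM", "intact"), ("qseC", "intact")]
    elements = [
        ElementSpec("ICE1", 0, "ICE", [("tRNA-Phe", 400_000)], divergence=0.08,
                    integrases=["integrase_tyrosine:intS"], symbiosis=True,
                    qs=qs_ice1, n_pads=2),
        ElementSpec("IME1", 0, "IME", [("tRNA-Asn", 700_000)], divergence=0.10,
                    backbone=False, traACD=True, relaxase_role=None,
                    integrases=["integrase_tyrosine:intY"], n_filler=3),
        # tripartite fragments 0/1/2 (alpha/beta/gamma) are deliberately
        # interleaved on the chromosome: alpha, then gamma, then beta, so
        # every att pair encloses another fragment's mobility genes
        ElementSpec("ICE2", 1, "ICE",
                    [("tRNA-Phe", 300_000), ("tRNA-Met", 700_000), ("guaA", 500_000)],
                    partite=3, divergence=0.09, symbiosis=True, qs=qs_tri,
                    n_pads=1, n_filler=4),
        ElementSpec("ICE3", 2, "ICE", [("guaA", 400_000)], divergence=0.12,
                    integrases=["integrase_tyrosine:intY"], trbK_set=True,
                    is_copies=2, n_filler=4),
        ElementSpec("ICE4", 3, "ICE", [("tRNA-Ser", 350_000)], divergence=0.10,
                    integrases=["integrase_tyrosine:intY"], symbiosis=True,
                    qs=qs_ice4, n_pads=1),
        ElementSpec("ART1", 3, "artifact", [], divergence=0.10,
                    artifact_position=1_200_000),
        ElementSpec("ICE5", 4, "ICE", [("radC", 400_000)], divergence=0.11,
                    integrases=["integrase_tyrosine:intY"], trbK_set=True,
                    n_filler=4),
        ElementSpec("IME2", 4, "IME", [("tRNA-Met", 800_000)], divergence=0.10,
                    backbone=False, traACD=True, relaxase_role=None,
                    integrases=["integrase_serine:intSer"], n_filler=3),
    ]
    plasmids = [
        PlasmidSpec("pSYN03", 2, "conjugative", length=45_000),
        PlasmidSpec("pSYN04", 3, "mobilizable", length=30_000),
    ]
    extra = [
        (0, "tRNA-Arg", 900_000, "-"), (0, "dusA", 950_000, "+"),
        (1, "tRNA-Gly", 1_000_000, "+"), (2, "tRNA-Pro", 800_000, "+"),
        (4, "tRNA-His", 1_100_000, "-"),
    ]
    events = [
        RecombinationEvent("ICE1", 0, "ICE4", 0, 5_000),
        RecombinationEvent("ICE2", 0, "ICE1", 1, 4_000),
    ]
    return SimulationConfig(seed=seed, n_genomes=5, chromosome_length=2_000_000,
                            elements=elements, plasmids=plasmids,
                            extra_anchors=extra, recombination_events=events)


def anchor_survey_config(seed: int = 7) -> SimulationConfig:
    """One small genome planting all 16 anchor classes (no elements)."""
    extra = [(0, label, 15_000 + 12_000 * i, "+" if i % 3 else "-")
             for i, label in enumerate(ANCHOR_CLASSES_16)]
    return SimulationConfig(seed=seed, n_genomes=1, chromosome_length=250_000,
                            n_core_families=0, n_accessory_per_genome=0,
                            extra_anchors=extra)


def backbone_panel_config(seed: int = 11, n_elements: int = 20) -> SimulationConfig:
    """Mini-ICEs in ``n_elements`` genomes, all carrying the 17 backbone
    genes; one element has a sporadic deletion of msi107."""
    integrases = ["integrase_tyrosine:intS", "integrase_tyrosine:intM",
                  "integrase_tyrosine:intG", "integrase_tyrosine:intY",
                  "integrase_serine:intSer"]
    elements = []
    for i in range(n_elements):
        drops = ["conj_accessory:msi107"] if i == 3 else []
        elements.append(ElementSpec(f"BB{i:02d}", i, "ICE",
                                    [("tRNA-Phe", 60_000)], divergence=0.08,
                                    integrases=[integrases[i % len(integrases)]],
                                    n_filler=2, drop_roles=drops))
    return SimulationConfig(seed=seed, n_genomes=n_elements,
                            chromosome_length=140_000, n_core_families=4,
                            n_accessory_per_genome=2, elements=elements)


def redundancy_config(seed: int = 13) -> SimulationConfig:
    """Three single-ICE genomes: A and B identical in cargo except IS
    copies; C differs by extra cargo."""
    common = dict(divergence=0.08, symbiosis=True, n_filler=0, n_pads=0)
    elements = [
        ElementSpec("RED_A", 0, "ICE", [("tRNA-Phe", 60_000)], **common),
        ElementSpec("RED_B", 1, "ICE", [("tRNA-Phe", 60_000)], is_copies=2, **common),
        ElementSpec("RED_C", 2, "ICE", [("tRNA-Phe", 60_000)], divergence=0.08,
                    symbiosis=True, n_pads=0, n_filler=3),
    ]
    return SimulationConfig(seed=seed, n_genomes=3, chromosome_length=150_000,
                            n_core_families=4, n_accessory_per_genome=2,
                            elements=elements)


def simulate_diverged_pair(length: int, divergence: float, seed: int,
                           gc: float = 0.62) -> tuple[str, str]:
    """A genome and a copy at exactly ``divergence`` substitutions/site."""
    rng = np.random.default_rng(seed)
    a = random_dna(rng, length, gc)
    b = list(a)
    k = int(round(divergence * length))
    pos = rng.choice(length, size=k, replace=False)
    for p in pos:
        alts = [x for x in "ACGT" if x != b[p]]
        b[p] = alts[rng.integers(0, 3)]
    return a, "".join(b)
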