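"""Genome and annotation I/O plus integration-anchor location.

Supported inputs: GenBank flat files (sequence + features together) or a
nucleotide FASTA with a GFF3 annotation and a protein FASTA keyed by
locus_id.  Internally everything is 0-based half-open; GFF3 in and out is
1-based inclusive.  Proteins are taken from the annotation, never
re-predicted: genomes lacking annotation are rejected.
"""

from __future__ import annotations

import os
import re
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO

from .model import AnchorLocus, DelineatedElement, GeneFeature, GenomeRecord, Replicon

_TRNA_RE = re.compile(r"tRNA-([A-Za-z]{3})")

# anchor classes observed at ICE/IME integration sites: tRNA 3' ends and
# three protein-coding genes
PROTEIN_ANCHORS = ("guaA", "radC", "dusA")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _clean_seq(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        import warnings
        warnings.warn(f"{name}: unknown residues {sorted(bad)} kept as N")
        seq = re.sub(r"[^ACGTN]", "N", seq)
    return seq


def read_genome(nucleotide_file, annotation_file, protein_file=None,
                genome_id: Optional[str] = None) -> GenomeRecord:
    """Load a genome from GenBank, or from FASTA + GFF3 (+ protein FASTA)."""
    annotation_file = str(annotation_file)
    if annotation_file.endswith((".gb", ".gbk", ".gbff", ".genbank")):
        return _read_genbank(annotation_file, genome_id)
    if protein_file is None:
        raise ValueError("GFF3 mode requires a protein FASTA keyed by locus_id")
    return _read_gff3(nucleotide_file, annotation_file, protein_file, genome_id)


def _read_genbank(path, genome_id) -> GenomeRecord:
    replicons, features = [], []
    for rec in SeqIO.parse(path, "genbank"):
        topology = rec.annotations.get("topology", "circular")
        source_class = "chromosome"
        for f in rec.features:
            if f.type == "source" and "plasmid" in f.qualifiers:
                source_class = "plasmid"
        replicons.append(Replicon(rec.id, _clean_seq(str(rec.seq), rec.id),
                                  topology, source_class))
        for f in rec.features:
            if f.type not in ("CDS", "tRNA"):
                continue
            locus = f.qualifiers.get("locus_tag", [f"{rec.id}_{len(features)}"])[0]
            product = f.qualifiers.get("product", [""])[0]
            strand = "+" if (f.location.strand or 1) >= 0 else "-"
            feat = GeneFeature(
                locus_id=locus, replicon_id=rec.id,
                start=int(f.location.start), end=int(f.location.end),
                strand=strand, kind=f.type, product=product,
                protein=f.qualifiers.get("translation", [None])[0]
                if f.type == "CDS" else None,
                trna_isotype=_isotype(product) if f.type == "tRNA" else None)
            features.append(feat)
    gid = genome_id or os.path.splitext(os.path.basename(path))[0]
    return GenomeRecord(gid, replicons, features)


def _isotype(product: str) -> Optional[str]:
    m = _TRNA_RE.search(product)
    return m.group(1) if m else None


def _read_gff3(nucleotide_file, gff_file, protein_file, genome_id) -> GenomeRecord:
    seqs = read_fasta(nucleotide_file)
    proteins = read_fasta(protein_file)
    meta: dict[str, dict] = {}
    db = gffutils.create_db(str(gff_file), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    replicons = {name: Replicon(name, _clean_seq(s, name)) for name, s in seqs.items()}
    for f in db.all_features():
        if f.featuretype == "region":
            rep = replicons.get(f.seqid)
            if rep is not None:
                rep.topology = f.attributes.get("topology", ["circular"])[0]
                rep.source_class = f.attributes.get("source_class", ["chromosome"])[0]
    features = []
    for f in db.all_features():
        if f.featuretype not in ("CDS", "tRNA"):
            continue
        if f.seqid not in replicons:
            raise ValueError(f"feature {f.id} references missing replicon {f.seqid}")
        locus = f.attributes.get("ID", [f.id])[0]
        product = f.attributes.get("product", [""])[0]
        prot = None
        if f.featuretype == "CDS":
            if locus not in proteins:
                raise ValueError(f"no protein for CDS {locus}")
            prot = proteins[locus]
        isot = f.attributes.get("isotype", [None])[0]
        if f.featuretype == "tRNA" and isot is None:
            isot = _isotype(product)
        features.append(GeneFeature(
            locus_id=locus, replicon_id=f.seqid,
            start=f.start - 1, end=f.end,  # GFF3 1-based inclusive -> half-open
            strand=f.strand if f.strand in "+-" else "+",
            kind=f.featuretype, product=product, protein=prot, trna_isotype=isot))
    gid = genome_id or os.path.splitext(os.path.basename(str(nucleotide_file)))[0]
    features.sort(key=lambda x: (x.replicon_id, x.start, x.locus_id))
    return GenomeRecord(gid, list(replicons.values()), features)


def write_genome(genome: GenomeRecord, out_dir, prefix: Optional[str] = None) -> dict:
    """Emit FASTA + GFF3 + protein FASTA for a GenomeRecord."""
    os.makedirs(out_dir, exist_ok=True)
    prefix = prefix or genome.genome_id
    paths = {
        "fasta": os.path.join(out_dir, f"{prefix}.fna"),
        "gff3": os.path.join(out_dir, f"{prefix}.gff3"),
        "proteins": os.path.join(out_dir, f"{prefix}.faa"),
    }
    write_fasta(paths["fasta"], [(r.id, r.sequence) for r in genome.replicons])
    write_fasta(paths["proteins"],
                [(f.locus_id, f.protein) for f in genome.features
                 if f.kind == "CDS" and f.protein])
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genome.replicons:
            fh.write(f"##sequence-region {r.id} 1 {len(r)}\n")
            fh.write(f"{r.id}\ticemob\tregion\t1\t{len(r)}\t.\t+\t.\t"
                     f"ID=region-{r.id};topology={r.topology};"
                     f"source_class={r.source_class}\n")
        for f in sorted(genome.features, key=lambda x: (x.replicon_id, x.start, x.locus_id)):
            attrs = [f"ID={f.locus_id}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.trna_isotype:
                attrs.append(f"isotype={f.trna_isotype}")
            phase = "0" if f.kind == "CDS" else "."
            fh.write(f"{f.replicon_id}\ticemob\t{f.kind}\t{f.start + 1}\t{f.end}"
                     f"\t.\t{f.strand}\t{phase}\t{';'.join(attrs)}\n")
    return paths


# ---------------------------------------------------------------------------
# anchors

def locate_anchors(genome: GenomeRecord, anchor_spec: Optional[list[str]] = None,
                   hits=None) -> list[AnchorLocus]:
    """Find integration anchors and their strand-aware 3' ends.

    ``anchor_spec`` lists labels: ``tRNA-Xxx`` isotype rules and/or protein
    anchor gene names (guaA, radC, dusA).  Protein anchors are recognised by
    their best panel hit (>=40% identity, >=70% coverage); pass the panel
    ``hits`` computed by :func:`icemob.homology.search_panel`.  When
    ``anchor_spec`` is None all tRNAs plus any hit protein anchors are
    reported.
    """
    want_trna: Optional[set[str]] = None
    want_genes: Optional[set[str]] = None
    if anchor_spec is not None:
        want_trna = {a.split("-", 1)[1] for a in anchor_spec if a.startswith("tRNA-")}
        want_genes = {a for a in anchor_spec if not a.startswith("tRNA-")}
    anchors = []
    for f in genome.features:
        if f.kind != "tRNA" or f.trna_isotype is None:
            continue
        if want_trna is not None and f.trna_isotype not in want_trna:
            continue
        anchors.append(AnchorLocus(f, f"tRNA-{f.trna_isotype}", f.three_prime()))
    if hits:
        best: dict[str, tuple[float, str]] = {}
        for h in hits:
            if h.role_category != "anchor_gene":
                continue
            if h.percent_identity < 40 or h.query_coverage < 0.7:
                continue
            name = h.role_name
            if want_genes is not None and name not in want_genes:
                continue
            cur = best.get(h.query_locus)
            if cur is None or h.score > cur[0]:
                best[h.query_locus] = (h.score, name)
        by_locus = {f.locus_id: f for f in genome.features}
        for locus, (_, name) in best.items():
            f = by_locus[locus]
            anchors.append(AnchorLocus(f, name, f.three_prime()))
    anchors.sort(key=lambda a: (a.feature.replicon_id, a.position, a.label))
    return anchors


# ---------------------------------------------------------------------------
# element outputs

def write_element_outputs(elements: list[DelineatedElement], out_dir,
                          classifications=None) -> dict:
    """GFF3 of fragment/att boundaries, FASTA of circles, TSV summary."""
    os.makedirs(out_dir, exist_ok=True)
    ids = [e.element_id for e in elements]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate element ids")
    cls = {c.element_id: c for c in (classifications or [])}
    gff_path = os.path.join(out_dir, "elements.gff3")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in sorted(elements, key=lambda x: x.element_id):
            for i, fr in enumerate(e.fragments):
                fh.write(f"{fr.replicon_id}\ticemob\tmobile_genetic_element\t"
                         f"{fr.start + 1}\t{fr.end}\t.\t+\t.\t"
                         f"ID={e.element_id}.frag{i};role={fr.role};"
                         f"element={e.element_id}\n")
            for p in e.att_pairs:
                for site, (s, t) in (("attL", p.attL), ("attR", p.attR)):
                    fh.write(f"{p.replicon_id}\ticemob\tattachment_site\t"
                             f"{s + 1}\t{t}\t.\t+\t.\t"
                             f"ID={e.element_id}.{site}.{p.pair_id};site={site};"
                             f"core={p.core.core_sequence};element={e.element_id}\n")
    fasta_path = os.path.join(out_dir, "element_circles.fna")
    write_fasta(fasta_path,
                [(f"{e.element_id}|{e.partite_count}|{e.integration_site_label}",
                  e.circular_sequence)
                 for e in sorted(elements, key=lambda x: x.element_id)
                 if e.circular_sequence])
    tsv_path = os.path.join(out_dir, "elements.tsv")
    with open(tsv_path, "w") as fh:
        fh.write("element_id\tmge_class\tlength\tintegration_site\t"
                 "partite_count\tatt_status\tis_ICESym\n")
        for e in sorted(elements, key=lambda x: x.element_id):
            c = cls.get(e.element_id)
            fh.write(f"{e.element_id}\t{c.mge_class if c else 'NA'}\t{e.length}\t"
                     f"{e.integration_site_label}\t{e.partite_count}\t"
                     f"{e.att_status}\t{c.is_ICESym if c else 'NA'}\n")
    return {"gff3": gff_path, "fasta": fasta_path, "tsv": tsv_path}
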