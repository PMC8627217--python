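"""Reference panel of labelled exemplar proteins.

Every similarity-based call in the pipeline (relaxase family, conjugation
cluster roles, integrases, quorum-sensing genes, symbiosis cargo, IS
transposases, protein-coding integration anchors) is made against this panel.
Role labels are ``category:name`` strings from a controlled vocabulary.

The bundled default panel is synthetic: exemplar sequences are generated
deterministically from a fixed seed, so the package carries no third-party
sequence data.  Real exemplar sets can be supplied as FASTA with
``exemplar_id|role_label`` headers and are used identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import back_translate, random_protein

# (role_label, exemplar_id, protein length).  Backbone roles mirror the
# conserved ICE gene set: the trb conjugation cluster, T4CP, relaxase,
# prepilin peptidase, transglycosylase and RDF.
_ROLE_TABLE: list[tuple[str, str, int]] = [
    # relaxase families (MOB typing)
    ("relaxase:MOB_F", "REF_MOBF", 280),
    ("relaxase:MOB_H", "REF_MOBH", 280),
    ("relaxase:MOB_Q", "REF_MOBQ", 260),
    ("relaxase:MOB_C", "REF_MOBC", 260),
    ("relaxase:MOB_P1", "REF_MOBP1", 300),
    ("relaxase:MOB_V", "REF_MOBV", 240),
    # trb-type T4SS conjugation cluster
    ("t4ss_trb:msi031", "REF_MSI031", 110),
    ("t4ss_trb:trbB", "REF_TRBB", 200),
    ("t4ss_trb:trbC", "REF_TRBC", 110),
    ("t4ss_trb:trbD", "REF_TRBD", 100),
    ("t4ss_trb:trbE", "REF_TRBE", 240),
    ("t4ss_trb:trbJ", "REF_TRBJ", 120),
    ("t4ss_trb:trbL", "REF_TRBL", 140),
    ("t4ss_trb:trbF", "REF_TRBF", 120),
    ("t4ss_trb:trbG", "REF_TRBG", 130),
    ("t4ss_trb:trbI", "REF_TRBI", 150),
    ("t4ss_trb:msi021", "REF_MSI021", 100),
    # vir-type T4SS
    ("t4ss_vir:virB2", "REF_VIRB2", 100),
    ("t4ss_vir:virB3", "REF_VIRB3", 100),
    ("t4ss_vir:virB4", "REF_VIRB4", 240),
    ("t4ss_vir:virB5", "REF_VIRB5", 110),
    ("t4ss_vir:virB6", "REF_VIRB6", 140),
    ("t4ss_vir:virB8", "REF_VIRB8", 120),
    ("t4ss_vir:virB9", "REF_VIRB9", 130),
    ("t4ss_vir:virB10", "REF_VIRB10", 140),
    ("t4ss_vir:virB11", "REF_VIRB11", 150),
    # coupling proteins
    ("t4cp:traG", "REF_TRAG", 220),
    ("t4cp:virD4", "REF_VIRD4", 220),
    # Ti-plasmid-like relaxosome (traA doubles as the MOB_F relaxase below)
    ("relaxosome:traA", "REF_TRAA", 280),
    ("relaxosome:traC", "REF_TRAC", 120),
    ("relaxosome:traD", "REF_TRAD", 90),
    # excision / transfer accessory backbone
    ("rdf:rdfS", "REF_RDFS", 70),
    ("conj_accessory:traF", "REF_TRAF", 130),
    ("conj_accessory:msi107", "REF_MSI107", 140),
    ("exclusion:trbK", "REF_TRBK", 80),
    ("marker:Rep_3", "REF_REP3", 160),
    ("marker:DUF2840", "REF_DUF2840", 90),
    ("marker:DUF736", "REF_DUF736", 100),
    # plasmid replication
    ("rep:repA", "REF_REPA", 180),
    ("rep:repB", "REF_REPB", 160),
    ("rep:repC", "REF_REPC", 170),
    # integrases
    ("integrase_tyrosine:intS", "REF_INTS", 220),
    ("integrase_tyrosine:intM", "REF_INTM", 220),
    ("integrase_tyrosine:intG", "REF_INTG", 220),
    ("integrase_tyrosine:intY", "REF_INTY", 210),
    ("integrase_serine:intSer", "REF_INTSER", 190),
    # quorum sensing
    ("qs:traR1", "REF_TRAR1", 160),
    ("qs:traR2", "REF_TRAR2", 160),
    ("qs:traI1", "REF_TRAI1", 200),
    ("qs:traI2", "REF_TRAI2", 200),
    ("qs:qseM", "REF_QSEM", 90),
    ("qs:qseC", "REF_QSEC", 80),
    ("qs:fseA", "REF_FSEA", 170),
    # symbiosis cargo
    ("sym:nodA", "REF_NODA", 130),
    ("sym:nodB", "REF_NODB", 130),
    ("sym:nodC", "REF_NODC", 180),
    ("sym:nodI", "REF_NODI", 120),
    ("sym:nodJ", "REF_NODJ", 110),
    ("sym:nodD2", "REF_NODD2", 150),
    ("sym:nodH", "REF_NODH", 120),
    ("sym:nodS", "REF_NODS", 110),
    ("sym:noeJ", "REF_NOEJ", 120),
    ("sym:noeK", "REF_NOEK", 110),
    ("sym:nifH", "REF_NIFH", 150),
    ("sym:nifD", "REF_NIFD", 200),
    ("sym:nifK", "REF_NIFK", 200),
    ("sym:fixN", "REF_FIXN", 160),
    ("sym:fixO", "REF_FIXO", 110),
    ("sym:fixQ", "REF_FIXQ", 60),
    ("sym:fixP", "REF_FIXP", 120),
    ("sym:fixV", "REF_FIXV", 130),
    ("sym:dctA", "REF_DCTA", 150),
    ("sym:dctB", "REF_DCTB", 180),
    ("sym:dctD", "REF_DCTD", 150),
    ("sym:queC", "REF_QUEC", 110),
    ("sym:queD", "REF_QUED", 100),
    ("sym:queE", "REF_QUEE", 110),
    ("sym:nopP", "REF_NOPP", 130),
    # mobile debris and anchors
    ("is:tnpA", "REF_TNPA", 180),
    ("anchor_gene:guaA", "REF_GUAA", 180),
    ("anchor_gene:radC", "REF_RADC", 150),
    ("anchor_gene:dusA", "REF_DUSA", 140),
]

# roles whose exemplar protein is shared with another role: the ICE relaxase
# rlxS is a MOB_P1-family protein and the Ti-type TraA is the MOB_F relaxase,
# so one locus legitimately hits both labels.
_ALIASES = [
    ("backbone_relaxase:rlxS", "REF_RLXS", "REF_MOBP1"),
    ("relaxase:MOB_F_traA", "REF_TRAA_MOBF", "REF_TRAA"),
]

_PANEL_SEED = 20211004  # fixed: the bundled panel is part of the package

BACKBONE_ROLES = [
    "t4ss_trb:msi031", "t4ss_trb:trbB", "t4ss_trb:trbC", "t4ss_trb:trbD",
    "t4ss_trb:trbE", "t4ss_trb:trbJ", "t4ss_trb:trbL", "t4ss_trb:trbF",
    "t4ss_trb:trbG", "t4ss_trb:trbI", "t4ss_trb:msi021", "t4cp:traG",
    "backbone_relaxase:rlxS", "conj_accessory:msi107", "conj_accessory:traF",
    "rdf:rdfS", "marker:DUF736",
]

TRB_CORE_ROLES = [f"t4ss_trb:trb{x}" for x in "BCDEJLFGI"]
VIR_CORE_ROLES = [f"t4ss_vir:virB{x}" for x in (2, 3, 4, 5, 6, 8, 9, 10, 11)]


@dataclass
class PanelEntry:
    exemplar_id: str
    role_label: str
    protein: str
    nucleotide: str = ""


@dataclass
class ReferencePanel:
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.exemplar_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate exemplar ids in panel")

    def get(self, exemplar_id: str) -> PanelEntry:
        for e in self.entries:
            if e.exemplar_id == exemplar_id:
                return e
        raise KeyError(exemplar_id)

    def by_role(self, role_label: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.role_label == role_label]

    def by_category(self, category: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.role_label.startswith(category + ":")]

    def roles(self) -> list[str]:
        return sorted({e.role_label for e in self.entries})

    def write_fasta(self, path, kind: str = "protein") -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                seq = e.protein if kind == "protein" else e.nucleotide
                fh.write(f">{e.exemplar_id}|{e.role_label}\n{seq}\n")

    @classmethod
    def read_fasta(cls, path) -> "ReferencePanel":
        entries = []
        header, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if header is not None:
                        entries.append(_entry_from(header, "".join(chunks)))
                    header, chunks = line[1:], []
                elif line:
                    chunks.append(line)
        if header is not None:
            entries.append(_entry_from(header, "".join(chunks)))
        return cls(entries)


def _entry_from(header: str, seq: str) -> PanelEntry:
    try:
        exemplar_id, role = header.split("|", 1)
    except ValueError as exc:
        raise ValueError(f"panel header without role: {header!r}") from exc
    if set(seq) <= set("ACGTN"):
        from ._seq import translate
        return PanelEntry(exemplar_id, role, translate(seq), seq)
    return PanelEntry(exemplar_id, role, seq, "")


def default_panel() -> ReferencePanel:
    """The bundled synthetic exemplar panel (deterministic)."""
    rng = np.random.default_rng(_PANEL_SEED)
    entries = []
    for role, ex_id, length in _ROLE_TABLE:
        prot = random_protein(rng, length)
        nt = back_translate(rng, prot)
        entries.append(PanelEntry(ex_id, role, prot, nt))
    panel = ReferencePanel(entries)
    for role, ex_id, source in _ALIASES:
        src = panel.get(source)
        panel.entries.append(PanelEntry(ex_id, role, src.protein, src.nucleotide))
    return panel
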