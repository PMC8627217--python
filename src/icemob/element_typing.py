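"""Classification of delineated regions and replicons into mobile-element
classes, symbiosis flagging, QS-locus profiling, redundancy collapse and
regulatory-motif scanning."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import revcomp
from .model import (ConjugationCluster, DelineatedElement, ElementClassification,
                    GenomeRecord, HomologyHit, IntegraseCall, MotifHit,
                    MotifModel, PseudogeneCall, QSGeneCopy, QSLocusProfile,
                    RedundancyGroup, RelaxaseCall, Replicon)
from .panel import ReferencePanel

QS_ROLES = ("traR1", "traR2", "traI1", "traI2", "qseM", "qseC", "fseA")

# ICESym rule: the full Nod-factor synthesis/secretion set plus at least one
# nitrogenase and one fix gene; the rule is configurable because published
# element inventories state the outcome, not the criterion.
SYM_REQUIRED_ALL = (("sym:nodA", "sym:nodB", "sym:nodC"), ("sym:nodI", "sym:nodJ"))
SYM_REQUIRED_ANY = (("sym:nifH", "sym:nifD", "sym:nifK"),
                    ("sym:fixN", "sym:fixO", "sym:fixQ", "sym:fixP", "sym:fixV"))


@dataclass
class ElementContext:
    """Per-element evidence bundle assembled by the pipeline."""

    element_id: str
    is_plasmid_replicon: bool
    att_status: Optional[str]  # resolved | att_not_found | None (plasmid)
    hits: list[HomologyHit] = field(default_factory=list)
    relaxases: list[RelaxaseCall] = field(default_factory=list)
    integrases: list[IntegraseCall] = field(default_factory=list)
    clusters: list[ConjugationCluster] = field(default_factory=list)

    def has_role(self, role_label: str) -> bool:
        return any(h.role_label == role_label for h in self.hits)

    def has_any(self, labels) -> bool:
        return any(self.has_role(r) for r in labels)


def classify_element(ctx: ElementContext) -> ElementClassification:
    """Ordered decision rules for ICE / IME / plasmid classes.

    Integrated + att + integrase + relaxase + T4SS -> ICE; without a T4SS
    (traACD or a lone MOB gene) -> IME.  Plasmid replicons: relaxase + T4SS
    -> conjugative, relaxase and/or T4CP without T4SS -> mobilizable.
    Conflicting evidence (att pair on a plasmid replicon) classifies by att
    and logs the conflict.
    """
    types = {c.cluster_type for c in ctx.clusters}
    t4ss = "trb" if "trb_T4SS" in types else ("vir" if "vir_T4SS" in types else "none")
    has_relaxase = bool(ctx.relaxases)
    relaxase_family = ctx.relaxases[0].family if has_relaxase else None
    has_integrase = bool(ctx.integrases)
    has_traACD = "traACD" in types
    has_t4cp = "T4CP_only" in types or ctx.has_any(("t4cp:virD4", "t4cp:traG"))
    has_att = ctx.att_status == "resolved"
    integrated = not ctx.is_plasmid_replicon
    notes = []
    if ctx.is_plasmid_replicon and has_att:
        integrated, notes = True, ["att pair found on plasmid-classed replicon; "
                                   "classified by att evidence"]
    repABC = ctx.has_any(("rep:repA", "rep:repB", "rep:repC"))
    flagged = False
    mge_class = "unclassified"
    if integrated:
        att_ok = has_att or ctx.att_status == "att_not_found"
        if repABC and not has_att and ctx.att_status is not None:
            flagged = True
            notes.append("repABC with no att pair: likely assembly-joined plasmid")
            mge_class = "unclassified"
        elif att_ok and has_integrase and has_relaxase and t4ss != "none":
            mge_class = "ICE"
        elif att_ok and has_integrase and has_relaxase:
            mge_class = "IME"
    else:
        if has_relaxase and t4ss != "none":
            mge_class = "conjugative_plasmid"
        elif has_relaxase or has_t4cp:
            mge_class = "mobilizable_plasmid"
    return ElementClassification(
        element_id=ctx.element_id, mge_class=mge_class, t4ss_type=t4ss,
        relaxase_family=relaxase_family,
        trbK_present=ctx.has_role("exclusion:trbK"),
        rep3_duf2840_present=(ctx.has_role("marker:Rep_3")
                              or ctx.has_role("marker:DUF2840")),
        flagged_assembly_artifact=flagged,
        notes="; ".join(notes))


def flag_symbiosis(ctx: ElementContext,
                   required_all=SYM_REQUIRED_ALL,
                   required_any=SYM_REQUIRED_ANY) -> bool:
    """ICESym test: nodABC and nodIJ complete, plus >=1 nif and >=1 fix."""
    for group in required_all:
        if not all(ctx.has_role(r) for r in group):
            return False
    for group in required_any:
        if not ctx.has_any(group):
            return False
    return True


# ---------------------------------------------------------------------------
# QS locus profiling

def _local_nt_align(query: str, target: str):
    from .homology import make_aligner
    aligner = make_aligner("nucleotide")
    alns = aligner.align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        return None
    return alns[0]


def profile_qs_locus(element: DelineatedElement, hits: Sequence[HomologyHit],
                     genome: GenomeRecord, panel: ReferencePanel,
                     intact_min_length: float = 0.8,
                     remnant_max_coverage: float = 0.4,
                     flank: int = 2000) -> tuple[QSLocusProfile, list[PseudogeneCall]]:
    """Copy number and intact/pseudogene/remnant status of QS genes.

    Protein hits of the element's CDS locate annotated copies; the QS locus
    window is then re-scanned at nucleotide level against each QS exemplar,
    which also recovers unannotated remnants.  A copy is a pseudogene when
    the alignment shows a net frameshifting indel, an internal stop, or
    <80% of the exemplar length; matches covering <40% of the exemplar are
    remnants.
    """
    feats = {f.locus_id: f for f in genome.features}
    qs_hits = [h for h in hits if h.role_category == "qs"]
    rep_by_frag = {}
    for fr in element.fragments:
        rep_by_frag[fr.replicon_id] = genome.replicon(fr.replicon_id).sequence

    # QS windows: span of QS protein hits per fragment, padded
    windows = []
    for fr in element.fragments:
        pos = [feats[h.query_locus] for h in qs_hits
               if h.query_locus in feats
               and feats[h.query_locus].replicon_id == fr.replicon_id
               and fr.start <= feats[h.query_locus].start < fr.end]
        if not pos:
            continue
        lo = max(fr.start, min(f.start for f in pos) - flank)
        hi = min(fr.end, max(f.end for f in pos) + flank)
        windows.append((fr, lo, hi))

    copies: list[QSGeneCopy] = []
    pseudo: list[PseudogeneCall] = []
    for fr, lo, hi in windows:
        target = rep_by_frag[fr.replicon_id][lo:hi]
        masked = target
        for role in QS_ROLES:
            entries = panel.by_role(f"qs:{role}")
            if not entries:
                continue
            ex = entries[0]
            work = masked
            while True:
                aln = _local_nt_align(ex.nucleotide, work)
                if aln is None or len(aln.aligned[0]) == 0:
                    break
                counts = aln.counts()
                cols = counts.identities + counts.mismatches + counts.gaps
                ident = counts.identities / cols if cols else 0.0
                qspan = sum(e - s for s, e in aln.aligned[0])
                coverage = qspan / len(ex.nucleotide)
                t0, t1 = aln.aligned[1][0][0], aln.aligned[1][-1][1]
                # 72% floor rejects the short spurious local matches random
                # sequence can reach; genuine diverged copies sit near 90%
                if ident < 0.72 or qspan < 60:
                    break
                status, basis = _copy_status(aln, ex, coverage, work[t0:t1],
                                             intact_min_length, remnant_max_coverage)
                copies.append(QSGeneCopy(
                    role=role, start=lo + t0 - fr.start, end=lo + t1 - fr.start,
                    status=status, basis=basis, identity=100 * ident,
                    exemplar_coverage=coverage))
                if status == "pseudogene":
                    locus = _overlapping_locus(genome, fr.replicon_id,
                                               lo + t0, lo + t1)
                    pseudo.append(PseudogeneCall(locus or f"{element.element_id}:"
                                                 f"{lo + t0}", basis, ex.exemplar_id))
                work = work[:t0] + "X" * (t1 - t0) + work[t1:]
            masked = work
    copies.sort(key=lambda c: (c.start, c.role))
    return QSLocusProfile(element.element_id, copies), pseudo


def _copy_status(aln, ex, coverage, matched_nt, intact_min_length,
                 remnant_max_coverage):
    if coverage < remnant_max_coverage:
        return "remnant", None
    # net indel from coordinate ranges (gap columns), not aligned residues
    qrange = int(aln.aligned[0][-1][1] - aln.aligned[0][0][0])
    trange = int(aln.aligned[1][-1][1] - aln.aligned[1][0][0])
    if (qrange - trange) % 3 != 0:
        return "pseudogene", "frameshift"
    # internal stop check, translated in the exemplar reading frame
    q0 = int(aln.aligned[0][0][0])
    frame_nt = matched_nt[(3 - q0 % 3) % 3:]
    aa = _translate_with_stops(frame_nt)
    if "*" in aa[:-2]:
        return "pseudogene", "premature_stop"
    if coverage < intact_min_length:
        return "pseudogene", "truncation"
    return "intact", None


def _translate_with_stops(nt: str) -> str:
    from Bio.Seq import Seq
    n = len(nt) - len(nt) % 3
    return str(Seq(nt[:n]).translate())


def _overlapping_locus(genome, replicon_id, start, end):
    for f in genome.features:
        if (f.replicon_id == replicon_id and f.kind == "CDS"
                and f.start < end and start < f.end):
            return f.locus_id
    return None


# ---------------------------------------------------------------------------
# redundancy

def collapse_redundant(element_lengths: dict[str, int],
                       presence: "object",
                       is_clusters: Sequence[str] = ()) -> list[RedundancyGroup]:
    """Partition elements sharing identical accessory cluster sets.

    ``presence`` is a clusters x elements 0/1 DataFrame.  IS clusters are
    ignored; SNP-level divergence is invisible at cluster level, so
    SNP-only variant copies collapse together.  The representative is the
    longest member; grouping is input-order invariant.
    """
    drop = [c for c in is_clusters if c in presence.index]
    pa = presence.drop(index=drop)
    signature: dict[tuple, list[str]] = {}
    for el in sorted(pa.columns):
        sig = tuple(pa.index[pa[el] > 0])
        signature.setdefault(sig, []).append(el)
    groups = []
    for sig in sorted(signature, key=lambda s: (len(s), s)):
        members = sorted(signature[sig])
        rep = max(members, key=lambda e: (element_lengths.get(e, 0), e))
        groups.append(RedundancyGroup(rep, members))
    groups.sort(key=lambda g: g.representative_element_id)
    return groups


# ---------------------------------------------------------------------------
# motif scan (nod boxes)

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def build_motif(motif_id: str, training: Sequence[str],
                background=(0.25, 0.25, 0.25, 0.25),
                pseudocount: float = 0.5) -> MotifModel:
    """Position weight matrix from aligned equal-length training sequences;
    threshold = the minimum self-score of the training set."""
    if len(training) < 2:
        raise ValueError("need >=2 training sequences")
    L = len(training[0])
    if any(len(t) != L for t in training):
        raise ValueError("training sequences of unequal length")
    counts = np.full((4, L), pseudocount)
    for t in training:
        for j, b in enumerate(t.upper()):
            if b in _BASE_INDEX:
                counts[_BASE_INDEX[b], j] += 1
    probs = counts / counts.sum(axis=0, keepdims=True)
    bg = np.asarray(background, dtype=float).reshape(4, 1)
    lo = np.log2(probs / bg)
    model = MotifModel(motif_id, lo, bg.ravel(), threshold=0.0)
    model.threshold = min(_score(model, t) for t in training)
    return model


def _score(model: MotifModel, window: str) -> float:
    s = 0.0
    for j, b in enumerate(window.upper()):
        i = _BASE_INDEX.get(b)
        if i is None:
            return -np.inf
        s += model.log_odds[i, j]
    return s


def scan_motif(model: MotifModel, replicon: Replicon,
               strand_mode: str = "both") -> list[MotifHit]:
    """All windows on the requested strands scoring >= the model threshold."""
    L = model.length
    seq = replicon.sequence
    hits = []
    strands = ("+", "-") if strand_mode == "both" else (strand_mode,)
    for strand in strands:
        s = seq if strand == "+" else revcomp(seq)
        n = len(s)
        for i in range(n - L + 1):
            sc = _score(model, s[i:i + L])
            if sc >= model.threshold:
                if strand == "+":
                    hits.append(MotifHit(i, i + L, "+", sc))
                else:
                    hits.append(MotifHit(n - (i + L), n - i, "-", sc))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
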