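"""Similarity-based calls: panel search, relaxase MOB typing, conjugation
clusters and integrase detection.

Pairwise identity is defined as identities / aligned columns (gaps counted
as columns) of the best local alignment, BLOSUM62 (open -11 / extend -1) for
proteins and +1/-1 with gap -2 for nucleotide, matching BLAST usage.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Optional, Sequence, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .model import (ConjugationCluster, GeneFeature, GenomeRecord, HomologyHit,
                    IntegraseCall, RelaxaseCall)
from .panel import ReferencePanel, TRB_CORE_ROLES, VIR_CORE_ROLES

RELAXASE_FAMILIES = ("MOB_F", "MOB_H", "MOB_Q", "MOB_C", "MOB_P", "MOB_V")


def make_aligner(seq_type: str = "protein") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if seq_type == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -2.0
    return aligner


def align_pair(query: str, subject: str, seq_type: str = "protein",
               aligner: Optional[Align.PairwiseAligner] = None):
    """Best local alignment -> (identity%, qcov, scov, score) or None."""
    if not query or not subject:
        return None
    if aligner is None:
        aligner = make_aligner(seq_type)
    alns = aligner.align(query, subject)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    identity = 100.0 * counts.identities / columns
    qblocks, sblocks = aln.aligned[0], aln.aligned[1]
    qcov = sum(e - s for s, e in qblocks) / len(query)
    scov = sum(e - s for s, e in sblocks) / len(subject)
    return identity, qcov, scov, float(aln.score)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def search_panel(proteins: Union[GenomeRecord, Sequence],
                 panel: ReferencePanel,
                 min_identity: float = 30.0,
                 min_coverage: float = 0.6,
                 seq_type: str = "protein") -> list[HomologyHit]:
    """All panel hits passing thresholds, per query sorted by descending score.

    ``proteins`` is a GenomeRecord (its CDS are used), a list of GeneFeature,
    or (locus_id, sequence) pairs.  Coverage is measured on the query.  A
    shared-k-mer prefilter skips alignments that cannot pass; queries with
    zero shared words with an exemplar are unrelated at these thresholds.
    """
    queries: list[tuple[str, str]] = []
    if isinstance(proteins, GenomeRecord):
        items: Iterable = proteins.cds()
    else:
        items = proteins
    for it in items:
        if isinstance(it, GeneFeature):
            if it.kind == "CDS" and it.protein:
                queries.append((it.locus_id, it.protein))
        else:
            queries.append((it[0], it[1]))
    if not panel.entries:
        raise ValueError("empty reference panel")
    k = 4 if seq_type == "protein" else 8
    aligner = make_aligner(seq_type)
    ex_kmers = []
    for e in panel.entries:
        seq = e.protein if seq_type == "protein" else e.nucleotide
        ex_kmers.append((e, seq, _kmers(seq, k)))
    hits: list[HomologyHit] = []
    for locus, qseq in queries:
        qk = _kmers(qseq, k)
        locus_hits = []
        for e, sseq, sk in ex_kmers:
            if len(qk & sk) < 2:
                continue
            res = align_pair(qseq, sseq, seq_type, aligner)
            if res is None:
                continue
            ident, qcov, scov, score = res
            if ident < min_identity or qcov < min_coverage:
                continue
            locus_hits.append(HomologyHit(
                query_locus=locus, exemplar_id=e.exemplar_id,
                role_label=e.role_label, percent_identity=ident,
                query_coverage=qcov, subject_coverage=scov, score=score,
                evalue_proxy=math.exp(-score / 10.0)))
        locus_hits.sort(key=lambda h: (-h.score, h.exemplar_id))
        hits.extend(locus_hits)
    return hits


# ---------------------------------------------------------------------------
# relaxase MOB typing

def parse_hmm_table(path_or_lines) -> list[dict]:
    """Parse an hmmscan ``--tblout``-style table.

    Space-delimited columns: target name, target accession, query name,
    query accession, full-sequence e-value, full-sequence score, ...  The
    target name must carry the MOB family (e.g. ``MOBP1`` or ``MOB_P``).
    Malformed rows are skipped with a warning.
    """
    if isinstance(path_or_lines, (str, bytes)) or hasattr(path_or_lines, "read"):
        fh = open(path_or_lines) if isinstance(path_or_lines, (str, bytes)) else path_or_lines
        lines = fh.read().splitlines()
    else:
        lines = list(path_or_lines)
    rows = []
    for ln in lines:
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split()
        try:
            rows.append({"target": parts[0], "query": parts[2],
                         "evalue": float(parts[4]), "score": float(parts[5])})
        except (IndexError, ValueError):
            warnings.warn(f"skipping malformed HMM table row: {ln!r}")
    return rows


def _family_from_label(label: str) -> tuple[Optional[str], Optional[str]]:
    """Normalise a profile/role name to (MOB family, subtype)."""
    s = label.upper().replace("-", "_")
    if "MOB" not in s:
        return None, None
    s = s[s.index("MOB") + 3:].lstrip("_")
    if not s:
        return None, None
    fam = s[0]
    if fam not in "FHQCPV":
        return None, None
    subtype = None
    rest = s[1:].lstrip("_")
    if fam == "P" and rest.startswith("1"):
        subtype = "P1"
    return f"MOB_{fam}", subtype


def classify_relaxases(hits_or_table, bit_threshold: float = 33.0) -> list[RelaxaseCall]:
    """One MOB family per locus from panel hits or an HMM domain table.

    Hits at or above ``bit_threshold`` qualify; ties across families are
    broken by best full-sequence e-value, then best score, then lexicographic
    exemplar/profile id.  Output is invariant to input order.
    """
    per_locus: dict[str, list[tuple[float, float, str, str, Optional[str], str]]] = {}
    for h in hits_or_table:
        if isinstance(h, HomologyHit):
            if h.role_category not in ("relaxase",):
                continue
            fam, sub = _family_from_label(h.role_name)
            rec = (h.evalue_proxy, -h.score, h.exemplar_id, fam, sub, "panel_search")
            locus, score = h.query_locus, h.score
        else:
            fam, sub = _family_from_label(h["target"])
            rec = (h["evalue"], -h["score"], h["target"], fam, sub, "hmm_table")
            locus, score = h["query"], h["score"]
        if fam is None or score < bit_threshold:
            continue
        per_locus.setdefault(locus, []).append(rec)
    calls = []
    for locus in sorted(per_locus):
        evalue, negscore, _, fam, sub, basis = min(per_locus[locus])
        calls.append(RelaxaseCall(locus, fam, sub, -negscore, basis))
    return calls


# ---------------------------------------------------------------------------
# conjugation clusters and integrases

_CLUSTER_CATEGORIES = ("t4ss_trb", "t4ss_vir", "t4cp", "relaxosome", "rdf",
                       "conj_accessory", "relaxase", "backbone_relaxase")


def detect_conjugation_clusters(genome: GenomeRecord, hits: list[HomologyHit],
                                locus_window: int = 10_000) -> list[ConjugationCluster]:
    """Group colocated conjugation-role hits and type each group.

    trb_T4SS: >=6 of the 9 trb roles; vir_T4SS: >=6 vir roles; traACD:
    traA + traC divergently oriented (traD optional, adjacent RDF noted);
    T4CP_only: a coupling protein with none of the above.
    """
    best_role: dict[str, HomologyHit] = {}
    for h in hits:
        if h.role_category not in _CLUSTER_CATEGORIES:
            continue
        cur = best_role.get(h.query_locus)
        if cur is None or h.score > cur.score:
            best_role[h.query_locus] = h
    feats = {f.locus_id: f for f in genome.features}
    loci = sorted((f.replicon_id, f.start, lid) for lid, f in feats.items()
                  if lid in best_role)
    clusters: list[ConjugationCluster] = []
    group: list[str] = []

    def flush(group):
        if not group:
            return
        cl = _type_cluster(genome, group, best_role, feats, len(clusters))
        if cl is not None:
            clusters.append(cl)

    prev_rep, prev_end = None, None
    for rep, start, lid in loci:
        if prev_rep == rep and prev_end is not None and start - prev_end <= locus_window:
            group.append(lid)
        else:
            flush(group)
            group = [lid]
        prev_rep, prev_end = rep, feats[lid].end
    flush(group)
    return clusters


def _type_cluster(genome, group, best_role, feats, idx) -> Optional[ConjugationCluster]:
    roles = {lid: best_role[lid].role_label for lid in group}
    role_set = set(roles.values())
    trb_n = len(role_set & set(TRB_CORE_ROLES))
    vir_n = len(role_set & set(VIR_CORE_ROLES))
    rep_id = feats[group[0]].replicon_id
    start = min(feats[l].start for l in group)
    end = max(feats[l].end for l in group)
    notes = []
    traA = [l for l, r in roles.items() if r == "relaxosome:traA"]
    traC = [l for l, r in roles.items() if r == "relaxosome:traC"]
    ctype = None
    completeness = 0.0
    if trb_n >= 6:
        ctype, completeness = "trb_T4SS", trb_n / 9.0
    elif vir_n >= 6:
        ctype, completeness = "vir_T4SS", vir_n / 9.0
    elif traA and traC:
        fa, fc = feats[traA[0]], feats[traC[0]]
        minus_first = (fc.strand == "-" and fa.strand == "+" and fc.start < fa.start) or \
                      (fa.strand == "-" and fc.strand == "+" and fa.start < fc.start)
        if fa.strand != fc.strand and minus_first:
            ctype = "traACD"
            present = {"relaxosome:traA", "relaxosome:traC"} | \
                      (role_set & {"relaxosome:traD"})
            completeness = len(present) / 3.0
            notes.append("traA/traC divergent")
            if any(r == "rdf:rdfS" for r in roles.values()):
                notes.append("adjacent RDF gene")
    if ctype is None and role_set & {"t4cp:traG", "t4cp:virD4"}:
        ctype, completeness = "T4CP_only", 1.0
    if ctype is None:
        return None
    members = sorted(group, key=lambda l: feats[l].start)
    return ConjugationCluster(f"{genome.genome_id}.conj{idx}", ctype, members,
                              completeness, rep_id, start, end, "; ".join(notes))


def detect_integrases(hits: list[HomologyHit]) -> list[IntegraseCall]:
    """Classify integrase hits tyrosine/serine; family from the best exemplar."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if h.role_category not in ("integrase_tyrosine", "integrase_serine"):
            continue
        cur = best.get(h.query_locus)
        if cur is None or h.score > cur.score:
            best[h.query_locus] = h
    calls = []
    for locus in sorted(best):
        h = best[locus]
        int_class = "tyrosine" if h.role_category == "integrase_tyrosine" else "serine"
        fam = h.role_name if h.role_name in ("intS", "intM", "intG") else "other"
        calls.append(IntegraseCall(locus, int_class, fam, h.score))
    return calls
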