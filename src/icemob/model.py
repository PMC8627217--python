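"""Shared domain types for the mobilome pipeline.

Coordinates are 0-based half-open throughout; emitted GFF3 is 1-based
inclusive.  A "unit" is whatever carries genes in a given analysis: a whole
genome, a delineated element, or a plasmid replicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

NUCLEOTIDES = set("ACGTN")


@dataclass
class Replicon:
    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    source_class: str = "chromosome"  # chromosome | plasmid | unplaced

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValueError(f"replicon {self.id}: bad residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    locus_id: str
    replicon_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # + | -
    kind: str  # CDS | tRNA | other
    product: str = ""
    protein: Optional[str] = None  # CDS only
    trna_isotype: Optional[str] = None  # tRNA only

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.locus_id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: bad strand {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def three_prime(self) -> int:
        """Strand-aware 3' end coordinate (end on +, start on -)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class GenomeRecord:
    genome_id: str
    replicons: list[Replicon]
    features: list[GeneFeature]
    host_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_id = {}
        for rep in self.replicons:
            if rep.id in by_id:
                raise ValueError(f"duplicate replicon id {rep.id}")
            by_id[rep.id] = rep
        for f in self.features:
            if f.replicon_id not in by_id:
                raise ValueError(f"{f.locus_id}: unknown replicon {f.replicon_id}")
            if f.end > len(by_id[f.replicon_id]):
                raise ValueError(f"{f.locus_id}: beyond replicon bounds")
        self._replicon_index = by_id

    def replicon(self, replicon_id: str) -> Replicon:
        return self._replicon_index[replicon_id]

    def features_on(self, replicon_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.replicon_id == replicon_id]

    def cds(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


@dataclass(frozen=True)
class AnchorLocus:
    """An integration anchor (tRNA or anchor gene) with its 3' end."""

    feature: GeneFeature
    label: str  # e.g. tRNA-Phe, guaA
    position: int  # strand-aware 3' end


# ---------------------------------------------------------------------------
# homology

@dataclass
class HomologyHit:
    query_locus: str
    exemplar_id: str
    role_label: str
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    score: float
    evalue_proxy: float = 0.0

    @property
    def role_category(self) -> str:
        return self.role_label.split(":", 1)[0]

    @property
    def role_name(self) -> str:
        return self.role_label.split(":", 1)[1]


@dataclass
class RelaxaseCall:
    query_locus: str
    family: str  # MOB_F/H/Q/C/P/V
    subtype: Optional[str]  # P1
    score: float
    decision_basis: str  # hmm_table | panel_search


@dataclass
class ConjugationCluster:
    cluster_id: str
    cluster_type: str  # trb_T4SS | vir_T4SS | traACD | T4CP_only
    member_loci: list[str]
    completeness: float
    replicon_id: str
    start: int
    end: int
    orientation_notes: str = ""


@dataclass
class IntegraseCall:
    query_locus: str
    int_class: str  # tyrosine | serine
    int_family: Optional[str]  # intS | intM | intG | other
    score: float


# ---------------------------------------------------------------------------
# att delineation

@dataclass
class AttCore:
    core_sequence: str
    core_family: str = "other"  # S | M | G | other, or pair id

    @property
    def length(self) -> int:
        return len(self.core_sequence)


@dataclass
class AttSitePair:
    replicon_id: str
    attL: tuple[int, int]
    attR: tuple[int, int]
    core: AttCore
    anchor: Optional[AnchorLocus]
    associated_integrase: Optional[IntegraseCall] = None
    pair_id: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.attL[0], self.attR[1])


@dataclass
class ElementFragment:
    replicon_id: str
    start: int
    end: int  # attL start -> attR end, cores included
    role: str  # mono | alpha | beta | gamma
    left_core_family: str
    right_core_family: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DelineatedElement:
    element_id: str
    fragments: list[ElementFragment]
    partite_count: int
    circular_sequence: Optional[str]
    attP_cores: list[AttCore]
    integration_site_label: str
    att_status: str  # resolved | att_not_found
    att_pairs: list[AttSitePair] = field(default_factory=list)

    @property
    def length(self) -> int:
        if self.circular_sequence is not None:
            return len(self.circular_sequence)
        return sum(f.length for f in self.fragments)


# ---------------------------------------------------------------------------
# element typing

@dataclass
class ElementClassification:
    element_id: str
    mge_class: str  # ICE | IME | conjugative_plasmid | mobilizable_plasmid | unclassified
    t4ss_type: str  # trb | vir | none
    relaxase_family: Optional[str]
    is_ICESym: bool = False
    trbK_present: bool = False
    rep3_duf2840_present: bool = False
    flagged_assembly_artifact: bool = False
    notes: str = ""


@dataclass
class QSGeneCopy:
    role: str  # traR1, traR2, traI1, traI2, qseM, qseC, fseA
    start: int  # element-relative
    end: int
    status: str  # intact | pseudogene | remnant
    basis: Optional[str] = None  # frameshift | premature_stop | truncation
    identity: float = 0.0
    exemplar_coverage: float = 0.0


@dataclass
class QSLocusProfile:
    element_id: str
    copies: list[QSGeneCopy]

    def count(self, role: str) -> int:
        return sum(1 for c in self.copies if c.role == role)


@dataclass
class PseudogeneCall:
    locus_id: str
    basis: str  # frameshift | premature_stop | truncation
    reference_exemplar: str


@dataclass
class MotifModel:
    motif_id: str
    log_odds: "object"  # 4 x L array, rows A,C,G,T
    background: "object"  # length-4 array
    threshold: float

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]


@dataclass(frozen=True)
class MotifHit:
    start: int
    end: int
    strand: str
    score: float


@dataclass
class RedundancyGroup:
    representative_element_id: str
    member_element_ids: list[str]


# ---------------------------------------------------------------------------
# pangenome

@dataclass
class OrthologClusterSet:
    clusters: dict[str, list[str]]  # cluster_id -> member locus ids
    identity_threshold: float
    singletons_included: bool = True

    def locus_to_cluster(self) -> dict[str, str]:
        out = {}
        for cid, members in self.clusters.items():
            for m in members:
                out[m] = cid
        return out


@dataclass
class BackboneSet:
    cluster_ids: list[str]
    prevalence_threshold: float
    single_copy_subset: list[str]


@dataclass
class MobilomeAccount:
    n_clusters: int
    n_mge_clusters: int
    mge_fraction: float
    category_share: dict[str, float]  # ICE/ICESym-nested accounting below
    icesym_share_of_ice: float


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    ani: float  # percent; nan if no qualifying fragments
    n_fragments: int


@dataclass
class AssociationResult:
    cluster_id: str
    table: tuple[int, int, int, int]  # a,b,c,d: presence x trait
    odds_ratio: float
    p_value: float
    bonferroni_p: float
    significant: bool


# ---------------------------------------------------------------------------
# recombination

@dataclass
class MatchProfile:
    query_id: str
    subject_id: str
    lengths: "object"  # int array over query positions


@dataclass
class HomologySegment:
    start: int
    end: int  # query coordinates, half-open
    mean_window_p: float

    @property
    def additive_length(self) -> int:
        return self.end - self.start


@dataclass
class RecombinationEdge:
    query_id: str
    subject_id: str
    additive_length: int
    query_fraction: float
    segments: list[HomologySegment] = field(default_factory=list)
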