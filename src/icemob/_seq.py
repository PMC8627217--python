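"""Low-level sequence utilities used across modules."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

# codon preferred per amino acid (deterministic back-translation base table)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def translate(nt: str) -> str:
    """Translate a CDS, trimming to codon boundary; no stop included."""
    n = len(nt) - len(nt) % 3
    aa = str(Seq(nt[:n]).translate())
    return aa[:-1] if aa.endswith("*") else aa


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def random_protein(rng: np.random.Generator, n_aa: int) -> str:
    body = "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=n_aa - 1)])
    return "M" + body


def back_translate(rng: np.random.Generator, protein: str) -> str:
    """Random-codon back-translation plus a stop codon."""
    codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein]
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def mutate_cds(nt: str, divergence: float, rng: np.random.Generator) -> tuple[str, float]:
    """Substitute ``divergence`` fraction of sites, avoiding new in-frame stops
    and the start/stop codons.  Returns (mutant, realized divergence)."""
    seq = list(nt)
    n = len(seq)
    candidates = np.arange(3, n - 3)
    k = int(round(divergence * n))
    k = min(k, len(candidates))
    pos = rng.choice(candidates, size=k, replace=False)
    changed = 0
    for p in pos:
        old = seq[p]
        alts = [b for b in BASES if b != old]
        rng.shuffle(alts)
        cstart = (p // 3) * 3
        for b in alts:
            seq[p] = b
            if "".join(seq[cstart:cstart + 3]) not in STOP_CODONS:
                changed += 1
                break
        else:
            seq[p] = old
    return "".join(seq), changed / n


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute an exact fraction of residues to different amino acids."""
    seq = list(protein)
    k = int(round(divergence * len(seq)))
    pos = rng.choice(len(seq), size=k, replace=False)
    for p in pos:
        alts = [a for a in AMINO_ACIDS if a != seq[p]]
        seq[p] = alts[rng.integers(0, len(alts))]
    return "".join(seq)


def rotations_equal(a: str, b: str) -> bool:
    """Equality of two sequences as circular strings."""
    return len(a) == len(b) and b in (a + a)
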