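"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (brute-force string splicing,
exhaustive dynamic programming, hypergeometric enumeration) and shares no
code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# splice oracles

def mono_reintegrate(scar: str, circle: str, attB_start: int, core_len: int) -> str:
    """Insert a circle at an attB site: the circle opens after its leading
    core and the core is duplicated, recreating attL/attR."""
    cut = attB_start + core_len
    return scar[:cut] + circle[core_len:] + circle[:core_len] + scar[cut:]


def scar_by_splicing(original: str, fragments, core_len: int) -> str:
    """Replace each fragment with a single copy of its leading core."""
    out, pos = [], 0
    for s, e in sorted(fragments):
        out.append(original[pos:s])
        out.append(original[s:s + core_len])
        pos = e
    out.append(original[pos:])
    return "".join(out)


def circle_by_splicing(original: str, join_order_fragments, core_len: int) -> str:
    """Concatenate fragments in join order, dropping each trailing core."""
    return "".join(original[s:e - core_len] for s, e in join_order_fragments)


# ---------------------------------------------------------------------------
# exhaustive local alignment (Gotoh affine) for short sequences

def local_align_score(a: str, b: str, sub, gap_open: float, gap_extend: float
                      ) -> float:
    """Best local alignment score; gap of length L costs open+(L-1)*extend."""
    n, m = len(a), len(b)
    neg = -math.inf
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = sub(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def blosum62_fn():
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(m[x, y])


# ---------------------------------------------------------------------------
# match-length profile oracle (vectorised longest-common-extension DP)

def lce_profile(query: str, subject: str) -> np.ndarray:
    """profile[i] = longest substring starting at query[i] present anywhere
    in subject or its reverse complement."""
    out = np.zeros(len(query), dtype=np.int64)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    for t in (subject, revcomp(subject)):
        s = np.frombuffer(t.encode(), dtype=np.uint8)
        m = len(s)
        nxt = np.zeros(m, dtype=np.int64)
        for i in range(len(q) - 1, -1, -1):
            cur = np.zeros(m, dtype=np.int64)
            eq = s == q[i]
            cur[:-1] = np.where(eq[:-1], nxt[1:] + 1, 0)
            cur[-1] = 1 if eq[-1] else 0
            if m:
                out[i] = max(out[i], int(cur.max()))
            nxt = cur
    return out


# ---------------------------------------------------------------------------
# exact two-sided Fisher p by hypergeometric enumeration

def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p: sum of hypergeometric probabilities of all tables with
    the same margins whose probability <= that of the observed table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(x, y):
        return math.lgamma(x + 1) - math.lgamma(y + 1) - math.lgamma(x - y + 1)

    def log_p(aa):
        return (log_comb(r1, aa) + log_comb(r2, c1 - aa) - log_comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = log_p(a)
    total = 0.0
    for aa in range(lo, hi + 1):
        lp = log_p(aa)
        if lp <= p_obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


# ---------------------------------------------------------------------------
# random planted-element constructors (used by the splice round-trip tests)

def _rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _patch_diff(seq_list, idx, other_char):
    if seq_list[idx] == other_char:
        for b in "ACGT":
            if b != other_char:
                seq_list[idx] = b
                break


def build_monopartite_case(rng, core_len: int = 17):
    """Random replicon with one planted integrated element.

    Returns (GenomeRecord, anchors, seeds, truth) where truth holds the
    fragment interval, att pair and the original sequence.
    """
    from icemob.model import GeneFeature, GenomeRecord, Replicon
    from icemob.genome_io import locate_anchors

    u = int(rng.integers(2000, 6000))
    inner_len = int(rng.integers(1500, 8000))
    bg1 = _rand_dna(rng, u)
    anchor = _rand_dna(rng, 76)
    core = anchor[-core_len:]
    inner = list(_rand_dna(rng, inner_len))
    bg2 = list(_rand_dna(rng, int(rng.integers(2000, 6000))))
    _patch_diff(inner, -1, anchor[-core_len - 1])  # attR left neighbour
    _patch_diff(bg2, 0, inner[0])  # attR right neighbour
    seq = bg1 + anchor + "".join(inner) + core + "".join(bg2)
    p = u + 76
    feat = GeneFeature("anchor1", "rep", u, p, "+", "tRNA",
                       product="tRNA-Phe", trna_isotype="Phe")
    genome = GenomeRecord("case", [Replicon("rep", seq, "circular")], [feat])
    anchors = locate_anchors(genome)
    mid = p + inner_len // 2
    seeds = [(mid, mid + 30)]
    truth = {"fragment": (p - core_len, p + inner_len + core_len),
             "attL": (p - core_len, p), "attR": (p + inner_len,
                                                 p + inner_len + core_len),
             "core": core, "original": seq}
    return genome, anchors, seeds, truth


def build_tripartite_case(rng, core_len: int = 17, corrupt_pair=None):
    """Random replicon with a planted tripartite element (fragments laid
    out 0, 2, 1 so that every att pair encloses mobility genes)."""
    from icemob.model import GeneFeature, GenomeRecord, Replicon
    from icemob.genome_io import locate_anchors

    anchors_seq = [_rand_dna(rng, 76) for _ in range(3)]
    cores = [a[-core_len:] for a in anchors_seq]
    if len(set(cores)) < 3:
        raise RuntimeError("core collision")
    inners = [list(_rand_dna(rng, int(rng.integers(1200, 5000))))
              for _ in range(3)]
    bgs = [list(_rand_dna(rng, int(rng.integers(1500, 4000))))
           for _ in range(4)]
    # genomic order: fragment 0 (c0..c1), fragment 2 (c2..c0), fragment 1
    # (c1..c2); right core of fragment i is cores[(i+1)%3]
    genomic = [0, 2, 1]
    pieces = []
    pos = 0
    feats = []
    frag_iv = {}
    isotypes = ["Phe", "Met", "Gly"]
    for k, fi in enumerate(genomic):
        bg = "".join(bgs[k])
        pieces.append(bg)
        pos += len(bg)
        astart = pos
        pieces.append(anchors_seq[fi])
        pos += 76
        feats.append(GeneFeature(f"anchor{fi}", "rep", astart, pos, "+",
                                 "tRNA", product=f"tRNA-{isotypes[fi]}",
                                 trna_isotype=isotypes[fi]))
        frag_start = pos - core_len
        right_core = cores[(fi + 1) % 3]
        if corrupt_pair is not None and (fi + 1) % 3 == corrupt_pair:
            right_core = _rand_dna(rng, core_len)
        pieces.append("".join(inners[fi]))
        pos += len(inners[fi])
        pieces.append(right_core)
        pos += core_len
        frag_iv[fi] = (frag_start, pos)
    pieces.append("".join(bgs[3]))
    seq = list("".join(pieces))
    # repeat-maximality guards on the right-copy flanks
    for fi in range(3):
        if corrupt_pair is not None and fi == corrupt_pair:
            continue
        left_s = frag_iv[fi][0]
        right_e = frag_iv[(fi - 1) % 3][1]
        right_s = right_e - core_len
        for la, ra in ((left_s - 1, right_s - 1), (left_s + core_len, right_e)):
            _patch_diff(seq, ra, seq[la])
    seq = "".join(seq)
    genome = GenomeRecord("case", [Replicon("rep", seq, "circular")], feats)
    anchors = locate_anchors(genome)
    seeds = []
    for fi in range(3):
        s, e = frag_iv[fi]
        mid = (s + e) // 2
        seeds.append((mid, mid + 30))
    join_order = [frag_iv[0], frag_iv[1], frag_iv[2]]
    truth = {"fragments": frag_iv, "join_order": join_order,
             "cores": cores, "original": seq}
    return genome, anchors, sorted(seeds), truth
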