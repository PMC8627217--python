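"""Alignment-free detection of exchanged sequence between elements.

For every query position the length of the longest exact substring match
anywhere in the subject (either strand) is computed via a suffix automaton
in linear time.  Windows whose mean match length is improbable under an
i.i.d.-subject null are called homologous segments; directed edges weighted
by additive segment length form the gene-flux network.  Chimaeric loci are
painted by windowed best-donor identity.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _st

from ._seq import complement, revcomp
from .model import HomologySegment, MatchProfile, RecombinationEdge


class _SuffixAutomaton:
    """Classic online suffix automaton over a text; supports matching
    statistics of a pattern streamed against it."""

    __slots__ = ("next", "link", "length", "last")

    def __init__(self, text: str):
        self.next: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self.last = 0
        for ch in text:
            self._extend(ch)

    def _extend(self, ch: str) -> None:
        nxt, link, length = self.next, self.link, self.length
        cur = len(nxt)
        nxt.append({})
        length.append(length[self.last] + 1)
        link.append(-1)
        p = self.last
        while p != -1 and ch not in nxt[p]:
            nxt[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nxt[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(nxt)
                nxt.append(dict(nxt[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and nxt[p].get(ch) == q:
                    nxt[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        self.last = cur

    def matching_statistics(self, pattern: str) -> np.ndarray:
        """ms[i] = length of the longest suffix of pattern[:i+1] occurring
        in the text."""
        out = np.zeros(len(pattern), dtype=np.int64)
        v, l = 0, 0
        nxt, link, length = self.next, self.link, self.length
        for i, ch in enumerate(pattern):
            while v != 0 and ch not in nxt[v]:
                v = link[v]
                l = length[v]
            if ch in nxt[v]:
                v = nxt[v][ch]
                l += 1
            else:
                v, l = 0, 0
            out[i] = l
        return out


def match_length_profile(query: str, subject: str,
                         query_id: str = "query",
                         subject_id: str = "subject") -> MatchProfile:
    """Longest-match length starting at each query position.

    Matches are sought anywhere in the subject or its reverse complement.
    Computed by streaming the reversed query through a suffix automaton of
    the reversed subject plus the complement strand (whose reversal is the
    reverse complement), giving per-start rather than per-end lengths.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    text = subject[::-1] + "#" + complement(subject)
    sam = _SuffixAutomaton(text)
    ms_end_rev = sam.matching_statistics(query[::-1])
    return MatchProfile(query_id, subject_id, ms_end_rev[::-1].copy())


def naive_match_length_profile(query: str, subject: str) -> np.ndarray:
    """O(n*m) reference scan used as the oracle on small inputs."""
    targets = (subject, revcomp(subject))
    n = len(query)
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        best = 0
        for t in targets:
            for j in range(len(t)):
                k = 0
                while i + k < n and j + k < len(t) and query[i + k] == t[j + k]:
                    k += 1
                if k > best:
                    best = k
        out[i] = best
    return out


# ---------------------------------------------------------------------------
# null model and segment calling

def _null_match_moments(subject_len: int, composition: np.ndarray,
                        max_l: int = 4096) -> tuple[float, float]:
    """Mean and variance of the per-position longest-match length against an
    i.i.d. sequence of the subject's length and composition (both strands).

    P(X >= L) ~ min(1, 2 m q^L) with q = sum p_b^2: the expected number of
    occurrences of a fixed L-word in 2m positions.
    """
    q = float(np.sum(composition ** 2))
    m2 = 2.0 * subject_len
    mean = 0.0
    ex2 = 0.0
    for L in range(1, max_l + 1):
        tail = min(1.0, m2 * q ** L)
        mean += tail
        ex2 += (2 * L - 1) * tail
        if tail < 1e-12:
            break
    var = max(ex2 - mean * mean, 1e-9)
    return mean, var


def _composition(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    counts = np.array([(arr == ord(b)).sum() for b in "ACGT"], dtype=float)
    total = counts.sum()
    return counts / total if total else np.full(4, 0.25)


def call_homologous_segments(profile: MatchProfile, subject: str,
                             window: int = 1000, alpha: float = 0.05,
                             null: str = "analytic",
                             n_permutations: int = 20,
                             seed: Optional[int] = None) -> list[HomologySegment]:
    """Windows whose mean match length is unexpectedly high, merged into
    maximal segments.

    analytic null: per-position match lengths treated as draws from the
    i.i.d. geometric-tail law; window means tested with a normal
    approximation whose effective sample size is window/(1+mean) because a
    single long match covers correlated positions.  permutation null:
    seeded dinucleotide-free shuffles of the subject re-profiled against
    the query.
    """
    lengths = np.asarray(profile.lengths)
    n = len(lengths)
    if window > n:
        import warnings
        warnings.warn("window longer than query; using one whole-query window")
        window = n
    starts = list(range(0, n - window + 1, window))
    if starts[-1] + window < n:
        starts.append(n - window)
    means = np.array([lengths[s:s + window].mean() for s in starts])
    if null == "permutation":
        raise ValueError("use call_homologous_segments_permutation for the "
                         "permutation null (it needs the query sequence)")
    if null != "analytic":
        raise ValueError(f"unknown null {null!r}")
    mu, var = _null_match_moments(len(subject), _composition(subject))
    n_eff = window / (1.0 + mu)
    z = (means - mu) / math.sqrt(var / n_eff)
    pvals = _st.norm.sf(z)
    segments = []
    cur = None
    for s, flag, p in zip(starts, pvals < alpha, pvals):
        if not flag:
            continue
        if cur is not None and s <= cur[1]:
            cur[1] = max(cur[1], s + window)
            cur[2].append(p)
        else:
            if cur is not None:
                segments.append(cur)
            cur = [s, s + window, [p]]
    if cur is not None:
        segments.append(cur)
    return [HomologySegment(s, e, float(np.mean(ps))) for s, e, ps in segments]


def call_homologous_segments_permutation(query: str, subject: str,
                                         window: int = 1000,
                                         alpha: float = 0.05,
                                         n_permutations: int = 20,
                                         seed: int = 0) -> list[HomologySegment]:
    """Permutation variant of the segment caller: the subject is shuffled
    (seeded), re-profiled, and window means compared empirically."""
    profile = match_length_profile(query, subject)
    lengths = np.asarray(profile.lengths)
    n = len(lengths)
    w = min(window, n)
    starts = list(range(0, n - w + 1, w))
    if starts[-1] + w < n:
        starts.append(n - w)
    obs = np.array([lengths[s:s + w].mean() for s in starts])
    rng = np.random.default_rng(seed)
    subj = np.frombuffer(subject.encode(), dtype=np.uint8)
    null_means = []
    for _ in range(n_permutations):
        perm = rng.permutation(subj)
        shuffled = perm.tobytes().decode()
        pl = np.asarray(match_length_profile(query, shuffled).lengths)
        null_means.extend(pl[s:s + w].mean() for s in starts)
    null_means = np.sort(np.array(null_means))
    segments = []
    cur = None
    for s, m in zip(starts, obs):
        ge = len(null_means) - np.searchsorted(null_means, m, side="left")
        p = (1 + ge) / (1 + len(null_means))
        if p < alpha:
            if cur is None:
                cur = [s, s + w, [p]]
            elif s <= cur[1]:
                cur[1] = max(cur[1], s + w)
                cur[2].append(p)
            else:
                segments.append(cur)
                cur = [s, s + w, [p]]
    if cur is not None:
        segments.append(cur)
    return [HomologySegment(s, e, float(np.mean(ps))) for s, e, ps in segments]


# ---------------------------------------------------------------------------
# network

def build_network(sequences: dict[str, str], window: int = 1000,
                  alpha: float = 0.05,
                  mask: Optional[dict[str, list[tuple[int, int]]]] = None,
                  mask_mode: str = "exclude") -> list[RecombinationEdge]:
    """Directed edge for every ordered pair with >=1 homologous segment.

    ``mask`` gives per-query intervals (e.g. backbone gene regions);
    ``mask_mode`` 'exclude' removes windows overlapping them (the cargo-only
    contrast), 'restrict' keeps only those windows.
    """
    ids = sorted(sequences)
    automata = {}
    edges: list[RecombinationEdge] = []
    for sid in ids:
        subj = sequences[sid]
        text = subj[::-1] + "#" + complement(subj)
        automata[sid] = _SuffixAutomaton(text)
    for qid in ids:
        query = sequences[qid]
        qmask = (mask or {}).get(qid, [])
        for sid in ids:
            if sid == qid:
                continue
            ms = automata[sid].matching_statistics(query[::-1])[::-1].copy()
            profile = MatchProfile(qid, sid, ms)
            segs = call_homologous_segments(profile, sequences[sid],
                                            window=window, alpha=alpha)
            if qmask:
                segs = _apply_mask(segs, qmask, mask_mode, window)
            if not segs:
                continue
            add = sum(s.additive_length for s in segs)
            edges.append(RecombinationEdge(qid, sid, add,
                                           add / len(query), segs))
    return edges


def _apply_mask(segments, intervals, mode, window):
    out = []
    for seg in segments:
        pieces = [(seg.start, seg.end)]
        if mode == "exclude":
            for ms, me in sorted(intervals):
                nxt = []
                for s, e in pieces:
                    if me <= s or ms >= e:
                        nxt.append((s, e))
                        continue
                    if s < ms:
                        nxt.append((s, ms))
                    if me < e:
                        nxt.append((me, e))
                pieces = nxt
        else:  # restrict
            nxt = []
            for ms, me in sorted(intervals):
                for s, e in pieces:
                    lo, hi = max(s, ms), min(e, me)
                    if hi > lo:
                        nxt.append((lo, hi))
            pieces = nxt
        for s, e in pieces:
            if e - s >= window // 2:
                out.append(HomologySegment(s, e, seg.mean_window_p))
    return out


def network_to_sif(edges: Sequence[RecombinationEdge], path) -> None:
    with open(path, "w") as fh:
        for e in sorted(edges, key=lambda e: (e.query_id, e.subject_id)):
            fh.write(f"{e.query_id}\thomologous_to\t{e.subject_id}\n")


# ---------------------------------------------------------------------------
# chimaera painting

def chimaera_painting(query: str, donors: dict[str, str], window: int = 1000,
                      step: int = 500, min_identity: float = 60.0) -> list[dict]:
    """Tile the query and label each region with its highest-identity donor.

    Ties are broken lexicographically and flagged.  Returns merged regions
    [{start, end, donor, identity, tie}]; breakpoints are region borders.
    """
    import edlib
    if len(donors) < 2:
        raise ValueError("need >=2 donors")
    names = sorted(donors)
    assignments = []
    for s in range(0, max(1, len(query) - window + 1), step):
        w = query[s:s + window]
        best = None
        tie = False
        for name in names:
            res = edlib.align(w, donors[name], mode="HW", task="distance")
            d = res["editDistance"]
            if d < 0:
                continue
            ident = 100.0 * (len(w) - d) / len(w)
            if best is None or ident > best[1]:
                best, tie = (name, ident), False
            elif ident == best[1]:
                tie = True
        if best and best[1] >= min_identity:
            assignments.append((s, min(s + window, len(query)), best[0],
                                best[1], tie))
    regions = []
    for s, e, donor, ident, tie in assignments:
        if regions and regions[-1]["donor"] == donor and s <= regions[-1]["end"]:
            regions[-1]["end"] = e
            regions[-1]["identity"] = max(regions[-1]["identity"], ident)
            regions[-1]["tie"] |= tie
        else:
            regions.append({"start": s, "end": e, "donor": donor,
                            "identity": ident, "tie": tie})
    return regions
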