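"""Ortholog clustering, backbone rule, mobilome accounting, NJ trees,
ANI/genospecies and Fisher association."""

import io
import math

import numpy as np
import pandas as pd
import pytest

import oracles
from icemob._seq import mutate_protein, random_protein
from icemob.model import ANIResult
from icemob.pangenome import (account_mobilome, associate_trait,
                              cluster_orthologs, compute_ani,
                              gene_content_distance, gene_content_tree,
                              identify_backbone, nj_tree_from_distances,
                              partition_genospecies, presence_absence,
                              sweep_core_size, write_nexus_distances)
from icemob.simulate import simulate_diverged_pair


def test_identical_proteins_one_cluster(rng):
    p = random_protein(rng, 80)
    cs = cluster_orthologs({"u1": {"a": p}, "u2": {"b": p}}, 40.0)
    assert sorted(cs.clusters.values()) == [["a", "b"]]


def test_threshold_splits_and_merges_families(rng):
    """A star family at ~30% identity to its base splits at a 40% threshold
    and merges at 25%; results match a naive all-vs-all single-linkage
    oracle."""
    units = {}
    bases = []
    for fam in range(3):
        base = random_protein(rng, 150)
        bases.append(base)
        units[f"u{fam}_0"] = {f"f{fam}_base": base}
        for v in range(2):
            units[f"u{fam}_{v + 1}"] = {
                f"f{fam}_v{v}": mutate_protein(base, 0.70, rng)}
    for threshold, expect_merged in ((40.0, False), (25.0, True)):
        cs = cluster_orthologs(units, threshold)
        fam_sizes = sorted(len(m) for m in cs.clusters.values())
        if expect_merged:
            assert fam_sizes == [3, 3, 3]
        else:
            assert fam_sizes == [1] * 9
        # oracle: naive single linkage over align_pair identities
        from icemob.homology import align_pair
        loci = {l: s for u in units.values() for l, s in u.items()}
        ids = sorted(loci)
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                r = align_pair(loci[a], loci[b], "protein")
                if r and r[0] >= threshold and min(r[1], r[2]) >= 0.5:
                    parent[find(b)] = find(a)
        oracle_groups = {}
        for i in ids:
            oracle_groups.setdefault(find(i), []).append(i)
        assert sorted(map(sorted, oracle_groups.values())) == \
            sorted(cs.clusters.values())


def test_order_invariance(rng):
    base = random_protein(rng, 100)
    units = {"a": {"x1": base}, "b": {"x2": mutate_protein(base, 0.1, rng)},
             "c": {"x3": mutate_protein(base, 0.1, rng)}}
    cs1 = cluster_orthologs(units, 40.0)
    cs2 = cluster_orthologs(dict(reversed(list(units.items()))), 40.0)
    assert cs1.clusters == cs2.clusters


def test_core_sweep_plateau_and_monotonicity(rng):
    """Core families at ~10% pairwise divergence persist until the
    threshold crosses their identity, and core size never grows with the
    threshold."""
    n_units, n_core = 4, 8
    units = {f"g{i}": {} for i in range(n_units)}
    for fam in range(n_core):
        base = random_protein(rng, 120)
        for i in range(n_units):
            units[f"g{i}"][f"c{fam}_{i}"] = mutate_protein(base, 0.15, rng)
    for i in range(n_units):
        for k in range(3):
            units[f"g{i}"][f"acc{i}_{k}"] = random_protein(rng, 120)
    # members are ~70-75% identical pairwise: the core count plateaus below
    # that and collapses once the threshold crosses the planted divergence.
    # Monotonicity is asserted above the very permissive zone where spurious
    # local-alignment links can merge unrelated families.
    table = sweep_core_size(units, thresholds=range(30, 100, 10))
    core = list(table["core_clusters"])
    assert all(a >= b for a, b in zip(core, core[1:]))  # monotone
    assert core[0] == n_core and core[1] == n_core and core[2] == n_core
    assert core[-1] == 0


def test_identical_units_core_constant(rng):
    prots = {f"p{i}": random_protein(rng, 90) for i in range(5)}
    units = {u: {f"{u}_{k}": v for k, v in prots.items()} for u in ("a", "b")}
    table = sweep_core_size(units, thresholds=(20, 50, 95))
    assert list(table["core_clusters"]) == [5, 5, 5]


def test_backbone_prevalence_rule():
    mat = pd.DataFrame(1, index=[f"c{i}" for i in range(5)],
                       columns=[f"e{j}" for j in range(20)])
    mat.loc["c1", "e0"] = 0  # 19/20 = 0.95: still backbone
    mat.loc["c2", ["e0", "e1"]] = 0  # 18/20: not
    bb = identify_backbone(mat, 0.95)
    assert bb.cluster_ids == ["c0", "c1", "c3", "c4"]
    # backbone shrinks as the threshold rises
    bb2 = identify_backbone(mat, 1.0)
    assert set(bb2.cluster_ids) <= set(bb.cluster_ids)
    with pytest.raises(ValueError):
        identify_backbone(mat[["e0"]], 0.95)


def test_mobilome_accounting():
    from icemob.model import OrthologClusterSet
    cs = OrthologClusterSet({"c1": ["a", "b"], "c2": ["c"], "c3": ["d"],
                             "c4": ["e"]}, 25.0)
    loc = {"a": "ICESym", "b": "chromosome", "c": "plasmid", "d": "chromosome",
           "e": "IME"}
    acc = account_mobilome(cs, loc)
    assert acc.n_clusters == 4 and acc.n_mge_clusters == 3
    assert acc.mge_fraction == pytest.approx(0.75)
    assert sum(acc.category_share.values()) == pytest.approx(1.0)
    assert acc.icesym_share_of_ice == pytest.approx(1.0)
    empty = account_mobilome(cs, {})
    assert empty.mge_fraction == 0.0


def _splits_of_tree(newick, taxa):
    from skbio import TreeNode
    t = TreeNode.read(io.StringIO(newick))
    out = set()
    for node in t.non_tips(include_self=False):
        names = frozenset(x.name for x in node.tips())
        if 1 < len(names) < len(taxa) - 1:
            out.add(names)
    return out


@pytest.mark.parametrize("n_taxa", [4, 5])
def test_nj_recovers_additive_tree(n_taxa):
    """NJ reconstructs the generating topology from additive distances."""
    if n_taxa == 4:
        # ((A,B),(C,D)) with distinct branch lengths
        d = {("A", "B"): 3, ("A", "C"): 9, ("A", "D"): 10,
             ("B", "C"): 10, ("B", "D"): 11, ("C", "D"): 5}
        want = {frozenset({"A", "B"}), frozenset({"C", "D"})}
    else:
        # ((A,B),C,(D,E)) caterpillar
        d = {("A", "B"): 2, ("A", "C"): 7, ("A", "D"): 12, ("A", "E"): 13,
             ("B", "C"): 7, ("B", "D"): 12, ("B", "E"): 13,
             ("C", "D"): 9, ("C", "E"): 10, ("D", "E"): 5}
        want = {frozenset({"A", "B"}), frozenset({"D", "E"})}
    taxa = sorted({x for p in d for x in p})
    mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for (a, b), v in d.items():
        mat.loc[a, b] = mat.loc[b, a] = float(v)
    nwk = nj_tree_from_distances(mat)
    splits = _splits_of_tree(nwk, taxa)
    comp = {frozenset(set(taxa) - s) for s in splits}
    assert want <= (splits | comp)


def test_gene_content_tree_separates_lineages(rng):
    """Two planted cargo lineages are separated by the NJ bipartitions."""
    clusters = [f"c{i}" for i in range(40)]
    cols = {}
    for i in range(3):  # lineage 1: clusters 0-19 (+noise)
        v = np.zeros(40, int)
        v[:20] = 1
        v[rng.integers(0, 40)] ^= 1
        cols[f"L1_{i}"] = v
    for i in range(3):
        v = np.zeros(40, int)
        v[20:] = 1
        v[rng.integers(0, 40)] ^= 1
        cols[f"L2_{i}"] = v
    mat = pd.DataFrame(cols, index=clusters)
    assert gene_content_distance(mat).loc["L1_0", "L1_0"] == 0
    nwk = gene_content_tree(mat)
    splits = _splits_of_tree(nwk, list(cols))
    full = {frozenset({"L1_0", "L1_1", "L1_2"}),
            frozenset({"L2_0", "L2_1", "L2_2"})}
    comp = {frozenset(set(cols) - s) for s in splits}
    assert full & (splits | comp)


def test_nexus_distance_export(tmp_path):
    mat = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["a", "b"],
                       columns=["a", "b"])
    p = tmp_path / "d.nex"
    write_nexus_distances(mat, p)
    text = p.read_text()
    assert text.startswith("#NEXUS")
    assert "BEGIN DISTANCES;" in text and "NTAX=2" in text


def test_fisher_matches_hypergeometric_oracle():
    """Two-sided Fisher p through associate_trait equals exhaustive
    hypergeometric enumeration for every 2x2 table with margins <= 12."""
    checked = 0
    for n_pos in range(1, 13):
        for n_neg in range(1, 13):
            rows, expected = {}, {}
            for a in range(0, n_pos + 1):
                for b in range(0, n_neg + 1):
                    if a + b > 12 or (n_pos - a) + (n_neg - b) > 12:
                        continue
                    cid = f"t{a}_{b}"
                    rows[cid] = [1] * a + [0] * (n_pos - a) + \
                        [1] * b + [0] * (n_neg - b)
                    expected[cid] = oracles.fisher_p_oracle(
                        a, b, n_pos - a, n_neg - b)
            if not rows:
                continue
            cols = [f"p{i}" for i in range(n_pos)] + \
                [f"n{i}" for i in range(n_neg)]
            mat = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
            trait = {c: c.startswith("p") for c in cols}
            res = associate_trait(mat, trait, alpha=0.05)
            for r in res:
                assert r.p_value == pytest.approx(expected[r.cluster_id],
                                                  rel=1e-7, abs=1e-12)
                checked += 1
    assert checked > 5000


def test_fisher_degenerate_and_extremes():
    mat = pd.DataFrame({"u1": [1], "u2": [1], "u3": [1], "u4": [1]},
                       index=["c"])
    trait = {"u1": True, "u2": True, "u3": False, "u4": False}
    (r,) = associate_trait(mat, trait)
    assert r.p_value == pytest.approx(1.0)
    assert not r.significant
    with pytest.raises(ValueError):
        associate_trait(mat, {u: True for u in mat.columns})


def test_perfect_separation_significant():
    """Present in all 10 trait-positives, absent from all 10 negatives:
    p = 2/C(20,10) two-sided, significant after Bonferroni over one test."""
    cols = [f"p{i}" for i in range(10)] + [f"n{i}" for i in range(10)]
    mat = pd.DataFrame([[1] * 10 + [0] * 10], index=["c"], columns=cols)
    trait = {c: c.startswith("p") for c in cols}
    (r,) = associate_trait(mat, trait)
    assert r.p_value == pytest.approx(oracles.fisher_p_oracle(10, 0, 0, 10))
    assert r.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-6)
    assert r.significant


def test_permuted_trait_pvalues_dominate_uniform(rng):
    """Under label permutation the p-value CDF never exceeds the uniform
    CDF by more than the discreteness allows."""
    cols = [f"u{i}" for i in range(12)]
    presence = rng.integers(0, 2, size=12)
    while presence.sum() in (0, 12):
        presence = rng.integers(0, 2, size=12)
    mat = pd.DataFrame([presence], index=["c"], columns=cols)
    pvals = []
    for _ in range(300):
        labels = np.array([True] * 6 + [False] * 6)
        rng.shuffle(labels)
        trait = dict(zip(cols, labels))
        (r,) = associate_trait(mat, trait)
        pvals.append(r.p_value)
    pvals = np.sort(pvals)
    for alpha in (0.01, 0.05, 0.10, 0.25):
        frac = np.mean(pvals <= alpha)
        assert frac <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / 300)


def test_ani_identical_and_diverged(rng):
    a, b = simulate_diverged_pair(60_000, 0.03, seed=11)
    r = compute_ani(a, a, ids=("x", "x2"))
    assert r.ani == pytest.approx(100.0)
    r2 = compute_ani(a, b, ids=("x", "y"))
    assert 95.5 <= r2.ani <= 98.5
    assert abs(compute_ani(b, a).ani - r2.ani) <= 0.5  # symmetry
    with pytest.raises(ValueError):
        compute_ani("ACGT" * 100, a)


def test_genospecies_cutoff_semantics():
    """ANI exactly 95.0 groups genomes into one genospecies; below does
    not; single linkage chains components."""
    res = [ANIResult("a", "b", 95.0, 50), ANIResult("b", "c", 94.9, 50),
           ANIResult("a", "c", 80.0, 50), ANIResult("d", "a", float("nan"), 0)]
    parts = partition_genospecies(res, cutoff=95.0)
    assert parts == [["a", "b"], ["c"], ["d"]]
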