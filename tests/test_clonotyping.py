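"""Clonal grouping: partition keys, junction distances, single-linkage clusters.

The clustering implementation is checked against an independent brute-force
oracle: build the full pairwise compatibility/distance graph and take
connected components (scipy.sparse.csgraph).
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from igtrace import clonotyping as ct
from igtrace.errors import InputError

from conftest import make_chain


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _compatible(a, b):
    return (
        len(a.junction_nt) == len(b.junction_nt)
        and bool(ct.strip_allele(a.v_call) & ct.strip_allele(b.v_call))
        and bool(ct.strip_allele(a.j_call) & ct.strip_allele(b.j_call))
    )


def oracle_partition(chains, threshold=0.2, weights=ct.UNIFORM_WEIGHTS):
    """All-pairs key graph -> components; distance graph within -> clones."""
    n = len(chains)
    key = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        key[i, j] = key[j, i] = _compatible(chains[i], chains[j])
    _, key_comp = connected_components(csr_matrix(key), directed=False)
    adj = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        if key_comp[i] == key_comp[j]:
            d = ct.junction_distance(
                chains[i].junction_nt, chains[j].junction_nt, weights
            )
            adj[i, j] = adj[j, i] = d < threshold
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(chains[i].cell_id)
    return frozenset(frozenset(g) for g in groups.values())


def clone_sets(assignment):
    return frozenset(frozenset(m) for m in assignment.members.values())


def random_instance(rng, n_max=15):
    v_pool = ["IGHV1-2*02", "IGHV1-2*04", "IGHV1-3*01",
              "IGHV1-2*02,IGHV1-3*01", "IGHV2-5*01"]
    j_pool = ["IGHJ4*01", "IGHJ4*02", "IGHJ6*01", "IGHJ4*01,IGHJ6*01"]
    n = int(rng.integers(2, n_max + 1))
    founders = ["".join(rng.choice(list("ACGT"), size=L))
                for L in (9, 12) for _ in range(2)]
    chains = []
    for i in range(n):
        base = list(founders[int(rng.integers(0, len(founders)))])
        for _ in range(int(rng.integers(0, 3))):
            p = int(rng.integers(0, len(base)))
            base[p] = "ACGT"[int(rng.integers(0, 4))]
        chains.append(
            make_chain(
                f"C{i:02d}", "".join(base),
                v_call=v_pool[int(rng.integers(0, len(v_pool)))],
                j_call=j_pool[int(rng.integers(0, len(j_pool)))],
            )
        )
    return chains


# ---------------------------------------------------------------------------
# partition_by_vj_len
# ---------------------------------------------------------------------------

class TestPartition:
    def test_allele_stripping_merges_allelic_variants(self):
        a = make_chain("A", "TGTGCTTGG", v_call="IGHV1-2*02")
        b = make_chain("B", "TGTGCATGG", v_call="IGHV1-2*04")
        parts = ct.partition_by_vj_len([a, b])
        assert len(parts) == 1

    def test_different_junction_lengths_split(self):
        a = make_chain("A", "TGTGCTTGG")
        b = make_chain("B", "TGTGCTGCTTGG")
        assert len(ct.partition_by_vj_len([a, b])) == 2

    def test_comma_separated_calls_join_via_set_intersection(self):
        a = make_chain("A", "TGTGCTTGG", v_call="IGHV1-2*02,IGHV1-3*01")
        b = make_chain("B", "TGTGCATGG", v_call="IGHV1-3*01")
        c = make_chain("C", "TGTGGGTGG", v_call="IGHV1-2*02")
        parts = ct.partition_by_vj_len([a, b, c])
        # transitive: B~A via IGHV1-3, C~A via IGHV1-2
        assert len(parts) == 1

    def test_light_chains_rejected(self):
        with pytest.raises(InputError):
            ct.partition_by_vj_len([make_chain("A", "TGTGCTTTC", locus="IGK")])


# ---------------------------------------------------------------------------
# junction_distance
# ---------------------------------------------------------------------------

class TestJunctionDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("ACGTACGTACGT", "ACGTACGTACGA", 1 / 12),
        ],
    )
    def test_uniform_distances(self, a, b, expected):
        assert ct.junction_distance(a, b) == pytest.approx(expected)

    def test_targeting_weight_scales_the_mismatch(self):
        # mismatch at position 3; both 5-mer contexts weighted 0.5
        w = ct.MismatchWeights(
            mode="targeting", table={"CGTNN": 0.5, "CGANN": 0.5}
        )
        assert ct.junction_distance("ACGT", "ACGA", w) == pytest.approx(0.125)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError):
            ct.junction_distance("ACGT", "ACG")

    @given(
        st.integers(1, 30).flatmap(
            lambda n: st.tuples(
                *[st.text("ACGT", min_size=n, max_size=n) for _ in range(3)]
            )
        )
    )
    def test_uniform_distance_is_a_metric(self, seqs):
        a, b, c = seqs
        dab = ct.junction_distance(a, b)
        assert dab == ct.junction_distance(b, a)
        assert (dab == 0) == (a == b)
        assert dab <= ct.junction_distance(a, c) + ct.junction_distance(c, b) + 1e-12


# ---------------------------------------------------------------------------
# cluster_clones
# ---------------------------------------------------------------------------

def _with_mismatches(base, positions, alt="A"):
    s = list(base)
    for p in positions:
        s[p] = "C" if s[p] == alt else alt
    return "".join(s)


class TestClusterClones:
    def test_single_linkage_chains_through_intermediate(self):
        base = "G" * 50
        a = make_chain("A", _with_mismatches(base, range(0, 5)))        # d(A,B)=0.10
        b = make_chain("B", base)
        c = make_chain("C", _with_mismatches(base, range(5, 10)))       # d(B,C)=0.10
        dac = ct.junction_distance(a.junction_nt, c.junction_nt)
        assert dac == pytest.approx(0.2)  # not directly linkable (strict <)
        clusters = ct.cluster_clones([a, b, c])
        assert len(clusters) == 1  # joined through B

    def test_identical_junctions_one_clone(self):
        a, b = make_chain("A", "TGTGCTTGG"), make_chain("B", "TGTGCTTGG")
        assert len(ct.cluster_clones([a, b])) == 1

    def test_all_distant_pairs_stay_singletons(self):
        base = "G" * 10
        chains = [
            make_chain("A", base),
            make_chain("B", _with_mismatches(base, range(0, 2))),  # d=0.2 exactly
            make_chain("C", _with_mismatches(base, range(4, 8))),
        ]
        assert len(ct.cluster_clones(chains)) == 3

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            chains = random_instance(rng)
            got = clone_sets(ct.assign_heavy_clones(chains))
            assert got == oracle_partition(chains)

    def test_partition_is_permutation_invariant(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            chains = random_instance(rng)
            ref = clone_sets(ct.assign_heavy_clones(chains))
            shuffled = list(chains)
            rng.shuffle(shuffled)
            assert clone_sets(ct.assign_heavy_clones(shuffled)) == ref

    def test_raising_threshold_never_splits_a_clone(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            chains = random_instance(rng)
            lo = ct.assign_heavy_clones(chains, threshold=0.15)
            hi = ct.assign_heavy_clones(chains, threshold=0.3)
            hi_clone = hi.cell_to_clone
            for members in lo.members.values():
                assert len({hi_clone[c] for c in members}) == 1


# ---------------------------------------------------------------------------
# refine_by_light_chain / collapse
# ---------------------------------------------------------------------------

def _heavy_clone(cells):
    chains = [make_chain(c, "TGTGCTTGG") for c in cells]
    return ct.assign_heavy_clones(chains)


class TestRefineByLightChain:
    def test_identical_light_chains_leave_assignment_unchanged(self):
        asg = _heavy_clone(["A", "B", "C"])
        lights = [
            make_chain(c, "TGTCACTTC", locus="IGK", v_call="IGKV1-5*01",
                       j_call="IGKJ1*01")
            for c in "ABC"
        ]
        refined = ct.refine_by_light_chain(asg, lights)
        assert clone_sets(refined) == clone_sets(asg)

    def test_different_light_loci_split_the_clone(self):
        asg = _heavy_clone(["A", "B"])
        lights = [
            make_chain("A", "TGTCACTTC", locus="IGK", v_call="IGKV1-5*01",
                       j_call="IGKJ1*01"),
            make_chain("B", "TGTCACTTC", locus="IGL", v_call="IGLV2-8*01",
                       j_call="IGLJ2*01"),
        ]
        refined = ct.refine_by_light_chain(asg, lights)
        assert len(refined.members) == 2

    def test_close_light_distances_do_not_split(self):
        base = "T" * 100
        asg = _heavy_clone(["A", "B", "C"])
        lights = [
            make_chain("A", base, locus="IGK", v_call="IGKV1-5*01",
                       j_call="IGKJ1*01"),
            make_chain("B", _with_mismatches(base, range(5)), locus="IGK",
                       v_call="IGKV1-5*01", j_call="IGKJ1*01"),      # d=0.05
            make_chain("C", _with_mismatches(base, range(5, 14)), locus="IGK",
                       v_call="IGKV1-5*01", j_call="IGKJ1*01"),      # d(A,C)=0.09
        ]
        refined = ct.refine_by_light_chain(asg, lights)
        assert len(refined.members) == 1

    def test_cell_without_light_joins_largest_subclone(self):
        asg = _heavy_clone(["A", "B", "C"])
        lights = [
            make_chain("A", "TGTCACTTC", locus="IGK", v_call="IGKV1-5*01",
                       j_call="IGKJ1*01"),
            make_chain("B", "TGTCACTTC", locus="IGK", v_call="IGKV1-5*01",
                       j_call="IGKJ1*01"),
        ]
        refined = ct.refine_by_light_chain(asg, lights)
        assert len(refined.members) == 1  # C stays with {A, B}


class TestCollapseClonotypes:
    def test_expanded_flag_tracks_member_count(self):
        asg = _heavy_clone(["A", "B", "C", "D", "E"])
        (ctype,) = ct.collapse_clonotypes(asg)
        assert ctype.expanded and not ctype.singleton

    def test_clone_size_profile(self):
        # clones of sizes {4, 3, 1, 1, 1} -> 5 clonotypes, 2 expanded
        members = {
            "c0": ["A1", "A2", "A3", "A4"],
            "c1": ["B1", "B2", "B3"],
            "c2": ["D1"],
            "c3": ["D2"],
            "c4": ["D3"],
        }
        asg = ct.CloneAssignment(
            "P1",
            {cell: cid for cid, cells in members.items() for cell in cells},
            members,
        )
        clonotypes = ct.collapse_clonotypes(asg)
        assert len(clonotypes) == 5
        assert sum(c.expanded for c in clonotypes) == 2
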