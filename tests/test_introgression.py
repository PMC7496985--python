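"""Distances, neighbor joining, f3, and the window scan / event calling."""

import numpy as np
import pytest

from introscan.introgression import (
    CALL_BIDIRECTIONAL,
    CALL_NONE,
    DistanceMatrix,
    IntrogressionLocus,
    WindowScanResult,
    allele_sharing_distance,
    call_events,
    call_loci,
    carrier_matrix,
    f3_statistic,
    nj_tree,
    patristic_distances,
    window_scan,
)
from introscan.model import MISSING, SampleInfo, Window
from introscan.sim import (
    A_TO_B,
    B_TO_A,
    PlantedSegment,
    simulate_panel,
    tiny_config,
)

from conftest import make_gm


class TestAlleleSharingDistance:
    def test_identical_rows_have_zero_distance(self):
        gm = make_gm([[0, 1, 2]] * 3, ["Gh"] * 3)
        dm = allele_sharing_distance(gm)
        assert np.allclose(dm.d, 0.0)

    def test_opposite_homozygotes_have_distance_one(self):
        gm = make_gm([[0] * 5, [2] * 5, [1] * 5], ["Gh"] * 3)
        dm = allele_sharing_distance(gm)
        assert dm.d[0, 1] == pytest.approx(1.0)
        assert dm.d[0, 2] == pytest.approx(0.5)

    def test_matches_scalar_loop(self, rng):
        calls = rng.integers(-1, 3, size=(8, 30)).astype(np.int8)
        gm = make_gm(calls, ["Gh"] * 8)
        dm = allele_sharing_distance(gm)
        for i in range(8):
            for j in range(8):
                num = den = 0
                for a, b in zip(calls[i], calls[j]):
                    if a >= 0 and b >= 0:
                        num += abs(int(a) - int(b))
                        den += 1
                assert dm.d[i, j] == pytest.approx(num / (2 * den), abs=1e-12)

    def test_no_shared_sites_is_error(self):
        calls = [[0, MISSING], [MISSING, 2], [0, 2]]
        gm = make_gm(calls, ["Gh"] * 3)
        with pytest.raises(ValueError, match="no shared called sites"):
            allele_sharing_distance(gm)


def make_additive_matrix(rng, n_taxa):
    """Leaf-to-leaf path lengths of a random binary tree with positive
    branch lengths, built by explicit path sums (independent of NJ)."""
    D = np.zeros((n_taxa, n_taxa))
    nodes = [{"leaves": {i}, "dist": {i: 0.0}} for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.1, 2.0, 2)
        for x in a["leaves"]:
            for y in b["leaves"]:
                d = a["dist"][x] + la + lb + b["dist"][y]
                D[x, y] = D[y, x] = d
        merged = {
            "leaves": a["leaves"] | b["leaves"],
            "dist": {
                **{k: v + la for k, v in a["dist"].items()},
                **{k: v + lb for k, v in b["dist"].items()},
            },
        }
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return D


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0.0]]),
        )
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_additive_four_taxon_recovered_exactly(self):
        # tree ((A:1,B:2):0.5,C:1.5,D:2.5) -> pairwise path lengths
        d = {
            ("A", "B"): 3.0, ("A", "C"): 3.0, ("A", "D"): 4.0,
            ("B", "C"): 4.0, ("B", "D"): 5.0, ("C", "D"): 4.0,
        }
        labels = ["A", "B", "C", "D"]
        M = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            M[i, j] = M[j, i] = v
        tree = nj_tree(DistanceMatrix(labels, M))
        pat = patristic_distances(tree)
        for (x, y), v in d.items():
            i, j = pat.labels.index(x), pat.labels.index(y)
            assert pat.d[i, j] == pytest.approx(v, abs=1e-9)

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            M = make_additive_matrix(rng, n)
            labels = [f"t{i}" for i in range(n)]
            tree = nj_tree(DistanceMatrix(labels, M))
            pat = patristic_distances(tree)
            order = [pat.labels.index(l) for l in labels]
            assert np.allclose(pat.d[np.ix_(order, order)], M, atol=1e-9)

    def test_topology_agrees_with_skbio_reference(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        for _ in range(10):
            n = int(rng.integers(5, 8))
            M = make_additive_matrix(rng, n)
            M += rng.uniform(0, 0.01, M.shape)  # slight non-additive noise
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            labels = [f"t{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(labels, M))
            ref = sk_nj(SkDM(M, labels))
            rf = mine.compare_rfd(ref)
            assert rf == 0.0

    def test_invalid_matrices_rejected(self):
        bad = DistanceMatrix(["a", "b", "c"], np.array([[0, 1.0, 2], [1, 0, 3], [2, 3.0, 0.1]]))
        with pytest.raises(ValueError):
            nj_tree(bad)
        asym = DistanceMatrix(["a", "b", "c"], np.array([[0, 1.0, 2], [4, 0, 3], [2, 3.0, 0]]))
        with pytest.raises(ValueError):
            nj_tree(asym)


def f3_scalar_oracle(gm, target, s1, s2, block_size, correction=True):
    """Naive per-site loop + explicit leave-one-block-out jackknife."""
    def freq_and_called(group):
        idx = gm.group_indices(group)
        out = []
        for j in range(gm.n_sites):
            col = [int(c) for c in gm.calls[idx, j] if c >= 0]
            out.append((sum(col) / (2 * len(col)) if col else None, 2 * len(col)))
        return out

    fc = {g: freq_and_called(g) for g in (target, s1, s2)}
    terms, blocks = [], []
    for j in range(gm.n_sites):
        if any(fc[g][j][1] < 4 for g in (target, s1, s2)):
            continue
        c, nc = fc[target][j]
        a, _ = fc[s1][j]
        b, _ = fc[s2][j]
        t = (c - a) * (c - b)
        if correction:
            t -= c * (1 - c) / (nc - 1)
        terms.append(t)
        blocks.append((gm.chrom[j], (gm.pos[j] - 1) // block_size))
    n = len(terms)
    theta = sum(terms) / n
    uniq = list(dict.fromkeys(blocks))
    g = len(uniq)
    theta_del, m = [], []
    for u in uniq:
        keep = [t for t, b in zip(terms, blocks) if b != u]
        m_j = n - len(keep)
        theta_del.append(sum(keep) / len(keep))
        m.append(m_j)
    theta_j = g * theta - sum(
        (1 - mj / n) * td for mj, td in zip(m, theta_del)
    )
    var = 0.0
    for mj, td in zip(m, theta_del):
        h = n / mj
        tau = h * theta - (h - 1) * td
        var += (tau - theta_j) ** 2 / (h - 1)
    var /= g
    return theta, var**0.5


class TestF3:
    def test_zero_when_target_equals_source1(self, rng):
        half = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        other = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        calls = np.vstack([half, half, other])
        gm = make_gm(
            calls, ["T"] * 6 + ["S1"] * 6 + ["S2"] * 6,
            chrom=["c1"] * 20 + ["c2"] * 20,
            pos=list(range(1, 21)) * 2,
        )
        r = f3_statistic(gm, "T", "S1", "S2", block_size_bp=10, correction=False)
        assert r.f3 == pytest.approx(0.0, abs=1e-15)

    def test_midpoint_identity_minus_quarter(self):
        # a=1, b=0, c=0.5 with correction off -> term -(a-b)^2/4 = -0.25
        calls = np.array(
            [[1, 1], [1, 1], [2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int8
        )
        gm = make_gm(
            calls, ["T"] * 2 + ["S1"] * 2 + ["S2"] * 2,
            chrom=["c1", "c2"], pos=[1, 1],
        )
        r = f3_statistic(gm, "T", "S1", "S2", block_size_bp=10, correction=False)
        assert r.f3 == pytest.approx(-0.25, abs=1e-15)

    def test_matches_scalar_jackknife_oracle(self, rng):
        calls = rng.integers(-1, 3, size=(18, 120)).astype(np.int8)
        gm = make_gm(
            calls, ["T"] * 6 + ["S1"] * 6 + ["S2"] * 6,
            chrom=["c1"] * 60 + ["c2"] * 60,
            pos=list(range(1, 61)) * 2,
        )
        r = f3_statistic(gm, "T", "S1", "S2", block_size_bp=12)
        theta, se = f3_scalar_oracle(gm, "T", "S1", "S2", 12)
        assert r.f3 == pytest.approx(theta, abs=1e-12)
        assert r.se == pytest.approx(se, abs=1e-12)
        assert r.z == pytest.approx(theta / se, abs=1e-9)

    def test_requires_two_blocks(self, rng):
        calls = rng.integers(0, 3, size=(9, 5)).astype(np.int8)
        gm = make_gm(calls, ["T"] * 3 + ["S1"] * 3 + ["S2"] * 3)
        with pytest.raises(ValueError, match="blocks"):
            f3_statistic(gm, "T", "S1", "S2", block_size_bp=10**9)


@pytest.fixture(scope="module")
def tiny_panel():
    return simulate_panel(tiny_config(2))


class TestWindowScan:
    def test_planted_carriers_found_exactly(self, tiny_panel):
        gm, truth = tiny_panel
        scan = window_scan(gm, "Gh", "Gb")
        by_window = {(r.window.chrom, r.window.start): r for r in scan}
        a2b = by_window[("A01", 0)]
        b2a = by_window[("D01", 0)]
        assert a2b.call == A_TO_B
        assert set(a2b.intruders_into_b) == set(truth.segments[0].carriers)
        assert b2a.call == B_TO_A
        assert set(b2a.intruders_into_a) == set(truth.segments[1].carriers)

    def test_clean_windows_called_none(self, tiny_panel):
        gm, _ = tiny_panel
        scan = window_scan(gm, "Gh", "Gb")
        clean = [r for r in scan if r.window.start == 1_000_000]
        assert clean and all(r.call == CALL_NONE for r in clean)
        assert all(not r.intruders_into_a and not r.intruders_into_b for r in clean)

    def test_min_fixed_gate_blocks_calls(self, tiny_panel):
        gm, _ = tiny_panel
        scan = window_scan(gm, "Gh", "Gb", min_fixed=10**6)
        assert all(not r.assessable and r.call == CALL_NONE for r in scan)

    def test_polarity_flip_invariance(self, tiny_panel):
        gm, _ = tiny_panel
        flipped = gm.subset()
        mask = flipped.calls >= 0
        flipped.calls[mask] = 2 - flipped.calls[mask]
        s1 = window_scan(gm, "Gh", "Gb")
        s2 = window_scan(flipped, "Gh", "Gb")
        for r1, r2 in zip(s1, s2):
            assert r1.call == r2.call
            assert r1.intruders_into_a == r2.intruders_into_a
            assert r1.intruders_into_b == r2.intruders_into_b

    def test_sample_order_invariance(self, tiny_panel, rng):
        gm, _ = tiny_panel
        perm = rng.permutation(gm.n_samples)
        shuffled = gm.subset(sample_idx=perm)
        s1 = window_scan(gm, "Gh", "Gb")
        s2 = window_scan(shuffled, "Gh", "Gb")
        for r1, r2 in zip(s1, s2):
            assert (r1.call, r1.intruders_into_a, r1.intruders_into_b) == (
                r2.call, r2.intruders_into_a, r2.intruders_into_b
            )


def mk_res(chrom, start, call, into_a=(), into_b=(), assessable=True):
    return WindowScanResult(
        window=Window(chrom, start, start + 100),
        n_snps=50,
        n_fixed=30,
        assessable=assessable,
        call=call,
        intruders_into_a=frozenset(into_a),
        intruders_into_b=frozenset(into_b),
    )


class TestCallLoci:
    def test_adjacent_same_direction_windows_merge(self):
        scan = [
            mk_res("c1", 0, A_TO_B, into_b=["x", "y"]),
            mk_res("c1", 100, A_TO_B, into_b=["x", "y"]),
        ]
        loci = call_loci(scan)
        assert len(loci) == 1
        assert loci[0].interval == Window("c1", 0, 200)
        assert loci[0].carriers == {"x", "y"}
        assert loci[0].n_windows == 2

    def test_opposite_directions_make_two_loci(self):
        scan = [
            mk_res("c1", 0, A_TO_B, into_b=["x"]),
            mk_res("c1", 100, B_TO_A, into_a=["q"]),
        ]
        loci = call_loci(scan)
        assert {l.direction for l in loci} == {A_TO_B, B_TO_A}
        assert len(loci) == 2

    def test_bidirectional_window_contributes_to_both(self):
        scan = [mk_res("c1", 0, CALL_BIDIRECTIONAL, into_a=["a1"], into_b=["b1"])]
        loci = call_loci(scan)
        assert {l.direction for l in loci} == {A_TO_B, B_TO_A}
        assert all(l.interval == Window("c1", 0, 100) for l in loci)

    def test_carrier_min_frac_filters_sporadic_intruders(self):
        scan = [
            mk_res("c1", 0, A_TO_B, into_b=["x", "y"]),
            mk_res("c1", 100, A_TO_B, into_b=["x"]),
            mk_res("c1", 200, A_TO_B, into_b=["x"]),
        ]
        [locus] = call_loci(scan, carrier_min_frac=0.5)
        assert locus.carriers == {"x"}  # y seen in 1/3 windows < 0.5

    def test_unsorted_scan_rejected(self):
        scan = [mk_res("c1", 100, CALL_NONE), mk_res("c1", 0, CALL_NONE)]
        with pytest.raises(ValueError, match="sorted"):
            call_loci(scan)


class TestCallEvents:
    def mk_locus(self, chrom, start, end, direction, carriers=("x",)):
        return IntrogressionLocus(
            Window(chrom, start, end), direction, frozenset(carriers), 1, 1.0
        )

    def test_nearby_same_direction_loci_merge(self):
        loci = [
            self.mk_locus("c1", 0, 1_000_000, A_TO_B),
            self.mk_locus("c1", 2_000_000, 3_000_000, A_TO_B, ("y",)),
        ]
        [event] = call_events(loci, merge_distance_bp=5_000_000)
        assert event.interval == Window("c1", 0, 3_000_000)
        assert event.carriers == {"x", "y"}
        assert len(event.loci) == 2
        assert event.id == "B_INT1"

    def test_distant_or_cross_chromosome_loci_stay_separate(self):
        loci = [
            self.mk_locus("c1", 0, 1_000_000, A_TO_B),
            self.mk_locus("c1", 2_000_000, 3_000_000, A_TO_B),
            self.mk_locus("c2", 0, 1_000_000, A_TO_B),
        ]
        events = call_events(loci, merge_distance_bp=500_000)
        assert len(events) == 3
        assert [e.id for e in events] == ["B_INT1", "B_INT2", "B_INT3"]

    def test_direction_prefixes_name_recipient(self):
        loci = [
            self.mk_locus("c1", 0, 1_000_000, A_TO_B),
            self.mk_locus("c1", 0, 1_000_000, B_TO_A, ("a",)),
        ]
        events = call_events(loci, merge_distance_bp=0)
        ids = {e.direction: e.id for e in events}
        assert ids[A_TO_B] == "B_INT1"
        assert ids[B_TO_A] == "A_INT1"

    def test_nan_merge_distance_falls_back(self):
        loci = [
            self.mk_locus("c1", 0, 1_000_000, A_TO_B),
            self.mk_locus("c1", 2_000_000, 3_000_000, A_TO_B),
        ]
        events = call_events(loci, merge_distance_bp=float("nan"))
        assert len(events) == 1  # fallback 5 Mb merges a 1 Mb gap


class TestCarrierMatrix:
    def test_counts_and_indicators(self):
        samples = [SampleInfo(x, "Gb") for x in ("u", "v", "w")]
        loci = [
            IntrogressionLocus(Window("c1", 0, 10), A_TO_B, frozenset({"u", "v"}), 1, 1.0),
            IntrogressionLocus(Window("c2", 0, 10), A_TO_B, frozenset({"u"}), 1, 1.0),
        ]
        ind, counts = carrier_matrix(loci, samples)
        assert counts["u"] == 2 and counts["v"] == 1 and counts["w"] == 0
        assert ind.loc["u"].tolist() == [1, 1]

    def test_all_carrier_locus_column_is_ones(self):
        samples = [SampleInfo(x, "Gb") for x in ("u", "v")]
        loci = [
            IntrogressionLocus(Window("c1", 0, 10), A_TO_B, frozenset({"u", "v"}), 1, 1.0)
        ]
        ind, _ = carrier_matrix(loci, samples)
        assert ind.iloc[:, 0].tolist() == [1, 1]

    def test_unknown_carrier_rejected(self):
        samples = [SampleInfo("u", "Gb")]
        loci = [
            IntrogressionLocus(Window("c1", 0, 10), A_TO_B, frozenset({"zz"}), 1, 1.0)
        ]
        with pytest.raises(KeyError):
            carrier_matrix(loci, samples)
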