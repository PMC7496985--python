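"""BLUP, trend tests, locus contrasts, stability, marker scan, overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from introscan.association import (
    LocusEffectResult,
    blup_traits,
    classify_stable,
    interval_overlap,
    locus_effect_tests,
    marker_scan,
    trend_test,
)
from introscan import io as iolib
from introscan.model import SampleInfo, Window
from introscan.sim import substream

from conftest import make_gm


def trait_frame(rows):
    return pd.DataFrame(rows, columns=["accession", "trait", "environment", "value"])


def balanced_traits(g, envs, env_effect=0.5, resid=0.0, rng=None, trait="FL"):
    rows = []
    for i, gi in enumerate(g):
        for j, env in enumerate(envs):
            noise = rng.normal(0, resid) if (rng is not None and resid) else 0.0
            rows.append((f"a{i:03d}", trait, env, 10 + env_effect * j + gi + noise))
    return trait_frame(rows)


class TestBlup:
    def test_zero_residual_returns_unshrunken_env_adjusted_means(self):
        g = np.array([1.0, -0.5, 0.25, -0.75, 0.0])
        tt = balanced_traits(g, ["E1", "E2", "E3"])
        res = blup_traits(tt, "FL")
        # shrinkage factor -> 1: BLUPs equal the centred true effects
        assert np.allclose(res.blups.to_numpy(), g - g.mean(), atol=1e-4)
        assert res.sigma2_e < 1e-6

    def test_constant_data_gives_zero_variance_and_blups(self):
        tt = balanced_traits(np.zeros(6), ["E1", "E2"])
        res = blup_traits(tt, "FL")
        assert res.sigma2_g == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.blups.to_numpy(), 0.0, atol=1e-6)

    def test_matches_lme4_reml_on_unbalanced_data(self):
        # deterministic unbalanced dataset; reference values computed once
        # with R lme4 (lmer REML) on the identical CSV
        rng = substream(42, "blup-oracle")
        g = rng.normal(0, 1.0, 25)
        rows = []
        for i in range(25):
            for j, env in enumerate(["E1", "E2", "E3", "E4"]):
                if rng.random() < 0.15:
                    continue
                rows.append(
                    (f"acc{i:02d}", "FL", env, 30.0 + 0.5 * j + g[i] + rng.normal(0, 0.8))
                )
        tt = trait_frame(rows)
        res = blup_traits(tt, "FL")
        assert res.sigma2_g == pytest.approx(0.6204376, abs=5e-5)
        assert res.sigma2_e == pytest.approx(0.5673132, abs=5e-5)
        assert res.blups["acc00"] == pytest.approx(0.6706399, abs=5e-5)
        assert res.blups["acc01"] == pytest.approx(0.3167983, abs=5e-5)
        assert res.converged

    def test_blups_sum_to_zero_and_env_relabeling_invariance(self):
        rng = substream(7, "blup-inv")
        g = rng.normal(0, 1, 40)
        tt = balanced_traits(g, ["E1", "E2", "E3"], resid=1.0, rng=rng)
        res = blup_traits(tt, "FL")
        assert abs(res.blups.sum()) < 1e-6
        relabeled = tt.replace({"environment": {"E1": "Z9", "E3": "A0"}})
        res2 = blup_traits(relabeled, "FL")
        assert res2.sigma2_g == pytest.approx(res.sigma2_g, rel=1e-9)
        assert res2.sigma2_e == pytest.approx(res.sigma2_e, rel=1e-9)

    def test_single_environment_rejected(self):
        tt = balanced_traits(np.arange(4, dtype=float), ["E1"])
        with pytest.raises(ValueError, match="2 environments"):
            blup_traits(tt, "FL")


class TestTrendTest:
    def test_noise_free_planted_effect_recovers_slope_exactly(self):
        counts = pd.Series({f"a{i:03d}": i % 4 for i in range(12)})
        tt = trait_frame(
            [(f"a{i:03d}", "FL", "E1", 5.0 + 0.7 * (i % 4)) for i in range(12)]
        )
        r = trend_test(counts, tt, "FL", "E1")
        assert r.slope == pytest.approx(0.7, abs=1e-12)
        assert r.p < 1e-10

    def test_zero_count_variance_flagged(self):
        counts = pd.Series({f"a{i}": 2 for i in range(5)})
        tt = trait_frame([(f"a{i}", "FL", "E1", float(i)) for i in range(5)])
        r = trend_test(counts, tt, "FL", "E1")
        assert r.degenerate and np.isnan(r.p)

    def test_shift_invariance_and_scaling(self):
        rng = substream(5, "trend")
        counts = pd.Series({f"a{i}": int(c) for i, c in enumerate(rng.integers(0, 5, 30))})
        tt = trait_frame(
            [(f"a{i}", "FL", "E1", float(v)) for i, v in enumerate(rng.normal(0, 1, 30))]
        )
        base = trend_test(counts, tt, "FL", "E1")
        shifted = tt.assign(value=tt["value"] + 100.0)
        scaled = tt.assign(value=tt["value"] * 3.0)
        assert trend_test(counts, shifted, "FL", "E1").slope == pytest.approx(
            base.slope, abs=1e-10
        )
        assert trend_test(counts, scaled, "FL", "E1").slope == pytest.approx(
            3 * base.slope, abs=1e-10
        )


def welch_scalar(x, y):
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((a - mx) ** 2 for a in x) / (nx - 1)
    vy = sum((a - my) ** 2 for a in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / se2**0.5
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestLocusEffects:
    def make_inputs(self, carrier_vals, noncarrier_vals):
        n_c, n_n = len(carrier_vals), len(noncarrier_vals)
        ids = [f"c{i}" for i in range(n_c)] + [f"n{i}" for i in range(n_n)]
        ind = pd.DataFrame({"L1": [1] * n_c + [0] * n_n}, index=ids)
        tt = trait_frame(
            [(a, "FL", "E1", v) for a, v in zip(ids, carrier_vals + noncarrier_vals)]
        )
        return ind, tt

    def test_identical_value_sets_give_t_zero_p_one(self):
        ind, tt = self.make_inputs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        [r] = locus_effect_tests(ind, tt)
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0, abs=1e-12)

    def test_welch_matches_scalar_formulas(self):
        rng = substream(9, "welch")
        yes = list(rng.normal(1, 2, 9))
        no = list(rng.normal(0, 1, 14))
        ind, tt = self.make_inputs(yes, no)
        [r] = locus_effect_tests(ind, tt, test="welch")
        t, p = welch_scalar(yes, no)
        assert r.t == pytest.approx(t, abs=1e-12)
        assert r.p == pytest.approx(p, abs=1e-12)
        assert r.direction_of_effect == 1

    def test_degenerate_group_sizes_skipped(self):
        ind, tt = self.make_inputs([1.0], [2.0, 3.0, 4.0])
        assert locus_effect_tests(ind, tt) == []

    def test_bh_adjustment_is_monotone_in_raw_p(self):
        rng = substream(13, "bh")
        ids = [f"a{i}" for i in range(30)]
        ind = pd.DataFrame(
            {f"L{k}": rng.integers(0, 2, 30) for k in range(8)}, index=ids
        )
        tt = trait_frame([(a, "FL", "E1", float(v)) for a, v in zip(ids, rng.normal(0, 1, 30))])
        res = locus_effect_tests(ind, tt)
        res = sorted(res, key=lambda r: r.p)
        adj = [r.p_adj for r in res]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(r.p_adj >= r.p - 1e-12 for r in res)


def mk_effect(locus, trait, env, p, delta):
    return LocusEffectResult(
        locus=locus, trait=trait, environment=env,
        mean_carrier=delta, mean_noncarrier=0.0,
        n_carrier=10, n_noncarrier=10, t=3.0 if delta > 0 else -3.0, p=p,
    )


class TestClassifyStable:
    def test_consistent_sign_in_enough_environments_is_stable(self):
        res = [mk_effect("L1", "FL", f"E{i}", 0.01, 1.0) for i in (1, 2, 3)]
        [call] = classify_stable(res, min_envs=3)
        assert call.stable
        assert len(call.supporting) == 3

    def test_too_few_environments_or_mixed_signs_not_stable(self):
        few = [mk_effect("L1", "FL", f"E{i}", 0.01, 1.0) for i in (1, 2)]
        assert not classify_stable(few, min_envs=3)[0].stable
        mixed = [
            mk_effect("L1", "FL", "E1", 0.01, 1.0),
            mk_effect("L1", "FL", "E2", 0.01, -1.0),
            mk_effect("L1", "FL", "E3", 0.01, 1.0),
        ]
        assert not classify_stable(mixed, min_envs=3)[0].stable

    def test_support_must_come_from_one_trait(self):
        res = [
            mk_effect("L1", "FL", "E1", 0.01, 1.0),
            mk_effect("L1", "FS", "E2", 0.01, 1.0),
            mk_effect("L1", "MV", "E3", 0.01, 1.0),
        ]
        assert not classify_stable(res, min_envs=3)[0].stable


class TestMarkerScan:
    def build_panel(self, n=40, m=400, seed=3):
        rng = substream(seed, "scan")
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(np.int8)
        gm = make_gm(calls, ["Gb"] * n, pos=np.arange(1, m + 1) * 100)
        return gm, calls

    def test_constant_trait_returns_empty_with_warning(self):
        gm, _ = self.build_panel()
        tt = trait_frame([(s, "FL", "BLUP", 1.0) for s in gm.sample_ids])
        with pytest.warns(UserWarning, match="constant trait"):
            out = marker_scan(gm, tt, "FL")
        assert out.empty

    def test_strong_causal_snp_ranks_first(self):
        gm, calls = self.build_panel()
        causal = 123
        y = calls[:, causal] * 2.0 + substream(4, "noise").normal(0, 0.3, gm.n_samples)
        tt = trait_frame([(s, "FL", "BLUP", float(v)) for s, v in zip(gm.sample_ids, y)])
        out = marker_scan(gm, tt, "FL", n_pcs=0)
        assert int(out.iloc[0]["pos"]) == (causal + 1) * 100
        assert bool(out.iloc[0]["significant"])

    def test_maf_filter_drops_rare_snps(self):
        gm, calls = self.build_panel()
        calls[:, 0] = 0
        calls[0, 0] = 1  # MAF 1/80
        y = substream(6, "y").normal(0, 1, gm.n_samples)
        tt = trait_frame([(s, "FL", "BLUP", float(v)) for s, v in zip(gm.sample_ids, y)])
        out = marker_scan(gm, tt, "FL")
        assert 100 not in set(out["pos"])


class TestIntervalOverlap:
    def test_identical_intervals_full_overlap(self):
        a = iolib.intervals_frame([Window("c1", 10, 60)], ["x"], "s1")
        b = iolib.intervals_frame([Window("c1", 10, 60)], ["y"], "s2")
        [row] = interval_overlap(a, b).to_dict("records")
        assert row["overlap_bp"] == 50
        assert row["frac_a"] == row["frac_b"] == 1.0

    def test_touching_half_open_intervals_do_not_overlap(self):
        a = iolib.intervals_frame([Window("c1", 0, 10)], ["x"], "s1")
        b = iolib.intervals_frame([Window("c1", 10, 20)], ["y"], "s2")
        assert interval_overlap(a, b).empty

    def test_matches_brute_force_on_random_pairs(self, rng):
        def random_ivs(tag, n):
            starts = rng.integers(0, 1000, n)
            lens = rng.integers(1, 200, n)
            chroms = rng.choice(["c1", "c2"], n)
            return pd.DataFrame(
                {
                    "chrom": chroms,
                    "start": starts,
                    "end": starts + lens,
                    "label": [f"{tag}{i}" for i in range(n)],
                    "source": tag,
                }
            )

        a, b = random_ivs("a", 40), random_ivs("b", 25)
        got = {
            (r.label_a, r.label_b): r.overlap_bp
            for r in interval_overlap(a, b).itertuples()
        }
        expected = {}
        for ra in a.itertuples():
            for rb in b.itertuples():
                if ra.chrom == rb.chrom:
                    ov = min(ra.end, rb.end) - max(ra.start, rb.start)
                    if ov > 0:
                        expected[(ra.label, rb.label)] = ov
        assert got == expected


@settings(max_examples=30, derandomize=True)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    seed=st.integers(0, 10**6),
)
def test_trend_slope_shift_invariance_property(shift, seed):
    rng = np.random.default_rng(seed)
    counts = pd.Series({f"a{i}": int(c) for i, c in enumerate(rng.integers(0, 4, 20))})
    if counts.nunique() < 2:
        return
    tt = trait_frame(
        [(f"a{i}", "FL", "E1", float(v)) for i, v in enumerate(rng.normal(0, 1, 20))]
    )
    base = trend_test(counts, tt, "FL", "E1")
    moved = trend_test(counts, tt.assign(value=tt["value"] + shift), "FL", "E1")
    assert moved.slope == pytest.approx(base.slope, abs=1e-8)
    assert moved.p == pytest.approx(base.p, rel=1e-6, abs=1e-12)
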