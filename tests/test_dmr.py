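"""Window tiling, enrichment quantification, ANOVA/BH and DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chillmeth import dmr as D
from chillmeth.dmr import (
    DMRModel,
    WindowQuant,
    anova_window,
    anova_windows,
    bh_adjust,
    call_dmrs,
    cluster_profiles,
    filter_windows,
    quantify_window,
    quantify_windows,
    tile_windows,
    top_variance,
)

from conftest import coverage_filtered


class TestTileWindows:
    @pytest.mark.parametrize(
        "length,width,step,expected",
        [
            (250, 100, None, [(1, 100), (101, 200), (201, 250)]),
            (100, 100, None, [(1, 100)]),
            (200, 100, 50, [(1, 100), (51, 150), (101, 200), (151, 200)]),
        ],
    )
    def test_tiling(self, length, width, step, expected):
        w = tile_windows({"c": length}, width=width, step=step)
        assert list(zip(w["start"], w["end"])) == expected

    def test_disjoint_and_exhaustive(self):
        w = tile_windows({"c": 12345}, width=100)
        assert w["start"].iloc[0] == 1
        assert (w["start"].iloc[1:].to_numpy() == w["end"].iloc[:-1].to_numpy() + 1).all()
        assert w["end"].iloc[-1] == 12345

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            tile_windows({"c": 100}, width=0)
        with pytest.raises(ValueError):
            tile_windows({"c": 100}, width=100, step=200)
        with pytest.raises(ValueError):
            tile_windows({"c": 0}, width=100)


class TestQuantifyWindow:
    def test_equal_density_gives_zero(self):
        assert quantify_window(40, 100, 4000, 10_000, pseudocount=0) == pytest.approx(0.0)

    def test_tenfold_density(self):
        # (40/100) / (400/10000) = 10
        e = quantify_window(40, 100, 400, 10_000, pseudocount=0)
        assert e == pytest.approx(np.log2(10), rel=1e-12)

    def test_pseudocount_keeps_empty_window_finite(self):
        e = quantify_window(0, 100, 400, 10_000, pseudocount=0.5)
        assert np.isfinite(e)
        assert e == pytest.approx(np.log2((0.5 / 100) / (400.5 / 10_000)))

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            quantify_window(1, 0, 10, 100)


class TestQuantifyWindows:
    def test_matches_brute_force_recount(self, rng):
        # random calls, two samples; E recomputed per window by direct loops
        n = 300
        calls = {}
        for s in ("a", "b"):
            pos = np.sort(rng.choice(np.arange(1, 2001), size=n, replace=False))
            calls[s] = pd.DataFrame(
                {
                    "chrom": "c",
                    "pos": pos,
                    "strand": "+",
                    "n_meth": rng.integers(0, 10, n),
                    "n_unmeth": rng.integers(0, 10, n),
                    "context": "CHH",
                }
            )
        windows = tile_windows({"c": 2000}, 100)
        wq = quantify_windows(calls, windows, genome_length=2000)
        for j, s in enumerate(("a", "b")):
            M = calls[s]["n_meth"].sum()
            for i, w in windows.iterrows():
                sub = calls[s][(calls[s]["pos"] >= w.start) & (calls[s]["pos"] <= w.end)]
                m_w = sub["n_meth"].sum()
                expect = np.log2(((m_w + 0.5) / 100) / ((M + 0.5) / 2000))
                assert wq.E[i, j] == pytest.approx(expect, rel=1e-12)
                assert wq.m[i, j] == m_w
                assert wq.c[i, j] == len(sub)

    def test_meth_position_union_across_samples(self):
        windows = tile_windows({"c": 100}, 100)
        mk = lambda pos, nm: pd.DataFrame(
            {"chrom": "c", "pos": pos, "strand": "+", "n_meth": nm,
             "n_unmeth": 1, "context": "CHH"}
        )
        calls = {"a": mk([10, 20], [1, 0]), "b": mk([20, 30], [2, 3])}
        wq = quantify_windows(calls, windows, 100)
        # methylated positions: 10 (a), 20 (b), 30 (b) -> 3 distinct
        assert wq.n_meth_positions[0] == 3


class TestFilterWindows:
    def _wq(self, n_meth_positions):
        windows = tile_windows({"c": max(len(n_meth_positions), 1) * 100}, 100)
        windows = windows.iloc[: len(n_meth_positions)].reset_index(drop=True)
        k = len(windows)
        return WindowQuant(
            windows=windows, samples=["s"], E=np.zeros((k, 1)),
            m=np.zeros((k, 1), int), c=np.zeros((k, 1), int),
            n_meth_positions=np.asarray(n_meth_positions),
            sample_totals=pd.Series({"s": 0}), genome_length=k * 100,
        )

    def test_boundary_inclusive_at_20(self):
        wq = filter_windows(self._wq([19, 20, 21]))
        assert list(wq.n_meth_positions) == [20, 21]

    def test_empty_input(self):
        wq = filter_windows(self._wq([]))
        assert len(wq) == 0


class TestAnova:
    def test_all_equal_returns_one(self):
        assert anova_window([[2.0, 2.0, 2.0]] * 4) == 1.0

    def test_perfect_separation_returns_min_positive(self):
        p = anova_window([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        assert 0 < p <= np.finfo(float).tiny

    def test_textbook_table_matches_scipy(self):
        groups = [[1, 2, 3], [2, 3, 4], [4, 5, 6], [5, 6, 7]]
        p = anova_window(groups)
        expect = sps.f_oneway(*groups).pvalue
        assert p == pytest.approx(expect, rel=1e-9)

    def test_single_replicate_group_is_nan(self, caplog):
        assert np.isnan(anova_window([[1.0], [2.0, 3.0]]))

    def test_vectorised_matches_scipy_on_random_instances(self, rng):
        E = rng.normal(size=(200, 12))
        idx = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 9), np.arange(9, 12)]
        p = anova_windows(E, idx)
        for i in range(E.shape[0]):
            expect = sps.f_oneway(*(E[i, g] for g in idx)).pvalue
            assert p[i] == pytest.approx(expect, rel=1e-9)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_capped_at_one(self):
        assert list(bh_adjust([1.0, 1.0])) == [1.0, 1.0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_monotone_on_sorted_input_and_bounded(self, rng):
        p = np.sort(rng.uniform(size=100))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()
        assert (q <= 1).all() and (q >= p - 1e-15).all()


def _toy_windowquant(E, ids=None):
    k = E.shape[0]
    windows = tile_windows({"c": k * 100}, 100)
    if ids is not None:
        windows["window_id"] = ids
    samples = [f"s{j}" for j in range(E.shape[1])]
    return WindowQuant(
        windows=windows, samples=samples, E=E,
        m=np.zeros_like(E, dtype=int), c=np.zeros_like(E, dtype=int),
        n_meth_positions=np.full(k, 100),
        sample_totals=pd.Series(0, index=samples), genome_length=k * 100,
    )


def _toy_design(n_conds=4, reps=3):
    design = {}
    for ci in range(n_conds):
        for r in range(reps):
            design[f"s{ci * reps + r}"] = f"c{ci}"
    return design


class TestCallDmrs:
    def _E(self, deltas, noise=0.05, seed=0):
        """12-sample window set; each row shifts conditions 1..3 by delta."""
        rng = np.random.default_rng(seed)
        E = rng.normal(0, noise, size=(len(deltas), 12))
        for i, d in enumerate(deltas):
            E[i, 3:] += d
        return E

    def test_threshold_gates(self):
        # rows: strong shift (DMR), sub-delta shift, null
        E = self._E([5.0, 2.0, 0.0])
        res = call_dmrs(_toy_windowquant(E), _toy_design(), baseline="c0")
        assert list(res.table["is_dmr"]) == [True, False, False]
        assert res.dmrs[f"direction_c1"].iloc[0] == "hyper"

    def test_fdr_gate_blocks_large_delta(self):
        # huge within-group noise -> no significance despite delta > 3
        rng = np.random.default_rng(1)
        E = rng.normal(0, 5.0, size=(50, 12))
        res = call_dmrs(_toy_windowquant(E), _toy_design(), baseline="c0",
                        q_max=1e-6, min_delta=0.0)
        assert res.n_dmrs < 5  # essentially nothing at such an FDR

    def test_hypo_direction(self):
        E = self._E([-5.0])
        res = call_dmrs(_toy_windowquant(E), _toy_design(), baseline="c0")
        assert res.dmrs["direction_c3"].iloc[0] == "hypo"

    def test_hyper_hypo_partition_per_contrast(self):
        E = self._E([5.0, -5.0, 4.0, -4.0, 0.0])
        res = call_dmrs(_toy_windowquant(E), _toy_design(), baseline="c0")
        for cond in res.conditions[1:]:
            d = res.dmrs[f"direction_{cond}"]
            assert set(d) <= {"hyper", "hypo"}
            counts = res.direction_counts(cond)
            assert counts["hyper"] + counts["hypo"] == res.n_dmrs

    def test_threshold_monotonicity_superset(self):
        rng = np.random.default_rng(2)
        E = rng.normal(0, 1.5, size=(200, 12))
        wq = _toy_windowquant(E)
        strict = call_dmrs(wq, _toy_design(), "c0", q_max=0.01, min_delta=3.0)
        looser_delta = call_dmrs(wq, _toy_design(), "c0", q_max=0.01, min_delta=2.0)
        looser_q = call_dmrs(wq, _toy_design(), "c0", q_max=0.05, min_delta=3.0)
        base = set(strict.dmrs["window_id"])
        assert base <= set(looser_delta.dmrs["window_id"])
        assert base <= set(looser_q.dmrs["window_id"])

    def test_missing_baseline_rejected(self):
        E = self._E([0.0])
        with pytest.raises(ValueError):
            call_dmrs(_toy_windowquant(E), _toy_design(), baseline="nope")


class TestSplitByContext:
    def test_no_chg_calls_gives_empty_chg_set(self, single_genotype_exp,
                                              single_genotype_design):
        d = single_genotype_design
        g = "royal_dawn"
        calls = coverage_filtered(single_genotype_exp.calls[g])
        calls = {s: df[df["context"] != "CHG"] for s, df in calls.items()}
        windows = tile_windows(dict(d.chrom_sizes), 100)
        ctx = D.split_by_context(
            calls, windows, single_genotype_exp.sample_design(g), "0CH",
            d.genome_length,
        )
        assert ctx["CHG"].n_dmrs == 0

    def test_single_context_data_equals_all_context_calling(
        self, single_genotype_exp, single_genotype_design
    ):
        d = single_genotype_design
        g = "royal_dawn"
        calls = coverage_filtered(single_genotype_exp.calls[g])
        chh_only = {s: df[df["context"] == "CHH"].reset_index(drop=True)
                    for s, df in calls.items()}
        windows = tile_windows(dict(d.chrom_sizes), 100)
        design = single_genotype_exp.sample_design(g)
        ctx = D.split_by_context(chh_only, windows, design, "0CH", d.genome_length)
        wq = filter_windows(
            quantify_windows(chh_only, windows, d.genome_length), 20,
            count_mode="per-sample-sum",
        )
        allres = call_dmrs(wq, design, "0CH")
        assert set(ctx["CHH"].dmrs["window_id"]) == set(allres.dmrs["window_id"])

    def test_uniform_all_context_dmr_found_in_all_three(self, single_genotype_design):
        # planted effect shifts every context -> each per-context set sees it
        from chillmeth.simulate import simulate_experiment, SimulationDesign

        # wide uniform-context DMRs so even the sparse CpG/CHG site classes
        # carry enough signal per locus
        d = SimulationDesign(
            seed=21, conditions={"royal_dawn": (0, 173, 348, 516)},
            chrom_sizes={"chr1": 60_000}, n_genes=50, n_dmrs=6, n_pairs=0,
            n_degs=0, dmr_context="all", dmr_width=400,
        )
        exp = simulate_experiment(d)
        calls = coverage_filtered(exp.calls["royal_dawn"])
        windows = tile_windows(dict(d.chrom_sizes), 100)
        ctx = D.split_by_context(
            calls, windows, exp.sample_design("royal_dawn"), "0CH", d.genome_length
        )
        truth = exp.truth_dmrs
        for c in ("CpG", "CHG", "CHH"):
            called = ctx[c].dmrs
            hits = 0
            for t in truth.itertuples():
                hits += bool(((called["start"] <= t.end) & (called["end"] >= t.start)).any())
            assert hits >= len(truth) - 1, f"context {c} missed planted DMRs"


class TestTopVariance:
    def test_orders_by_variance(self):
        prof = pd.DataFrame([[1, 1, 1, 1], [0, 2, 0, 2]], index=["flat", "osc"])
        assert list(top_variance(prof, 2).index) == ["osc", "flat"]

    def test_n_larger_than_items_returns_all(self):
        prof = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"])
        assert len(top_variance(prof, 10)) == 2

    def test_matches_brute_force_sort(self, rng):
        prof = pd.DataFrame(rng.normal(size=(10, 4)),
                            index=[f"w{i}" for i in range(10)])
        got = list(top_variance(prof, 5).index)
        expect = sorted(
            prof.index, key=lambda i: (-prof.loc[i].var(ddof=0), i)
        )[:5]
        assert got == expect


class TestClusterProfiles:
    def test_two_planted_groups_recovered(self, rng):
        up = np.tile([0, 1, 2, 3], (10, 1)) + rng.normal(0, 0.05, (10, 4))
        down = np.tile([3, 2, 1, 0], (10, 1)) + rng.normal(0, 0.05, (10, 4))
        prof = pd.DataFrame(np.vstack([up, down]),
                            index=[f"i{i}" for i in range(20)])
        out = cluster_profiles(prof, k=2, seed=0)
        labels = out["cluster_id"].to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k_equals_items_zero_inertia(self, rng):
        prof = pd.DataFrame(rng.normal(size=(5, 4)))
        out = cluster_profiles(prof, k=5, seed=0)
        assert out.attrs["inertia"] == pytest.approx(0.0, abs=1e-12)
        assert out["cluster_id"].nunique() == 5

    def test_same_seed_same_partition(self, rng):
        prof = pd.DataFrame(rng.normal(size=(30, 4)))
        a = cluster_profiles(prof, 4, seed=7)
        b = cluster_profiles(prof, 4, seed=7)
        assert (a["cluster_id"] == b["cluster_id"]).all()

    def test_invalid_k(self, rng):
        prof = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            cluster_profiles(prof, 0)
        with pytest.raises(ValueError):
            cluster_profiles(prof, 4)
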