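import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pclfit as pf
from pclfit.sampling import (
    SampleTrace,
    correlation_bins,
    correlation_table,
    min_drmsd_summary,
    run_sampler,
    spearman,
)


def make_trace(pairs, sampler="pclf", pid="p1"):
    """Trace with given (e_hp, drmsd) pairs; other energies mirror e_hp."""
    records = [
        (k, float(d), float(e), float(e), float(e)) for k, (e, d) in enumerate(pairs)
    ]
    return SampleTrace(pid, "fcc", sampler, records)


class TestSpearman:
    def test_monotone_increasing_is_plus_one(self):
        t = make_trace([(1, 1), (2, 3), (5, 7), (9, 8)])
        assert spearman(t, "hp-basic") == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        t = make_trace([(9, 1), (5, 3), (2, 7), (1, 8)])
        assert spearman(t, "hp-basic") == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # ranks differ by (1,-1,1,-1): rho = 1 - 6*4/(4*15) = 0.6
        t = make_trace([(1, 2), (2, 1), (3, 4), (4, 3)])
        assert spearman(t, "hp-basic") == pytest.approx(0.6)

    def test_constant_column_flagged_nan(self):
        t = make_trace([(0, 1), (0, 2), (0, 3)])
        assert np.isnan(spearman(t, "hp-basic"))

    def test_agrees_with_rank_difference_formula(self):
        """Oracle: direct d^2 formula on tie-free data."""
        rng = np.random.default_rng(0)
        e = rng.permutation(20).astype(float)
        d = rng.permutation(20).astype(float)
        t = make_trace(list(zip(e, d)))
        rank = lambda x: np.argsort(np.argsort(x)) + 1
        dd = rank(e) - rank(d)
        n = len(e)
        expected = 1 - 6 * (dd**2).sum() / (n * (n**2 - 1))
        assert spearman(t, "hp-basic") == pytest.approx(expected)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            spearman(make_trace([(1, 2), (2, 1)]), "hp-basic")


class TestCorrelationBins:
    def test_two_value_example(self):
        bins = correlation_bins([0.6, -0.6])
        assert bins == {">0": 50.0, ">0.5": 50.0, "<=0": 50.0, "<-0.5": 50.0}

    def test_zero_counts_as_nonpositive(self):
        bins = correlation_bins([0.0, 0.0])
        assert bins[">0"] == 0.0 and bins["<=0"] == 100.0
        assert bins["<-0.5"] == 0.0

    def test_nan_excluded(self):
        bins = correlation_bins([0.9, float("nan")])
        assert bins[">0"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            correlation_bins([float("nan")])

    @given(
        st.lists(st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1)
    )
    @settings(max_examples=60, deadline=None)
    def test_partition_and_subset_structure(self, rhos):
        bins = correlation_bins(rhos)
        assert bins[">0"] + bins["<=0"] == pytest.approx(100.0)
        assert bins[">0.5"] <= bins[">0"] + 1e-9
        assert bins["<-0.5"] <= bins["<=0"] + 1e-9


class TestSamplers:
    def test_pclf_trace_reaches_floor_on_exact_walk(self):
        B, _ = pf.lattice_walk_backbone(15, pf.FCC, seed=40)
        trace = run_sampler(B, pf.FCC, "pclf", n_samples=200,
                            cfg=pf.SearchConfig(seed=1))
        d = trace.column("drmsd")
        assert len(trace.records) == 200
        assert np.all(np.diff(d) <= 1e-12)  # dRMSD-guided: non-increasing
        assert d[-1] == pytest.approx(0.0, abs=1e-9)

    def test_guided_trace_monotone_in_energy_not_drmsd(self):
        B = pf.offlattice_backbone(20, seed=41)
        trace = run_sampler(B, pf.FCC, "guided-mj", n_samples=600,
                            cfg=pf.SearchConfig(seed=2))
        e = trace.column("e_mj")
        d = trace.column("drmsd")
        assert np.all(np.diff(e) <= 1e-9)
        assert np.any(np.diff(d) > 1e-9)  # dRMSD free to rise

    def test_guided_hp_all_polar_sequence_keeps_zero_energy(self):
        B, _ = pf.lattice_walk_backbone(12, pf.FCC, seed=42)
        B = pf.Backbone("S" * 12, B.coords, id=B.id)  # serine: polar
        trace = run_sampler(B, pf.FCC, "guided-hp-basic", n_samples=100,
                            cfg=pf.SearchConfig(seed=3))
        assert np.all(trace.column("e_hp") == 0.0)

    def test_random_walk_valid_and_not_monotone(self):
        B = pf.offlattice_backbone(15, seed=43)
        trace = run_sampler(B, pf.FCC, "random-walk", n_samples=500,
                            cfg=pf.SearchConfig(seed=4))
        assert len(trace.records) == 500
        d = trace.column("drmsd")
        assert np.any(np.diff(d) > 0) and np.any(np.diff(d) < 0)

    def test_recorded_energies_match_recompute(self):
        """Spot-check: re-run a short sampler and recompute the energy columns."""
        B = pf.offlattice_backbone(10, seed=44)
        confs = []
        from pclfit.local_search import pclf_search, SearchConfig

        pclf_search(B, pf.FCC, SearchConfig(seed=5, max_iterations=50),
                    record_hook=lambda it, C, d: confs.append(C) if it else None)
        trace = run_sampler(B, pf.FCC, "pclf", n_samples=50,
                            cfg=pf.SearchConfig(seed=5))
        models = {n: pf.load_energy_model(n) for n in ("hp-basic", "mj", "bre")}
        for C, rec in zip(confs, trace.records):
            assert rec[2] == pytest.approx(pf.total_energy(C, B.sequence, models["hp-basic"]))
            assert rec[3] == pytest.approx(pf.total_energy(C, B.sequence, models["mj"]))
            assert rec[4] == pytest.approx(pf.total_energy(C, B.sequence, models["bre"]))

    def test_unknown_mode_rejected(self):
        B = pf.offlattice_backbone(10, seed=0)
        with pytest.raises(ValueError):
            run_sampler(B, pf.FCC, "metropolis")


class TestSummaries:
    def test_min_of_monotone_trace_is_final_value(self):
        t = make_trace([(0, 3.0), (0, 2.0), (0, 1.5)], sampler="pclf")
        assert t.min_drmsd() == pytest.approx(1.5)

    def test_summary_pivots_by_sampler(self):
        a = make_trace([(0, 3.0), (0, 1.0)], sampler="pclf", pid="x")
        b = make_trace([(0, 4.0), (0, 2.5)], sampler="random-walk", pid="x")
        table = min_drmsd_summary([a, b])
        row = table.iloc[0]
        assert row["pclf"] == pytest.approx(1.0)
        assert row["random-walk"] == pytest.approx(2.5)

    def test_empty_traces_dropped(self):
        empty = SampleTrace("y", "fcc", "pclf", [])
        table = min_drmsd_summary([empty])
        assert len(table) == 0

    def test_correlation_table_has_bin_columns(self):
        traces = [
            make_trace([(1, 1), (2, 2), (3, 3), (4, 5)], pid=f"p{k}") for k in range(3)
        ]
        table = correlation_table(traces)
        assert set(table.columns) >= {">0", ">0.5", "<=0", "<-0.5"}
        assert (table[">0"] + table["<=0"]).eq(100.0).all()


def test_trace_csv_roundtrip(tmp_path):
    t = make_trace([(1, 2.0), (0, 1.0), (-1, 3.0)])
    path = tmp_path / "t.csv"
    t.to_csv(path)
    back = SampleTrace.from_csv(path, sampler="pclf")
    assert back.records == t.records
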