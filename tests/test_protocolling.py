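import numpy as np
import pytest

from amri.protocolling import (
    LUT,
    LUTEntry,
    AllocationLine,
    assemble_fastest_protocol,
    brute_force_search,
    build_allocation_line,
    geometric_schedule,
    percent_time_allocated,
    rank_entries,
    read_lut_csv,
    select_optimal,
    write_lut_csv,
)
from amri.synthetic import make_lut_fixture


def _simple_lut(entries=None, default=None, **kwargs):
    if entries is None:
        entries = [
            LUTEntry({"TR": 100.0, "NEX": 2.0}, t_acq_s=120.0, rsnr=1.0),
            LUTEntry({"TR": 80.0, "NEX": 2.0}, t_acq_s=90.0, rsnr=0.9),
            LUTEntry({"TR": 60.0, "NEX": 1.0}, t_acq_s=50.0, rsnr=0.6),
        ]
    return LUT("seq", entries, default or entries[0], **kwargs)


class TestAllocationLine:
    def test_endpoints_and_midpoint(self):
        line = AllocationLine(x1=600.0, x2=1200.0, y1=10.0, y2=25.0)
        assert percent_time_allocated(line, 600.0) == pytest.approx(10.0)
        assert percent_time_allocated(line, 1200.0) == pytest.approx(25.0)
        assert percent_time_allocated(line, 900.0) == pytest.approx(17.5)

    def test_clamping_warns(self):
        line = AllocationLine(x1=600.0, x2=1200.0, y1=10.0, y2=25.0)
        with pytest.warns(UserWarning, match="clamping"):
            assert percent_time_allocated(line, 100.0) == pytest.approx(10.0)

    def test_build_ratio(self):
        line = build_allocation_line(60.0, 200.0, 600.0, 1200.0)
        assert line.y1 == pytest.approx(10.0)
        assert line.y2 == pytest.approx(100.0 * 200.0 / 1200.0)

    def test_single_sequence_protocol(self):
        line = build_allocation_line(600.0, 1100.0, 600.0, 1100.0)
        assert line.y1 == pytest.approx(100.0)
        assert line.y2 == pytest.approx(100.0)

    def test_seven_sequence_fixture_hand_computed(self):
        """Multi-sequence timing fixture: line parameters equal a hand
        computation from the per-sequence extremes."""
        seq_min = [30.0, 20.0, 45.0, 60.0, 25.0, 30.0, 40.0]
        seq_max = [164.0, 44.0, 150.0, 141.0, 226.0, 164.0, 154.0]
        pmin, pmax = sum(seq_min), sum(seq_max)
        line0 = build_allocation_line(seq_min[0], seq_max[0], pmin, pmax)
        assert line0.x1 == pytest.approx(250.0)
        assert line0.x2 == pytest.approx(1043.0)
        assert line0.y1 == pytest.approx(100 * 30.0 / 250.0)
        assert line0.y2 == pytest.approx(100 * 164.0 / 1043.0)

    def test_ordering_violations(self):
        with pytest.raises(ValueError):
            build_allocation_line(700.0, 800.0, 600.0, 1200.0)
        with pytest.raises(ValueError):
            AllocationLine(x1=100.0, x2=100.0, y1=5.0, y2=6.0)


class TestRanking:
    def test_default_entry_rank_zero_first(self):
        lut = _simple_lut()
        ranked = rank_entries(lut)
        assert ranked[0][0] == lut.default
        assert ranked[0][1] == 0.0

    def test_linearity_in_single_dof(self):
        default = LUTEntry({"TR": 100.0}, t_acq_s=100.0, rsnr=1.0)
        e1 = LUTEntry({"TR": 110.0}, t_acq_s=100.0, rsnr=1.0)
        e2 = LUTEntry({"TR": 120.0}, t_acq_s=100.0, rsnr=1.0)
        lut = LUT("s", [default, e1, e2], default)
        ranks = {id(e): r for e, r in rank_entries(lut)}
        assert ranks[id(e2)] == pytest.approx(2 * ranks[id(e1)])

    def test_rank_ordering_matches_independent_computation(self):
        lut = make_lut_fixture(20, ["TR", "TE"], seed=4)
        w, wr = lut.weights, lut.rsnr_weight

        def oracle_rank(e):
            r = sum(
                w[d] * abs(e.p_acq[d] - lut.default.p_acq[d]) / lut.normalizers[d]
                for d in lut.default.p_acq
            )
            return r + wr * abs(e.rsnr - lut.default.rsnr) / lut.default.rsnr

        got = [r for _, r in rank_entries(lut)]
        expected = sorted(oracle_rank(e) for e in lut.entries)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_missing_dof_named(self):
        default = LUTEntry({"TR": 100.0, "TE": 10.0}, t_acq_s=100.0, rsnr=1.0)
        bad = LUTEntry({"TR": 90.0}, t_acq_s=90.0, rsnr=0.9)
        with pytest.raises(ValueError, match="TE"):
            LUT("s", [default, bad], default)

    def test_rsnr_weight_cap_enforced(self):
        with pytest.raises(ValueError, match="rsnr weight"):
            _simple_lut(weights={"TR": 0.5, "NEX": 0.5}, rsnr_weight=0.6)

    def test_categorical_dof(self):
        default = LUTEntry({"ASSET": "on"}, t_acq_s=100.0, rsnr=1.0)
        same = LUTEntry({"ASSET": "on"}, t_acq_s=90.0, rsnr=1.0)
        other = LUTEntry({"ASSET": "off"}, t_acq_s=80.0, rsnr=1.0)
        lut = LUT("s", [default, same, other], default, weights={"ASSET": 1.0})
        ranks = dict((id(e), r) for e, r in rank_entries(lut))
        assert ranks[id(same)] == 0.0
        assert ranks[id(other)] == pytest.approx(1.0)


class TestSelectOptimal:
    def test_infeasible_budget_returns_none(self):
        assert select_optimal(_simple_lut(), 10.0) is None

    def test_boundary_budget_inclusive(self):
        lut = _simple_lut()
        assert select_optimal(lut, 50.0) == lut.entries[2]

    def test_oracle_equivalence_seeded_fixtures(self):
        rng = np.random.default_rng(42)
        for trial in range(200):
            lut = make_lut_fixture(
                int(rng.integers(1, 40)), ["TR", "TE", "NEX"], seed=int(rng.integers(1 << 30))
            )
            budget = float(rng.uniform(0.3 * lut.min_t_acq(), 1.2 * lut.max_t_acq()))
            assert select_optimal(lut, budget) == brute_force_search(lut, budget)

    def test_tie_break_shared(self):
        default = LUTEntry({"TR": 100.0}, t_acq_s=100.0, rsnr=1.0)
        tie_a = LUTEntry({"TR": 90.0}, t_acq_s=70.0, rsnr=1.0)
        tie_b = LUTEntry({"TR": 110.0}, t_acq_s=60.0, rsnr=1.0)
        lut = LUT("s", [default, tie_a, tie_b], default)
        # equal rank, lower t_acq wins in both implementations
        assert select_optimal(lut, 80.0) == tie_b == brute_force_search(lut, 80.0)

    def test_result_respects_budget_and_rank(self):
        lut = make_lut_fixture(60, ["TR"], seed=13)
        budget = float(np.median([e.t_acq_s for e in lut.entries]))
        chosen = select_optimal(lut, budget)
        ranks = {id(e): r for e, r in rank_entries(lut)}
        assert chosen.t_acq_s <= budget
        feasible = [e for e in lut.entries if e.t_acq_s <= budget]
        assert all(ranks[id(chosen)] <= ranks[id(e)] for e in feasible)


class TestAssembleFastest:
    def test_default_only_luts_reproduce_gs(self):
        luts = []
        for i, t in enumerate((120.0, 80.0)):
            e = LUTEntry({"TR": 100.0}, t_acq_s=t, rsnr=1.0)
            luts.append(LUT(f"s{i}", [e], e))
        plan = assemble_fastest_protocol(luts, [200.0, 190.0, 150.0])
        assert plan.total_t_acq_s == pytest.approx(200.0)
        assert plan.imposed_budget_s == pytest.approx(200.0)

    def test_matches_exhaustive_schedule_search(self):
        luts = [make_lut_fixture(30, ["TR", "NEX"], seed=s, sequence_id=f"s{s}")
                for s in (1, 2, 3)]
        gs_total = sum(l.default.t_acq_s for l in luts)
        schedule = geometric_schedule(gs_total, factor=0.9)
        plan = assemble_fastest_protocol(luts, schedule)

        # independent oracle: scan the schedule exhaustively with brute force
        pmin = sum(l.min_t_acq() for l in luts)
        pmax = sum(l.max_t_acq() for l in luts)
        best = None
        for budget in schedule:
            chosen = {}
            for l in luts:
                y1 = 100 * l.min_t_acq() / pmin
                y2 = 100 * l.max_t_acq() / pmax
                x = min(max(budget, pmin), pmax)
                pct = (y2 - y1) / (pmax - pmin) * (x - pmin) + y1
                e = brute_force_search(l, pct / 100 * budget)
                if e is None:
                    chosen = None
                    break
                chosen[l.sequence_id] = e
            if chosen is None:
                break
            best = (budget, chosen)
        assert plan.imposed_budget_s == pytest.approx(best[0])
        assert plan.per_sequence == best[1]

    def test_removing_fast_entries_raises_budget(self):
        rng = np.random.default_rng(0)
        luts = [make_lut_fixture(40, ["TR"], seed=s, sequence_id=f"s{s}") for s in (5, 6)]
        schedule = geometric_schedule(sum(l.default.t_acq_s for l in luts), factor=0.9)
        full = assemble_fastest_protocol(luts, schedule)
        median_t = float(np.median([e.t_acq_s for e in luts[0].entries]))
        slow_entries = [e for e in luts[0].entries if e.t_acq_s >= median_t]
        crippled = [LUT("s5", slow_entries, luts[0].default), luts[1]]
        reduced = assemble_fastest_protocol(crippled, schedule)
        assert reduced.imposed_budget_s >= full.imposed_budget_s

    def test_superset_monotonicity(self):
        base = make_lut_fixture(20, ["TR"], seed=8, sequence_id="a")
        extra = make_lut_fixture(40, ["TR"], seed=8, sequence_id="a")
        # the 40-entry fixture is a superset in terms of timing coverage
        other = make_lut_fixture(20, ["TR"], seed=9, sequence_id="b")
        schedule = geometric_schedule(
            base.default.t_acq_s + other.default.t_acq_s, factor=0.9
        )
        small = assemble_fastest_protocol([base, other], schedule)
        grown = assemble_fastest_protocol(
            [LUT("a", base.entries + extra.entries, base.default), other], schedule
        )
        assert grown.total_t_acq_s <= small.total_t_acq_s + 1e-9

    def test_infeasible_first_budget_errors(self):
        e = LUTEntry({"TR": 100.0}, t_acq_s=100.0, rsnr=1.0)
        lut = LUT("s", [e], e)
        with pytest.raises(RuntimeError, match="infeasible"):
            assemble_fastest_protocol([lut], [50.0, 40.0])


class TestCsvRoundTrip:
    def test_roundtrip(self, tmp_path):
        lut = make_lut_fixture(25, ["TR", "TE"], seed=3)
        p = tmp_path / "lut.csv"
        write_lut_csv(lut, p)
        back = read_lut_csv(p)
        assert back.sequence_id == lut.sequence_id
        assert len(back.entries) == len(lut.entries)
        assert back.default.t_acq_s == pytest.approx(lut.default.t_acq_s)
        for a, b in zip(lut.entries, back.entries):
            assert a.t_acq_s == pytest.approx(b.t_acq_s, rel=1e-4)

    def test_missing_default_flag(self, tmp_path):
        lut = make_lut_fixture(5, ["TR"], seed=3)
        p = tmp_path / "lut.csv"
        write_lut_csv(lut, p)
        import pandas as pd

        df = pd.read_csv(p)
        df["is_default"] = 0
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="is_default"):
            read_lut_csv(p)
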