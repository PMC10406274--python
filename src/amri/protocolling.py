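"""Intelligent protocolling: look-up-table (LUT) constrained search.

Each pulse sequence owns a LUT mapping acquisition-parameter combinations
(``P_acq`` over the sequence's degrees of freedom, DOF) to the acquisition
time ``t_acq`` and the console-reported relative SNR (rSNR).  Accelerating a
protocol is a constrained search: impose a whole-protocol time budget
``T_acq``, split it across sequences along a straight line between the
minimum and maximum feasible time percentages, discard LUT rows exceeding
the per-sequence share, and among the survivors pick the row whose weighted
distance to the default (gold-standard) combination is smallest -- so the
chosen combination preserves image contrast while shedding time.  Repeating
with ever lower budgets until some sequence runs out of feasible rows yields
the "Fastest" protocol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from numbers import Real
from pathlib import Path

import pandas as pd

__all__ = [
    "LUTEntry",
    "LUT",
    "AllocationLine",
    "ProtocolPlan",
    "percent_time_allocated",
    "build_allocation_line",
    "rank_entries",
    "select_optimal",
    "brute_force_search",
    "assemble_fastest_protocol",
    "geometric_schedule",
    "read_lut_csv",
    "write_lut_csv",
]

# Default DOF weighting: contrast-critical timing parameters dominate,
# geometry parameters count half, rSNR gets the smallest weight (acceleration
# deliberately trades SNR away, to be recovered by denoising).
TIMING_DOFS = frozenset({"TE", "TR", "TI", "ETL"})
DEFAULT_TIMING_WEIGHT = 1.0
DEFAULT_GEOMETRY_WEIGHT = 0.5
DEFAULT_RSNR_WEIGHT = 0.1


@dataclass(frozen=True)
class LUTEntry:
    """One DOF combination with its recorded time and relative SNR."""

    p_acq: dict
    t_acq_s: float
    rsnr: float

    def __post_init__(self):
        if self.t_acq_s <= 0:
            raise ValueError("t_acq_s must be > 0")
        if self.rsnr <= 0:
            raise ValueError("rsnr must be > 0")
        for name, value in self.p_acq.items():
            if isinstance(value, Real) and not math.isfinite(float(value)):
                raise ValueError(f"DOF {name!r} is non-finite")


@dataclass
class LUT:
    """A sequence's look-up table plus the ranking configuration.

    ``weights`` maps each DOF name to a non-negative weight; ``rsnr_weight``
    must not exceed the smallest DOF weight.  ``normalizers`` holds the
    positive scale used to normalise each DOF difference; when omitted it is
    derived from the default entry's value (or the LUT's value range when the
    default is zero / categorical).
    """

    sequence_id: str
    entries: list[LUTEntry]
    default: LUTEntry
    weights: dict = field(default_factory=dict)
    rsnr_weight: float = DEFAULT_RSNR_WEIGHT
    normalizers: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("LUT must contain at least one entry")
        dof_names = set(self.default.p_acq)
        for i, e in enumerate(self.entries):
            missing = dof_names - set(e.p_acq)
            if missing:
                raise ValueError(
                    f"LUT {self.sequence_id!r} entry {i} lacks DOF(s) {sorted(missing)}"
                )
        if not self.weights:
            self.weights = {
                d: DEFAULT_TIMING_WEIGHT if d in TIMING_DOFS else DEFAULT_GEOMETRY_WEIGHT
                for d in dof_names
            }
        missing_w = dof_names - set(self.weights)
        if missing_w:
            raise ValueError(f"weights missing for DOF(s) {sorted(missing_w)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")
        if self.weights and self.rsnr_weight > min(self.weights.values()):
            raise ValueError("rsnr weight must not exceed the smallest DOF weight")
        for d in dof_names:
            self.normalizers.setdefault(d, self._auto_normalizer(d))
        if any(z <= 0 for z in self.normalizers.values()):
            raise ValueError("normalizers must be > 0")

    def _auto_normalizer(self, dof: str) -> float:
        ref = self.default.p_acq[dof]
        if isinstance(ref, Real) and float(ref) != 0.0:
            return abs(float(ref))
        values = [e.p_acq[dof] for e in self.entries if isinstance(e.p_acq[dof], Real)]
        if values:
            span = max(values) - min(values)
            if span > 0:
                return float(span)
        return 1.0

    @property
    def dof_names(self) -> list[str]:
        return sorted(self.default.p_acq)

    def min_t_acq(self) -> float:
        return min(e.t_acq_s for e in self.entries)

    def max_t_acq(self) -> float:
        return max(e.t_acq_s for e in self.entries)


@dataclass(frozen=True)
class AllocationLine:
    """Straight line mapping a protocol budget to a sequence's time share (%)."""

    x1: float  # shortest protocol acquisition time (s)
    x2: float  # longest protocol acquisition time (s)
    y1: float  # minimum time percentage
    y2: float  # maximum time percentage

    def __post_init__(self):
        if not self.x2 > self.x1:
            raise ValueError("allocation line requires x2 > x1")
        for y in (self.y1, self.y2):
            if not (0 < y <= 100):
                raise ValueError("time percentages must lie in (0, 100]")


@dataclass
class ProtocolPlan:
    """Chosen entry per sequence under the smallest feasible protocol budget."""

    per_sequence: dict
    imposed_budget_s: float

    @property
    def total_t_acq_s(self) -> float:
        return sum(e.t_acq_s for e in self.per_sequence.values())


def percent_time_allocated(line: AllocationLine, x: float) -> float:
    """Percentage of the protocol budget allocated to a sequence at budget ``x``.

    %TA = ((y2 - y1) / (x2 - x1)) * (x - x1) + y1; budgets outside
    [x1, x2] are clamped with a warning.
    """
    if x < line.x1 or x > line.x2:
        warnings.warn(
            f"budget {x} s outside allocation range [{line.x1}, {line.x2}]; clamping",
            stacklevel=2,
        )
        x = min(max(x, line.x1), line.x2)
    slope = (line.y2 - line.y1) / (line.x2 - line.x1)
    return slope * (x - line.x1) + line.y1


def build_allocation_line(
    seq_min_t: float, seq_max_t: float, protocol_min_t: float, protocol_max_t: float
) -> AllocationLine:
    """Allocation line for one sequence.

    y1 is the ratio (as %) of the shortest sequence time to the shortest
    protocol time; y2 is built analogously from the longest times.
    """
    if not (0 < seq_min_t <= protocol_min_t < protocol_max_t):
        raise ValueError("require 0 < seq_min_t <= protocol_min_t < protocol_max_t")
    if not (seq_min_t <= seq_max_t <= protocol_max_t):
        raise ValueError("require seq_min_t <= seq_max_t <= protocol_max_t")
    return AllocationLine(
        x1=protocol_min_t,
        x2=protocol_max_t,
        y1=100.0 * seq_min_t / protocol_min_t,
        y2=100.0 * seq_max_t / protocol_max_t,
    )


def _entry_rank(lut: LUT, e: LUTEntry) -> float:
    rank = 0.0
    for d in lut.default.p_acq:
        w = lut.weights[d]
        a, b = e.p_acq[d], lut.default.p_acq[d]
        if isinstance(a, Real) and isinstance(b, Real):
            rank += w * abs(float(a) - float(b)) / lut.normalizers[d]
        else:
            # categorical DOF: full weight unless identical to the default
            rank += 0.0 if a == b else w
    rank += lut.rsnr_weight * abs(e.rsnr - lut.default.rsnr) / lut.default.rsnr
    return rank


def rank_entries(lut: LUT) -> list[tuple[LUTEntry, float]]:
    """Entries with their weighted-difference rank, ascending.

    The rank sums the weighted absolute differences of each DOF (and rSNR)
    from the default combination, each scaled by its normalizer.  Ties break
    by lower ``t_acq_s``, then input order (stable).
    """
    ranked = [(e, _entry_rank(lut, e)) for e in lut.entries]
    order = sorted(range(len(ranked)), key=lambda i: (ranked[i][1], ranked[i][0].t_acq_s, i))
    return [ranked[i] for i in order]


def select_optimal(lut: LUT, t_budget_s: float) -> LUTEntry | None:
    """Minimum-rank entry whose ``t_acq_s`` does not exceed the budget.

    Entries *exceeding* the budget are discarded (boundary inclusive);
    ``None`` when nothing is feasible.
    """
    if t_budget_s <= 0:
        raise ValueError("t_budget_s must be > 0")
    for entry, _rank in rank_entries(lut):
        if entry.t_acq_s <= t_budget_s:
            return entry
    return None


def brute_force_search(lut: LUT, t_budget_s: float) -> LUTEntry | None:
    """Independent exhaustive implementation of :func:`select_optimal`'s contract."""
    if t_budget_s <= 0:
        raise ValueError("t_budget_s must be > 0")
    best = None
    best_key = None
    for i, e in enumerate(lut.entries):
        if e.t_acq_s > t_budget_s:
            continue
        key = (_entry_rank(lut, e), e.t_acq_s, i)
        if best_key is None or key < best_key:
            best, best_key = e, key
    return best


def geometric_schedule(start_s: float, factor: float = 0.95, floor_s: float | None = None):
    """Strictly decreasing budget schedule ``start, start*factor, ...`` (>= floor)."""
    if not (0 < factor < 1):
        raise ValueError("factor must be in (0, 1)")
    if floor_s is None:
        floor_s = 0.05 * start_s
    budgets = []
    b = float(start_s)
    while b >= floor_s:
        budgets.append(b)
        b *= factor
    return budgets


def assemble_fastest_protocol(luts: list[LUT], schedule) -> ProtocolPlan:
    """Lowest-budget protocol for which every sequence still has a feasible entry.

    For each budget in the (strictly decreasing) schedule, per-sequence
    budgets come from :func:`percent_time_allocated` and the per-sequence
    optimum from :func:`select_optimal`; iteration stops at the first budget
    where some sequence is infeasible and the previous complete plan wins.
    """
    if not luts:
        raise ValueError("need at least one LUT")
    schedule = list(schedule)
    if any(b2 >= b1 for b1, b2 in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly decreasing")
    protocol_min = sum(l.min_t_acq() for l in luts)
    protocol_max = sum(l.max_t_acq() for l in luts)
    if protocol_min < protocol_max:
        lines = {
            l.sequence_id: build_allocation_line(
                l.min_t_acq(), l.max_t_acq(), protocol_min, protocol_max
            )
            for l in luts
        }
    else:
        # degenerate single-timing LUTs: allocation collapses to a fixed share
        lines = None
        shares = {l.sequence_id: 100.0 * l.max_t_acq() / protocol_max for l in luts}
    best_plan = None
    for budget in schedule:
        chosen = {}
        for lut in luts:
            if lines is None:
                pct = shares[lut.sequence_id]
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pct = percent_time_allocated(lines[lut.sequence_id], budget)
            entry = select_optimal(lut, pct / 100.0 * budget)
            if entry is None:
                chosen = None
                break
            chosen[lut.sequence_id] = entry
        if chosen is None:
            break
        best_plan = ProtocolPlan(per_sequence=chosen, imposed_budget_s=budget)
    if best_plan is None:
        raise RuntimeError("protocol infeasible even at the first (largest) budget")
    return best_plan


# ---------------------------------------------------------------------------
# LUT CSV dialect: sequence_id, dof:<name>..., t_acq_s, rsnr, is_default

def write_lut_csv(lut: LUT, path) -> None:
    rows = []
    for e in lut.entries:
        row = {"sequence_id": lut.sequence_id}
        row.update({f"dof:{d}": e.p_acq[d] for d in lut.dof_names})
        row["t_acq_s"] = e.t_acq_s
        row["rsnr"] = e.rsnr
        row["is_default"] = int(e == lut.default)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_lut_csv(path, weights: dict | None = None, rsnr_weight: float = DEFAULT_RSNR_WEIGHT,
                 normalizers: dict | None = None) -> LUT:
    df = pd.read_csv(path)
    dof_cols = [c for c in df.columns if c.startswith("dof:")]
    entries, default = [], None
    for _, row in df.iterrows():
        e = LUTEntry(
            p_acq={c[4:]: row[c] for c in dof_cols},
            t_acq_s=float(row["t_acq_s"]),
            rsnr=float(row["rsnr"]),
        )
        entries.append(e)
        if int(row.get("is_default", 0)):
            default = e
    if default is None:
        raise ValueError(f"{Path(path).name}: no row flagged is_default=1")
    return LUT(
        sequence_id=str(df["sequence_id"].iloc[0]),
        entries=entries,
        default=default,
        weights=weights or {},
        rsnr_weight=rsnr_weight,
        normalizers=normalizers or {},
    )
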