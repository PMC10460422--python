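"""Four-driver decomposition of burden change by stepwise introduction.

The change in attributable deaths between two time points is attributed to
four drivers — age structure, total population, air quality (entering
through the attributable fraction), and cause-specific mortality — by
walking from the start state to the end state, replacing one factor at a
time and recording the resulting change.  Because contributions depend on
the order of introduction, all 4! = 24 orderings are enumerated and each
factor's contribution is averaged across them; per ordering the four
contributions telescope exactly to the net change, so the averages do too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations

import pandas as pd

FACTORS = ("age_structure", "population", "air_quality", "mortality")


@dataclass(frozen=True)
class FactorState:
    """A complete input snapshot at one time point.

    ``agep`` is indexed by (region, age); ``pop`` by region; ``paf`` and
    ``rate`` by (region, disease, age).  Air quality enters through the
    attributable fraction: the concentration -> relative risk -> PAF
    composition is evaluated before decomposition, so swapping the PAF
    table swaps the air-quality state wholesale and the factorisation of
    the death equation stays exact.
    """

    agep: pd.Series
    pop: pd.Series
    paf: pd.Series
    rate: pd.Series

    def __post_init__(self) -> None:
        for name, series, levels in (
            ("agep", self.agep, ("region", "age")),
            ("pop", self.pop, ("region",)),
            ("paf", self.paf, ("region", "disease", "age")),
            ("rate", self.rate, ("region", "disease", "age")),
        ):
            got = tuple(series.index.names)
            if got != levels:
                raise ValueError(
                    f"FactorState.{name} must be indexed by {levels}, got {got}")

    def replace_factor(self, factor: str, other: "FactorState") -> "FactorState":
        if factor == "age_structure":
            return replace(self, agep=other.agep)
        if factor == "population":
            return replace(self, pop=other.pop)
        if factor == "air_quality":
            return replace(self, paf=other.paf)
        if factor == "mortality":
            return replace(self, rate=other.rate)
        raise ValueError(f"unknown factor {factor!r}")


def dapp_total(state: FactorState) -> float:
    """Total attributable deaths of a state: sum PAF*POP*Rate*AgeP."""
    df = state.paf.rename("paf").reset_index()
    df = df.merge(state.rate.rename("rate").reset_index(),
                  on=["region", "disease", "age"], validate="1:1")
    df = df.merge(state.agep.rename("agep").reset_index(),
                  on=["region", "age"], validate="m:1")
    df = df.merge(state.pop.rename("pop").reset_index(),
                  on=["region"], validate="m:1")
    if df.isna().any().any():
        raise ValueError("factor components are not index-aligned")
    return float((df["paf"] * df["pop"] * df["rate"] * df["agep"]).sum())


@dataclass
class DecompositionResult:
    """Averaged factor contributions plus the per-ordering audit trail."""

    contributions: dict[str, float]
    per_ordering: dict[tuple[str, ...], dict[str, float]]
    net_change: float
    start_total: float = 0.0
    end_total: float = 0.0
    period: tuple[int, int] | None = None

    @property
    def n_orderings(self) -> int:
        return len(self.per_ordering)

    def to_frame(self) -> pd.DataFrame:
        gross_increase = sum(v for v in self.contributions.values() if v > 0)
        rows = []
        for factor in FACTORS:
            c = self.contributions[factor]
            rows.append({
                "factor": factor,
                "contribution_deaths": c,
                "share_of_gross_increase":
                    c / gross_increase if gross_increase > 0 and c > 0 else 0.0,
            })
        df = pd.DataFrame(rows)
        if self.period is not None:
            df.insert(0, "period", f"{self.period[0]}-{self.period[1]}")
        return df


def contribution_for_ordering(
    start: FactorState,
    end: FactorState,
    ordering: tuple[str, ...],
) -> dict[str, float]:
    """Factor contributions along one introduction order.

    At step k the k-th factor's start value is replaced by its end value
    and the death total recomputed; the factor's contribution is the
    difference between the post- and pre-introduction totals.
    """
    if sorted(ordering) != sorted(FACTORS):
        raise ValueError(
            f"ordering must be a permutation of {FACTORS}, got {ordering}")
    state = start
    previous = dapp_total(state)
    contributions: dict[str, float] = {}
    for factor in ordering:
        state = state.replace_factor(factor, end)
        current = dapp_total(state)
        contributions[factor] = current - previous
        previous = current
    return contributions


def _aligned_arrays(start: FactorState, end: FactorState):
    """Start/end value arrays for each factor on one master stratum index."""
    master = start.paf.index
    if not master.equals(end.paf.index.reorder_levels(master.names)):
        end_paf = end.paf.reindex(master)
    else:
        end_paf = end.paf
    ra = pd.MultiIndex.from_arrays(
        [master.get_level_values("region"), master.get_level_values("age")],
        names=("region", "age"))
    regions = master.get_level_values("region")
    out = {}
    for name, s0, s1, idx in (
        ("air_quality", start.paf, end_paf, master),
        ("mortality", start.rate, end.rate, master),
        ("age_structure", start.agep, end.agep, ra),
        ("population", start.pop, end.pop, regions),
    ):
        a0 = s0.reindex(idx).to_numpy(dtype=float)
        a1 = s1.reindex(idx).to_numpy(dtype=float)
        if pd.isna(a0).any() or pd.isna(a1).any():
            raise ValueError(f"factor {name!r} is not index-aligned across states")
        out[name] = (a0, a1)
    return out


def decompose(start: FactorState, end: FactorState) -> DecompositionResult:
    """Average factor contributions over all 24 introduction orders."""
    arrays = _aligned_arrays(start, end)

    cache: dict[frozenset, float] = {}

    def total(at_end: frozenset[str]) -> float:
        if at_end not in cache:
            value = None
            for name, (a0, a1) in arrays.items():
                a = a1 if name in at_end else a0
                value = a if value is None else value * a
            cache[at_end] = float(value.sum())
        return cache[at_end]

    per_ordering: dict[tuple[str, ...], dict[str, float]] = {}
    for ordering in permutations(FACTORS):
        introduced: set[str] = set()
        previous = total(frozenset())
        contributions: dict[str, float] = {}
        for factor in ordering:
            introduced.add(factor)
            current = total(frozenset(introduced))
            contributions[factor] = current - previous
            previous = current
        per_ordering[ordering] = contributions
    averaged = {
        f: sum(c[f] for c in per_ordering.values()) / len(per_ordering)
        for f in FACTORS
    }
    start_total = total(frozenset())
    end_total = total(frozenset(FACTORS))
    return DecompositionResult(
        contributions=averaged,
        per_ordering=per_ordering,
        net_change=end_total - start_total,
        start_total=start_total,
        end_total=end_total,
    )


def period_decomposition(
    states_by_year: dict[int, FactorState],
    periods: list[tuple[int, int]],
) -> list[DecompositionResult]:
    """Decompose between the endpoint years of each period.

    Net changes are additive across consecutive periods (the death totals
    telescope), but per-factor contributions are path dependent and need
    not sum across sub-periods to the full-period contribution.
    """
    results = []
    for y0, y1 in periods:
        for y in (y0, y1):
            if y not in states_by_year:
                raise ValueError(f"no factor state for endpoint year {y}")
        res = decompose(states_by_year[y0], states_by_year[y1])
        res.period = (y0, y1)
        results.append(res)
    return results
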