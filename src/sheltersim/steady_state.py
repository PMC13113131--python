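"""Deterministic steady-state census and flow allocation across kennel tiers.

At steady state each track's intake rate equals its adoption rate, and for
every (tier, track) cell Little's law ties the expected in-care census to
the adoption flow through the cell:

    census = flow x LOS_cell,        LOS_cell = 1 + 1 / (A_tier x D_track)

The allocator is a greedy waterfall.  Tiers are processed in preference
order (rank 1 first).  Within a tier, the priority track's remaining
intake flow is placed before the other tracks'.  A track with remaining
flow ``f`` placed in a tier with remaining census capacity ``c`` receives
flow ``min(f, c / LOS_cell)`` -- i.e. the tier fills to capacity before
any flow spills to the next tier.  Leftover flow lands in the unbounded
overflow tier; if no tier is unbounded and capacity runs out, the
scenario is infeasible and an error reports the unplaced flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import Scenario

__all__ = [
    "InfeasibleScenarioError",
    "SteadyStateTableau",
    "solve_steady_state",
    "census_gap",
]


class InfeasibleScenarioError(RuntimeError):
    """Total intake flow cannot be housed within the configured capacities."""

    def __init__(self, unplaced: dict[str, float]):
        self.unplaced = unplaced
        detail = ", ".join(f"{k}: {v:.4g}/day" for k, v in unplaced.items())
        super().__init__(
            f"steady-state flow cannot be fully placed (no unbounded overflow "
            f"tier and capacities exhausted); unplaced intake flow: {detail}"
        )


@dataclass(frozen=True)
class SteadyStateTableau:
    """Census and adoption flow per (tier, track) cell at steady state.

    ``census`` and ``flow`` are DataFrames indexed by tier name (in
    preference order) with one column per track.  Census counts are
    expectations and may be fractional.
    """

    census: pd.DataFrame
    flow: pd.DataFrame
    priority: str

    @property
    def tier_census(self) -> pd.Series:
        return self.census.sum(axis=1)

    @property
    def track_census(self) -> pd.Series:
        return self.census.sum(axis=0)

    @property
    def total_census(self) -> float:
        return float(self.census.to_numpy().sum())

    @property
    def tier_flow(self) -> pd.Series:
        return self.flow.sum(axis=1)

    @property
    def total_flow(self) -> float:
        return float(self.flow.to_numpy().sum())

    def to_long(self) -> pd.DataFrame:
        """Long-format table: priority, tier, track, census, flow."""
        rows = []
        for tier in self.census.index:
            for track in self.census.columns:
                rows.append(
                    {
                        "priority": self.priority,
                        "tier": tier,
                        "track": track,
                        "census": self.census.loc[tier, track],
                        "flow": self.flow.loc[tier, track],
                    }
                )
        return pd.DataFrame(rows)


def solve_steady_state(scenario: Scenario) -> SteadyStateTableau:
    """Run the greedy waterfall allocator for the scenario's priority mode."""
    tiers = scenario.tiers  # already in rank order
    tier_names = [t.name for t in tiers]
    track_names = [t.name for t in scenario.tracks]
    census = pd.DataFrame(0.0, index=tier_names, columns=track_names)
    flow = pd.DataFrame(0.0, index=tier_names, columns=track_names)

    remaining_flow = {t.name: t.intake_rate for t in scenario.tracks}
    ordered_tracks = scenario.tracks_by_priority()

    for tier in tiers:
        remaining_capacity = np.inf if tier.unbounded else float(tier.capacity)
        for track in ordered_tracks:
            f = remaining_flow[track.name]
            if f <= 0 or remaining_capacity <= 0:
                continue
            los = scenario.cell_los(tier, track)
            placed = f if tier.unbounded else min(f, remaining_capacity / los)
            flow.loc[tier.name, track.name] = placed
            census.loc[tier.name, track.name] = placed * los
            remaining_flow[track.name] = f - placed
            remaining_capacity -= placed * los

    unplaced = {k: v for k, v in remaining_flow.items() if v > 1e-12}
    if unplaced:
        raise InfeasibleScenarioError(unplaced)
    return SteadyStateTableau(census=census, flow=flow, priority=scenario.priority)


def census_gap(scenario: Scenario) -> float:
    """Total steady-state census under F priority minus under S priority.

    Positive values mean the shelter holds fewer animals when slow-track
    animals get the preferred kennels.
    """
    total_s = solve_steady_state(scenario.with_priority("S")).total_census
    total_f = solve_steady_state(scenario.with_priority("F")).total_census
    return total_f - total_s
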