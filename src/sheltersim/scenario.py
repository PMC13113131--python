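"""Shelter scenario definition: kennel tiers, animal tracks, priority policy.

A scenario describes a shelter as

* a set of *kennel tiers*, each with a capacity and a multiplicative
  adoption-odds factor ``A`` (spotlight and showcase kennels boost odds,
  non-viewable overflow housing penalizes them), ranked by preference;
* a set of *animal tracks* -- homogeneous classes such as slow-track and
  fast-track -- each with a baseline expected LOS (in a standard,
  ``A = 1`` kennel) and a mean daily intake rate; and
* a *priority mode*: ``"S"`` assigns slow-track animals (longest baseline
  LOS first) preferentially to the best-ranked kennels, ``"F"`` assigns
  fast-track animals first.

Scenarios round-trip through a small YAML schema (see :func:`save_scenario`)
so that experiments are reproducible from a version-controlled text file.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import yaml

from .los import expected_los, los_to_odds

__all__ = [
    "ScenarioError",
    "TrackProfile",
    "KennelTier",
    "Scenario",
    "load_scenario",
    "save_scenario",
    "example_scenario",
]

PRIORITY_MODES = ("S", "F")


class ScenarioError(ValueError):
    """A scenario failed validation; the message names the offending field."""


@dataclass(frozen=True)
class TrackProfile:
    """An animal class with a baseline expected LOS and intake rate.

    ``baseline_los`` is the expected stay, in days, in a reference
    (``A = 1``) kennel; it must exceed 1 day.  ``intake_rate`` is the mean
    number of such animals arriving per day.
    """

    name: str
    baseline_los: float
    intake_rate: float

    @property
    def baseline_odds(self) -> float:
        """Daily adoption odds implied by the baseline LOS."""
        return los_to_odds(self.baseline_los)


@dataclass(frozen=True)
class KennelTier:
    """A housing tier: capacity, odds multiplier, and preference rank.

    ``capacity`` is a whole number of kennels, or ``None`` for the
    unbounded overflow tier.  ``multiplier`` is the tier's effect ``A`` on
    an occupant's daily adoption odds.  ``rank`` 1 is the most preferred.
    """

    name: str
    capacity: int | None
    multiplier: float
    rank: int

    @property
    def unbounded(self) -> bool:
        return self.capacity is None


@dataclass(frozen=True)
class Scenario:
    """A complete model input: tiers + tracks + priority mode.

    Tiers are stored sorted by rank.  Validation runs on construction and
    raises :class:`ScenarioError` on the first violated invariant.
    """

    tiers: tuple[KennelTier, ...]
    tracks: tuple[TrackProfile, ...]
    priority: str = "S"

    def __post_init__(self):
        object.__setattr__(
            self, "tiers", tuple(sorted(self.tiers, key=lambda t: t.rank))
        )
        object.__setattr__(self, "tracks", tuple(self.tracks))
        self._validate()

    def _validate(self) -> None:
        if self.priority not in PRIORITY_MODES:
            raise ScenarioError(
                f"priority must be one of {PRIORITY_MODES}, got {self.priority!r}"
            )
        if not self.tiers:
            raise ScenarioError("tiers: at least one kennel tier is required")
        if not self.tracks:
            raise ScenarioError("tracks: at least one animal track is required")

        names = [t.name for t in self.tiers]
        if len(set(names)) != len(names):
            raise ScenarioError(f"tiers: duplicate tier names in {names}")
        ranks = [t.rank for t in self.tiers]
        if sorted(ranks) != list(range(1, len(ranks) + 1)):
            raise ScenarioError(
                f"tiers: ranks must be unique and contiguous from 1, got {sorted(ranks)}"
            )
        unbounded = [t for t in self.tiers if t.unbounded]
        if len(unbounded) > 1:
            raise ScenarioError(
                "tiers: at most one tier (the overflow tier) may be unbounded"
            )
        if unbounded and unbounded[0].rank != len(self.tiers):
            raise ScenarioError(
                f"tiers: the unbounded overflow tier {unbounded[0].name!r} must have "
                "the lowest preference (highest rank number)"
            )
        for tier in self.tiers:
            if tier.capacity is not None and (
                tier.capacity < 0 or tier.capacity != int(tier.capacity)
            ):
                raise ScenarioError(
                    f"tiers[{tier.name}].capacity: must be a whole number >= 0 "
                    f"or unbounded, got {tier.capacity!r}"
                )
            if not tier.multiplier > 0:
                raise ScenarioError(
                    f"tiers[{tier.name}].multiplier: must be > 0, got {tier.multiplier!r}"
                )

        track_names = [t.name for t in self.tracks]
        if len(set(track_names)) != len(track_names):
            raise ScenarioError(f"tracks: duplicate track names in {track_names}")
        for track in self.tracks:
            if not track.baseline_los > 1:
                raise ScenarioError(
                    f"tracks[{track.name}].baseline_los_days: must exceed 1 day, "
                    f"got {track.baseline_los!r}"
                )
            if track.intake_rate < 0:
                raise ScenarioError(
                    f"tracks[{track.name}].intake_per_day: must be >= 0, "
                    f"got {track.intake_rate!r}"
                )

    # -- lookups -----------------------------------------------------------

    def tier(self, name: str) -> KennelTier:
        for t in self.tiers:
            if t.name == name:
                return t
        raise KeyError(f"unknown tier {name!r}")

    def track(self, name: str) -> TrackProfile:
        for t in self.tracks:
            if t.name == name:
                return t
        raise KeyError(f"unknown track {name!r}")

    def tracks_by_priority(self) -> tuple[TrackProfile, ...]:
        """Tracks in assignment-priority order for this scenario's mode.

        ``"S"`` orders tracks by baseline LOS descending (slowest first),
        ``"F"`` ascending; ties keep the configured track order.
        """
        reverse = self.priority == "S"
        return tuple(
            sorted(self.tracks, key=lambda t: t.baseline_los, reverse=reverse)
        )

    def with_priority(self, priority: str) -> "Scenario":
        return replace(self, priority=priority)

    def effective_odds(self, tier: KennelTier | str, track: TrackProfile | str) -> float:
        """Daily adoption odds in a cell: tier multiplier x baseline odds."""
        tier = self.tier(tier) if isinstance(tier, str) else self.tier(tier.name)
        track = self.track(track) if isinstance(track, str) else self.track(track.name)
        return tier.multiplier * track.baseline_odds

    def cell_los(self, tier: KennelTier | str, track: TrackProfile | str) -> float:
        """Expected LOS of a track's animals housed in a tier."""
        return expected_los(self.effective_odds(tier, track))


def effective_odds(scenario: Scenario, tier, track) -> float:
    """Module-level alias for :meth:`Scenario.effective_odds`."""
    return scenario.effective_odds(tier, track)


def _tier_from_mapping(item: dict, default_rank: int | None) -> KennelTier:
    try:
        name = item["name"]
        capacity = item["capacity"]
        multiplier = float(item["multiplier"])
    except KeyError as exc:
        raise ScenarioError(f"tiers: missing required field {exc.args[0]!r}") from exc
    if isinstance(capacity, str):
        if capacity.lower() != "unbounded":
            raise ScenarioError(
                f"tiers[{name}].capacity: expected a number or 'unbounded', "
                f"got {capacity!r}"
            )
        capacity = None
    rank = item.get("rank", default_rank)
    if rank is None:
        raise ScenarioError(f"tiers[{name}].rank: missing and no default applies")
    return KennelTier(name=name, capacity=capacity, multiplier=multiplier, rank=int(rank))


def _scenario_from_mapping(doc: dict) -> Scenario:
    if not isinstance(doc, dict) or "scenario" not in doc:
        raise ScenarioError("config: top-level 'scenario' mapping is missing")
    body = doc["scenario"]
    for key in ("tiers", "tracks", "priority"):
        if key not in body:
            raise ScenarioError(f"scenario.{key}: missing required field")

    raw_tiers = body["tiers"]
    # default preference order: descending odds multiplier
    default_ranks: list[int | None]
    if any("rank" in t for t in raw_tiers):
        default_ranks = [None] * len(raw_tiers)
    else:
        order = sorted(
            range(len(raw_tiers)),
            key=lambda i: -float(raw_tiers[i].get("multiplier", 0.0)),
        )
        default_ranks = [0] * len(raw_tiers)
        for rank, i in enumerate(order, start=1):
            default_ranks[i] = rank
    tiers = [
        _tier_from_mapping(item, default_ranks[i]) for i, item in enumerate(raw_tiers)
    ]

    tracks = []
    for item in body["tracks"]:
        try:
            tracks.append(
                TrackProfile(
                    name=item["name"],
                    baseline_los=float(item["baseline_los_days"]),
                    intake_rate=float(item["intake_per_day"]),
                )
            )
        except KeyError as exc:
            raise ScenarioError(
                f"tracks: missing required field {exc.args[0]!r}"
            ) from exc

    return Scenario(tiers=tuple(tiers), tracks=tuple(tracks), priority=body["priority"])


def load_scenario(path: str | Path) -> Scenario:
    """Read and validate a scenario from a YAML config file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ScenarioError(f"config: {path} is not valid YAML: {exc}") from exc
    return _scenario_from_mapping(doc)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario to the YAML config schema (round-trips exactly)."""
    doc = {
        "scenario": {
            "priority": scenario.priority,
            "tiers": [
                {
                    "name": t.name,
                    "capacity": "unbounded" if t.unbounded else t.capacity,
                    "multiplier": t.multiplier,
                    "rank": t.rank,
                }
                for t in scenario.tiers
            ],
            "tracks": [
                {
                    "name": t.name,
                    "baseline_los_days": t.baseline_los,
                    "intake_per_day": t.intake_rate,
                }
                for t in scenario.tracks
            ],
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def example_scenario(priority: str = "S") -> Scenario:
    """The bundled two-track, four-tier example shelter.

    One spotlight kennel (``A = 3``), 7 showcase kennels (``A = 1.5``),
    18 standard kennels (``A = 1``) and unbounded non-viewable overflow
    housing (``A = 0.5``); a slow track with baseline LOS 27 days and a
    fast track with baseline LOS 3 days, each averaging one intake per day.
    """
    ref = resources.files("sheltersim").joinpath("data/example_shelter.yaml")
    with resources.as_file(ref) as path:
        scenario = load_scenario(path)
    return scenario.with_priority(priority)
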