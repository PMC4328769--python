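"""Divergence scenarios: rooted population-split histories.

A scenario lists sampled regions (leaves), a set of backward-in-time merge
events (derived region folds into an ancestral region, which keeps its
label and effective size), and per-region effective sizes.  This covers
pure-divergence histories: no migration, no admixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime

from .errors import ConfigurationError

#: region label shorthands used throughout: BF = Black Forest,
#: MC = Massif Central, PY = Pyrenees, CM = Cantabrian Mountains
REGIONS = ("BF", "CM", "MC", "PY")


@dataclass(frozen=True)
class MergeEvent:
    """Backward in time at `time` generations, `derived` folds into `ancestral`."""

    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class Scenario:
    name: str
    leaves: tuple[str, ...]
    events: tuple[MergeEvent, ...]
    sizes: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        object.__setattr__(
            self,
            "events",
            tuple(e if isinstance(e, MergeEvent) else MergeEvent(*e) for e in self.events),
        )
        self.validate()

    def validate(self) -> None:
        if len(set(self.leaves)) != len(self.leaves):
            raise ConfigurationError("duplicate leaf labels")
        for r in self.leaves:
            if r not in self.sizes:
                raise ConfigurationError(f"no effective size for region {r!r}")
            if self.sizes[r] <= 0:
                raise ConfigurationError(f"non-positive N_e for region {r!r}")
        active = set(self.leaves)
        last_time = {r: 0.0 for r in self.leaves}
        for ev in sorted(self.events, key=lambda e: e.time):
            if ev.time <= 0:
                raise ConfigurationError("merge times must be positive")
            if ev.derived == ev.ancestral:
                raise ConfigurationError(f"self-merge of {ev.derived!r}")
            if ev.derived not in active:
                raise ConfigurationError(
                    f"region {ev.derived!r} merges twice or is unknown"
                )
            if ev.ancestral not in active:
                raise ConfigurationError(
                    f"ancestral region {ev.ancestral!r} not active at t={ev.time}"
                )
            if ev.time <= last_time[ev.derived] or ev.time <= last_time[ev.ancestral]:
                raise ConfigurationError(
                    "event times must strictly increase along every root path"
                )
            active.discard(ev.derived)
            last_time[ev.ancestral] = ev.time
        if len(active) != 1:
            raise ConfigurationError(
                f"history must leave exactly one root lineage, got {sorted(active)}"
            )

    @property
    def root_region(self) -> str:
        active = set(self.leaves)
        for ev in sorted(self.events, key=lambda e: e.time):
            active.discard(ev.derived)
        (root,) = active
        return root

    def join_times(self) -> dict[frozenset, float]:
        """Earliest time at which each pair of leaf regions shares a deme."""
        comp = {r: {r} for r in self.leaves}
        joined: dict[frozenset, float] = {}
        for ev in sorted(self.events, key=lambda e: e.time):
            a, b = comp[ev.derived], comp[ev.ancestral]
            for x in a:
                for y in b:
                    joined[frozenset((x, y))] = ev.time
            merged = a | b
            for r in merged:
                comp[r] = merged
        return joined

    @property
    def depth_levels(self) -> int:
        """Number of distinct merge times (tree depth in event layers)."""
        return len({e.time for e in self.events})

    def with_parameters(
        self, sizes: dict[str, float] | None = None, times: list[float] | None = None
    ) -> "Scenario":
        """Same topology with new sizes and/or event times.

        `times` are assigned to the events in the order of the template's
        event times; they must preserve the root-path ordering (validated).
        """
        new_sizes = dict(self.sizes if sizes is None else sizes)
        events = sorted(self.events, key=lambda e: e.time)
        if times is not None:
            if len(times) != len(events):
                raise ConfigurationError("need one time per merge event")
            events = [replace(e, time=t) for e, t in zip(events, sorted(times))]
        return Scenario(self.name, self.leaves, tuple(events), new_sizes)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        """Build a scenario from a JSON-style mapping.

        Expected keys: name, leaves, events (list of [time, derived,
        ancestral]), sizes (region -> N_e)."""
        try:
            events = tuple(MergeEvent(float(t), str(a), str(b)) for t, a, b in d["events"])
            return cls(str(d["name"]), tuple(d["leaves"]), events,
                       {str(k): float(v) for k, v in d["sizes"].items()})
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed scenario config: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "leaves": list(self.leaves),
            "events": [[e.time, e.derived, e.ancestral] for e in self.events],
            "sizes": dict(self.sizes),
        }

    def demography(self, size_scale: float = 1.0) -> msprime.Demography:
        """msprime demography for this scenario.

        `size_scale` rescales every effective size (the mitochondrial
        genome uses 1/4 of the nuclear effective size; see simulate).
        """
        demog = msprime.Demography()
        for r in self.leaves:
            demog.add_population(name=r, initial_size=self.sizes[r] * size_scale)
        for ev in sorted(self.events, key=lambda e: e.time):
            demog.add_mass_migration(
                time=ev.time, source=ev.derived, dest=ev.ancestral, proportion=1.0
            )
        return demog


def scenario_library(
    ne: float = 10_000.0,
    times: tuple[float, float, float] = (100_000.0, 400_000.0, 1_200_000.0),
) -> dict[str, Scenario]:
    """The three text-described phylogeographic scenarios as built-ins.

    - scenario_6 : vicariance, ((CM,PY),(MC,BF)) — an ancestral north/south
      split, with the within-group splits more recent;
    - scenario_17: gradual colonization from the Cantabrian Mountains,
      (CM,(PY,(MC,BF)));
    - scenario_20: gradual colonization from the Pyrenees,
      (PY,(CM,(MC,BF))).

    `ne` and `times` give the default deep-split parameterization; ABC
    replaces them with prior draws.
    """
    sizes = {r: ne for r in REGIONS}
    t1, t2, t3 = times
    lib = {
        # the two within-group splits share one depth level
        "scenario_6": Scenario(
            "scenario_6",
            REGIONS,
            (
                MergeEvent(t1, "BF", "MC"),
                MergeEvent(t1, "PY", "CM"),
                MergeEvent(t3, "MC", "CM"),
            ),
            sizes,
        ),
        "scenario_17": Scenario(
            "scenario_17",
            REGIONS,
            (
                MergeEvent(t1, "BF", "MC"),
                MergeEvent(t2, "MC", "PY"),
                MergeEvent(t3, "PY", "CM"),
            ),
            sizes,
        ),
        "scenario_20": Scenario(
            "scenario_20",
            REGIONS,
            (
                MergeEvent(t1, "BF", "MC"),
                MergeEvent(t2, "MC", "CM"),
                MergeEvent(t3, "CM", "PY"),
            ),
            sizes,
        ),
    }
    return lib
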