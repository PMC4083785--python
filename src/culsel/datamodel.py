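"""Core data model for coded micro-society communication games.

The unit of analysis is a :class:`DataStructure`: the full record of how one
concept was communicated within one isolated micro-society — a grid of coded
variant labels with one production per participant per generation, together
with the pairing schedule (who talked to whom in each generation) and the
draw order within each pair (who produced first).

Generations here are rounds of pairwise interaction, not birth/death
turnover: the same people interact throughout, switching partners each round
in a round-robin so that everyone eventually interacts with everyone else.

Indexing is 0-based internally; serialization uses 1-based participant and
generation numbers (see :mod:`culsel.io`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

__all__ = [
    "VariantLabel",
    "PairingSchedule",
    "DataStructure",
    "Corpus",
    "ValidationError",
    "validate_schedule",
]

# A coded variant type is just an opaque, non-empty string token.
VariantLabel = str


class ValidationError(ValueError):
    """A data structure or schedule violated a structural invariant."""


@dataclass(frozen=True)
class PairingSchedule:
    """Who interacts with whom, and who produces first, in each generation.

    Parameters
    ----------
    rounds
        One entry per generation; each entry partitions the participant ids
        ``0..n-1`` into unordered pairs, stored as sorted tuples.
    second_drawers
        Aligned with ``rounds``: for each pair, the id of the member that
        produced *second* in that interaction.
    """

    rounds: tuple[tuple[tuple[int, int], ...], ...]
    second_drawers: tuple[tuple[int, ...], ...]

    @property
    def n_generations(self) -> int:
        return len(self.rounds)

    def partner_of(self, participant: int, generation: int) -> int:
        for a, b in self.rounds[generation]:
            if participant == a:
                return b
            if participant == b:
                return a
        raise KeyError(f"participant {participant} not scheduled in generation {generation}")

    def drew_second(self, participant: int, generation: int) -> bool:
        return participant in self.second_drawers[generation]


def validate_schedule(schedule: PairingSchedule, n: int, g: int) -> list[str]:
    """Check a pairing schedule against the round-robin game rules.

    Returns a list of human-readable violations (empty iff valid):

    * each generation must be a perfect matching of the ``n`` participants;
    * no unordered pair may recur before a full round-robin cycle completes
      (each pair at most ``ceil(g / (n - 1))`` times; for the canonical
      8-participant, 7-generation game this means every one of the 28 pairs
      occurs exactly once);
    * exactly one member of each pair is flagged as having drawn second.
    """
    violations: list[str] = []
    if len(schedule.rounds) != g:
        violations.append(f"expected {g} rounds, found {len(schedule.rounds)}")
    if len(schedule.second_drawers) != len(schedule.rounds):
        violations.append("second_drawers not aligned with rounds")
        return violations

    all_ids = set(range(n))
    pair_counts: dict[tuple[int, int], int] = {}
    for r, (pairs, seconds) in enumerate(zip(schedule.rounds, schedule.second_drawers)):
        seen: list[int] = []
        for a, b in pairs:
            if a == b:
                violations.append(f"round {r}: participant {a} paired with itself")
            seen.extend((a, b))
            key = (min(a, b), max(a, b))
            pair_counts[key] = pair_counts.get(key, 0) + 1
        if sorted(seen) != sorted(all_ids):
            violations.append(
                f"round {r}: not a perfect matching of participants 0..{n - 1}"
            )
        if len(seconds) != len(pairs):
            violations.append(f"round {r}: need one second-drawer per pair")
        else:
            for (a, b), s in zip(pairs, seconds):
                if s not in (a, b):
                    violations.append(
                        f"round {r}: second drawer {s} not a member of pair ({a},{b})"
                    )

    if n > 1:
        max_repeats = math.ceil(g / (n - 1))
        for (a, b), count in sorted(pair_counts.items()):
            if count > max_repeats:
                violations.append(
                    f"round-robin violated: pair ({a},{b}) occurs {count} times "
                    f"(at most {max_repeats} allowed for {n} participants over {g} rounds)"
                )
    return violations


@dataclass
class DataStructure:
    """All coded productions of one concept in one micro-society.

    ``productions[g][p]`` is the variant label produced by participant ``p``
    in generation ``g`` (0-based). The canonical experiment has 8
    participants and 7 generations, i.e. 56 productions; smaller structures
    are allowed for testing.
    """

    society_id: str
    concept_id: str
    productions: tuple[tuple[VariantLabel, ...], ...]
    schedule: PairingSchedule
    universe: frozenset[VariantLabel] = field(default=frozenset())
    n_participants: int = 8
    n_generations: int = 7

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset(self.attested_labels())

    def attested_labels(self) -> set[VariantLabel]:
        return {label for row in self.productions for label in row}

    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first broken invariant."""
        ident = f"data structure ({self.society_id}, {self.concept_id})"
        expected = self.n_participants * self.n_generations
        got = sum(len(row) for row in self.productions)
        if len(self.productions) != self.n_generations or got != expected:
            raise ValidationError(
                f"{ident}: expected {expected} productions "
                f"({self.n_participants} participants x {self.n_generations} "
                f"generations), found {got}"
            )
        for g, row in enumerate(self.productions):
            if len(row) != self.n_participants:
                raise ValidationError(
                    f"{ident}: generation {g + 1} has {len(row)} productions, "
                    f"expected {self.n_participants}"
                )
        for row in self.productions:
            for label in row:
                if not label:
                    raise ValidationError(f"{ident}: empty variant label")
                if label not in self.universe:
                    raise ValidationError(
                        f"{ident}: label {label!r} not in declared universe"
                    )
        missing = self.attested_labels() - set(self.universe)
        if missing:
            raise ValidationError(f"{ident}: labels {sorted(missing)} missing from universe")
        violations = validate_schedule(
            self.schedule, self.n_participants, self.n_generations
        )
        if violations:
            raise ValidationError(f"{ident}: round-robin violated: {violations[0]}")


@dataclass
class Corpus:
    """A collection of data structures, e.g. 4 societies x 16 concepts."""

    data_structures: list[DataStructure]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data_structures)

    def __iter__(self):
        return iter(self.data_structures)

    def validate(self) -> None:
        keys = [(d.society_id, d.concept_id) for d in self.data_structures]
        dupes = [k for k, group in itertools.groupby(sorted(keys)) if len(list(group)) > 1]
        if dupes:
            raise ValidationError(f"duplicate (society, concept) identifiers: {dupes}")
        for d in self.data_structures:
            d.validate()
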