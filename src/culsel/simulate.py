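"""Forward simulation of micro-society communication games.

Generates corpora with exactly the statistical structure the inference
assumes: ``n_societies x n_concepts`` data structures, each an
``n_participants x n_generations`` grid filled pair by pair under the
choice model with known (true) parameters. This provides the synthetic
stand-in for the original laboratory corpus and makes the whole pipeline
testable by parameter recovery.

Generation 1 is not governed by the choice model (the likelihood ignores
it and the model defines no memory-free choice); it is filled by an
initialization rule. The default draws each participant's first variant
uniformly from a universe of K = 7 potential labels, which for 8 draws
gives an expected initial diversity of about 4.2 distinct types —
comparable to the starting diversity of the laboratory micro-societies.
Within-generation-1 convergence between partners is deliberately not
simulated: the likelihood never evaluates generation-1 choices, so its
internal structure is irrelevant to inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .choice_model import History, ParameterSetting, choice_distribution
from .datamodel import Corpus, DataStructure, PairingSchedule, VariantLabel

__all__ = [
    "SimulationConfig",
    "round_robin_schedule",
    "simulate_data_structure",
    "simulate_corpus",
    "diversity_trajectory",
]

INIT_RULES = ("uniform_over_K", "all_distinct", "fixed_assignment")
TAU_RULES = ("fixed", "random_g1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design plus true generative parameters.

    Defaults mirror the laboratory setup: four 8-person micro-societies,
    each communicating 16 concepts over 7 generations (64 data structures,
    3584 productions). ``universe_size`` is the number of potential variant
    labels K; mutation draws uniformly from all K labels, so extinct or
    never-seen variants can (re)appear.

    ``tau_rule`` controls the content-bias target when ``true_params.b > 0``:
    ``"fixed"`` uses ``true_params.tau`` everywhere, while ``"random_g1"``
    picks, independently per structure, a random variant among those
    attested at generation 1 — letting different societies converge on
    different variants.
    """

    true_params: ParameterSetting
    n_participants: int = 8
    n_generations: int = 7
    n_societies: int = 4
    n_concepts: int = 16
    universe_size: int = 7
    init_rule: str = "uniform_over_K"
    init_assignment: Optional[tuple[VariantLabel, ...]] = None
    tau_rule: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants % 2 != 0:
            raise ValueError("n_participants must be even (all interaction is pairwise)")
        if self.universe_size < 1:
            raise ValueError("universe_size must be at least 1")
        if self.init_rule not in INIT_RULES:
            raise ValueError(f"init_rule must be one of {INIT_RULES}")
        if self.tau_rule not in TAU_RULES:
            raise ValueError(f"tau_rule must be one of {TAU_RULES}")
        if self.init_rule == "all_distinct" and self.universe_size < self.n_participants:
            raise ValueError("all_distinct initialization needs K >= n_participants")
        if self.init_rule == "fixed_assignment" and (
            self.init_assignment is None
            or len(self.init_assignment) != self.n_participants
        ):
            raise ValueError("fixed_assignment needs one initial label per participant")
        if (
            self.true_params.b > 0
            and self.tau_rule == "fixed"
            and self.true_params.tau is None
        ):
            raise ValueError("content bias with tau_rule='fixed' requires true_params.tau")

    @property
    def universe(self) -> tuple[VariantLabel, ...]:
        return tuple(f"V{i + 1}" for i in range(self.universe_size))


def round_robin_schedule(
    n: int, g: int, rng: np.random.Generator | int | None = None
) -> PairingSchedule:
    """Circle-method round-robin pairing for ``n`` participants, ``g`` rounds.

    For ``g = n - 1`` every unordered pair occurs exactly once; for larger
    ``g`` the rotation repeats cyclically. The draw order within each pair
    is assigned uniformly at random per generation from ``rng``.
    """
    if n % 2 != 0:
        raise ValueError("round-robin pairing requires an even participant count")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # Circle method: fix participant 0, rotate the rest.
    others = list(range(1, n))
    rounds = []
    seconds = []
    for r in range(g):
        rotation = others[r % (n - 1):] + others[: r % (n - 1)]
        circle = [0] + rotation
        pairs = []
        for i in range(n // 2):
            a, b = circle[i], circle[n - 1 - i]
            pairs.append((min(a, b), max(a, b)))
        rounds.append(tuple(pairs))
        seconds.append(tuple(p[int(rng.integers(2))] for p in pairs))
    return PairingSchedule(rounds=tuple(rounds), second_drawers=tuple(seconds))


def _initial_generation(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[VariantLabel, ...]:
    universe = cfg.universe
    if cfg.init_rule == "uniform_over_K":
        return tuple(universe[i] for i in rng.integers(cfg.universe_size, size=cfg.n_participants))
    if cfg.init_rule == "all_distinct":
        picks = rng.choice(cfg.universe_size, size=cfg.n_participants, replace=False)
        return tuple(universe[i] for i in picks)
    assert cfg.init_assignment is not None
    return tuple(cfg.init_assignment)


def _sample(dist: dict[VariantLabel, float], rng: np.random.Generator) -> VariantLabel:
    labels = sorted(dist)
    probs = np.asarray([dist[lab] for lab in labels])
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def simulate_data_structure(
    cfg: SimulationConfig,
    society_id: str = "S1",
    concept_id: str = "C1",
    rng: np.random.Generator | int | None = None,
) -> DataStructure:
    """Simulate one data structure under the true parameters.

    Generation 1 is filled by the initialization rule; each later
    generation is filled pair by pair in draw order, every production
    sampled from the choice model given the producer's reconstructed
    history (the second drawer's history includes the first drawer's
    current-generation production).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    universe = frozenset(cfg.universe)
    schedule = round_robin_schedule(cfg.n_participants, cfg.n_generations, rng)

    grid: list[list[VariantLabel]] = [list(_initial_generation(cfg, rng))]
    params = cfg.true_params
    if params.b > 0 and cfg.tau_rule == "random_g1":
        g1_types = sorted(set(grid[0]))
        params = replace(params, tau=g1_types[int(rng.integers(len(g1_types)))])

    for g in range(1, cfg.n_generations):
        row: list[Optional[VariantLabel]] = [None] * cfg.n_participants
        for (a, b), second in zip(schedule.rounds[g], schedule.second_drawers[g]):
            first = b if second == a else a
            for p, partner, sees_current in ((first, second, False), (second, first, True)):
                ego = tuple(grid[past][p] for past in range(g))
                allo = [grid[past][schedule.partner_of(p, past)] for past in range(g)]
                if sees_current:
                    current = row[partner]
                    assert current is not None
                    allo.append(current)
                dist = choice_distribution(
                    History(ego=ego, allo=tuple(allo)), params, universe
                )
                row[p] = _sample(dist, rng)
        grid.append(row)  # type: ignore[arg-type]

    return DataStructure(
        society_id=society_id,
        concept_id=concept_id,
        productions=tuple(tuple(row) for row in grid),
        schedule=schedule,
        universe=universe,
        n_participants=cfg.n_participants,
        n_generations=cfg.n_generations,
    )


def simulate_corpus(cfg: SimulationConfig) -> Corpus:
    """Simulate ``n_societies x n_concepts`` independent data structures.

    Per-structure random streams are spawned deterministically from the
    master seed, so the same seed always yields the same corpus and each
    structure is independent of the others.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_societies * cfg.n_concepts)
    structures = []
    i = 0
    for s in range(cfg.n_societies):
        for c in range(cfg.n_concepts):
            rng = np.random.default_rng(children[i])
            structures.append(
                simulate_data_structure(cfg, f"S{s + 1}", f"C{c + 1}", rng)
            )
            i += 1
    meta = {
        "generator": "culsel.simulate",
        "seed": cfg.seed,
        "true_params": {
            "m": cfg.true_params.m,
            "c": cfg.true_params.c,
            "b": cfg.true_params.b,
            "tau": cfg.true_params.tau,
            "mu": cfg.true_params.mu,
        },
        "init_rule": cfg.init_rule,
        "tau_rule": cfg.tau_rule,
        "universe_size": cfg.universe_size,
    }
    return Corpus(data_structures=structures, metadata=meta)


def diversity_trajectory(d: DataStructure) -> list[int]:
    """Number of distinct variant types present at each generation."""
    return [len(set(row)) for row in d.productions]
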