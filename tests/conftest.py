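from __future__ import annotations

import pytest

from culsel import (
    DataStructure,
    PairingSchedule,
    ParameterSetting,
    SimulationConfig,
    round_robin_schedule,
    simulate_corpus,
)


@pytest.fixture
def schedule_8x7() -> PairingSchedule:
    return round_robin_schedule(8, 7, rng=0)


@pytest.fixture
def toy_structure() -> DataStructure:
    """2 participants, 3 generations, hand-laid-out productions.

    Generation 1: A, B. Generation 2 (P2 drew second): A, A.
    Generation 3 (P1 drew second): B, A.
    """
    schedule = PairingSchedule(
        rounds=(((0, 1),), ((0, 1),), ((0, 1),)),
        second_drawers=((1,), (1,), (0,)),
    )
    return DataStructure(
        society_id="S1",
        concept_id="toy",
        productions=(("A", "B"), ("A", "A"), ("B", "A")),
        schedule=schedule,
        n_participants=2,
        n_generations=3,
    )


def single_variant_structure(schedule: PairingSchedule) -> DataStructure:
    return DataStructure(
        society_id="S1",
        concept_id="mono",
        productions=tuple(tuple("A" for _ in range(8)) for _ in range(7)),
        schedule=schedule,
    )


@pytest.fixture
def mono_structure(schedule_8x7) -> DataStructure:
    return single_variant_structure(schedule_8x7)


@pytest.fixture(scope="session")
def small_corpus():
    """Six simulated structures under a moderately biased setting."""
    cfg = SimulationConfig(
        true_params=ParameterSetting(m=2, c=-0.4, b=0.5, tau=None),
        tau_rule="random_g1",
        n_societies=2,
        n_concepts=3,
        seed=42,
    )
    return simulate_corpus(cfg)
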