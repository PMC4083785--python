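"""Likelihood of a coded data structure and exhaustive ML grid search.

The conditional probability of an entire data structure under one parameter
setting is the product, over every production from generation 2 onwards, of
the probability the choice model assigns to the variant actually produced
given the producer's history at that moment. Generation-1 productions are
excluded: with no history, variant choice cannot be predicted.

History reconstruction follows the game's information structure: a
participant witnesses only their own partner's productions (interaction is
pairwise and anonymous), and the second drawer in a pair additionally
witnesses the first drawer's current-generation production before making
their own choice.

Fitting is an exhaustive search over a finite grid of parameter settings
(the full default: 4 memory sizes x 11 coordination-bias levels x 11
content-bias levels = 484 points, mutation fixed at 0.02). The content-bias
target ``tau`` is profiled out: at each (m, c, b) point with ``b > 0`` the
likelihood is maximized over candidate targets, so the grid cardinality
counts (m, c, b) points only and the winning target is reported separately.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .choice_model import History, ParameterSetting, choice_distribution, memory_windows
from .datamodel import DataStructure, VariantLabel

__all__ = [
    "ChoiceEvent",
    "GridSpec",
    "FitResult",
    "build_choice_events",
    "data_structure_loglik",
    "tau_candidates",
    "grid_search",
    "ml_settings_frame",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ChoiceEvent:
    """One modelled production: what was produced, given which history."""

    generation: int
    participant: int
    produced: VariantLabel
    history: History


def build_choice_events(d: DataStructure) -> list[ChoiceEvent]:
    """Reconstruct the history behind every production after generation 1.

    For participant ``p`` at generation ``g`` (0-based ``g >= 1``):

    * ego entries: ``p``'s own productions at generations ``0..g-1``;
    * allo entries: the production of ``p``'s partner in each generation
      ``0..g-1``, plus the current generation's partner production if and
      only if ``p`` drew second in their pair.

    Both lists are chronological. An 8x7 structure yields 48 events.
    """
    events: list[ChoiceEvent] = []
    prods = d.productions
    sched = d.schedule
    for g in range(1, d.n_generations):
        for p in range(d.n_participants):
            ego = tuple(prods[past][p] for past in range(g))
            allo = [prods[past][sched.partner_of(p, past)] for past in range(g)]
            if sched.drew_second(p, g):
                allo.append(prods[g][sched.partner_of(p, g)])
            events.append(
                ChoiceEvent(
                    generation=g,
                    participant=p,
                    produced=prods[g][p],
                    history=History(ego=ego, allo=tuple(allo)),
                )
            )
    return events


def data_structure_loglik(d: DataStructure, p: ParameterSetting) -> float:
    """Log-likelihood of one data structure at one parameter setting.

    A zero-probability event (possible only when ``mu == 0``) yields
    ``-inf`` rather than an exception, so such settings simply lose every
    model comparison.
    """
    total = 0.0
    for event in build_choice_events(d):
        prob = choice_distribution(event.history, p, d.universe)[event.produced]
        if prob <= 0.0:
            return NEG_INF
        total += math.log(prob)
    return total


def tau_candidates(d: DataStructure, cap: int = 8) -> list[VariantLabel]:
    """Candidate content-bias targets: the most frequent attested variants.

    Ordered by frequency over all productions (descending), ties broken by
    first appearance in the grid (generation-major scan), capped at ``cap``
    (default 8, the number of target levels in the full default grid).
    """
    counts: Counter[VariantLabel] = Counter()
    first_seen: dict[VariantLabel, int] = {}
    for i, label in enumerate(
        label for row in d.productions for label in row
    ):
        counts[label] += 1
        first_seen.setdefault(label, i)
    ordered = sorted(counts, key=lambda lab: (-counts[lab], first_seen[lab]))
    return ordered[:cap]


@dataclass(frozen=True)
class GridSpec:
    """The finite parameter grid searched exhaustively.

    Defaults reproduce the full default grid: m in {2, 4, 6, 8}; c from -1.0
    to 1.0 in steps of 0.2 (11 levels); b from 0.0 to 1.0 in steps of 0.1
    (11 levels); mu fixed at 0.02; at most 8 candidate targets.
    """

    m_levels: tuple[int, ...] = (2, 4, 6, 8)
    c_levels: tuple[float, ...] = tuple(round(-1.0 + 0.2 * i, 10) for i in range(11))
    b_levels: tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(11))
    mu: float = 0.02
    max_tau_candidates: int = 8

    @property
    def n_points(self) -> int:
        return len(self.m_levels) * len(self.c_levels) * len(self.b_levels)


# Model families used in best-account comparisons, defined by constraints
# on (b, c): drift is the neutral null with neither bias.
_FAMILIES = {
    "unconstrained": lambda b, c: True,
    "drift": lambda b, c: b == 0.0 and c == 0.0,
    "no_content": lambda b, c: b == 0.0,
    "no_coordination": lambda b, c: c == 0.0,
    "content": lambda b, c: b > 0.0,
    "coordination": lambda b, c: c != 0.0,
    "any_bias": lambda b, c: b > 0.0 or c != 0.0,
    "both_biases": lambda b, c: b > 0.0 and c != 0.0,
}


@dataclass
class FitResult:
    """Exhaustive-search output for one data structure."""

    society_id: str
    concept_id: str
    loglik_table: dict[tuple[int, float, float], float]
    best_tau: dict[tuple[int, float, float], Optional[VariantLabel]]
    ml_setting: ParameterSetting = field(init=False)
    ml_loglik: float = field(init=False)
    family_maxima: dict[str, float] = field(init=False)
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.family_maxima = {
            name: max(
                (ll for (m, c, b), ll in self.loglik_table.items() if member(b, c)),
                default=NEG_INF,
            )
            for name, member in _FAMILIES.items()
        }
        self.ml_loglik = self.family_maxima["unconstrained"]
        self.ml_setting = self._argmax()

    def _argmax(self) -> ParameterSetting:
        # Conservative tie-break: among (near-)maximal points prefer the one
        # closest to drift — b ascending, |c| ascending, m ascending.
        tol = 1e-9 * max(1.0, abs(self.ml_loglik))
        tau_rank = {t: i for i, t in enumerate(dict.fromkeys(self.best_tau.values()))}
        candidates = [
            key for key, ll in self.loglik_table.items() if ll >= self.ml_loglik - tol
        ]
        m, c, b = min(
            candidates,
            key=lambda key: (key[2], abs(key[1]), key[0], key[1], tau_rank[self.best_tau[key]]),
        )
        return ParameterSetting(m=m, c=c, b=b, tau=self.best_tau[(m, c, b)], mu=self.grid.mu)

    def to_record(self) -> dict:
        """Flat JSON-serializable summary (ML point and family maxima)."""
        s = self.ml_setting
        return {
            "society_id": self.society_id,
            "concept_id": self.concept_id,
            "ml_m": s.m,
            "ml_c": s.c,
            "ml_b": s.b,
            "ml_tau": s.tau,
            "mu": s.mu,
            "ml_loglik": self.ml_loglik,
            "family_maxima": dict(self.family_maxima),
            "n_grid_points": len(self.loglik_table),
        }


def _event_arrays(d: DataStructure, events: list[ChoiceEvent], m: int, taus: list[VariantLabel]):
    """Per-event quantities that the grid likelihood is linear in.

    For memory size ``m`` returns, over events ``e``: the produced variant's
    relative frequency in each memory window, emptiness flags, and per
    candidate target: whether the target is in memory and whether it was
    the variant produced.
    """
    n = len(events)
    p_ego = np.zeros(n)
    p_allo = np.zeros(n)
    both = np.zeros(n, dtype=bool)
    tau_in = np.zeros((len(taus), n), dtype=bool)
    is_tau = np.zeros((len(taus), n), dtype=bool)
    for e, ev in enumerate(events):
        ego_w, allo_w = memory_windows(ev.history, m)
        if ego_w:
            p_ego[e] = ego_w.count(ev.produced) / len(ego_w)
        if allo_w:
            p_allo[e] = allo_w.count(ev.produced) / len(allo_w)
        both[e] = bool(ego_w) and bool(allo_w)
        for t, tau in enumerate(taus):
            tau_in[t, e] = tau in ego_w or tau in allo_w
            is_tau[t, e] = ev.produced == tau
    return p_ego, p_allo, both, tau_in, is_tau


def grid_search(d: DataStructure, grid: GridSpec | None = None) -> FitResult:
    """Evaluate the log-likelihood at every (m, c, b) grid point.

    At points with ``b > 0`` the content-bias target is profiled out
    (maximized over :func:`tau_candidates`). The computation is vectorized
    over events and the (c, b) plane; it agrees with per-event evaluation
    via :func:`data_structure_loglik` to floating-point accuracy.
    """
    if grid is None:
        grid = GridSpec()
    events = build_choice_events(d)
    taus = tau_candidates(d, cap=grid.max_tau_candidates)
    k = len(d.universe)
    mu, flat = grid.mu, grid.mu / k
    c_arr = np.asarray(grid.c_levels)
    gamma = (c_arr + 1.0) / 2.0
    b_pos = [b for b in grid.b_levels if b > 0.0]
    b_arr = np.asarray(b_pos)

    table: dict[tuple[int, float, float], float] = {}
    best_tau: dict[tuple[int, float, float], Optional[VariantLabel]] = {}
    with np.errstate(divide="ignore"):
        for m in grid.m_levels:
            p_ego, p_allo, both, tau_in, is_tau = _event_arrays(d, events, m, taus)
            # base[c, e]: probability of the produced variant under memory
            # mixing alone; empty windows give all weight to the other side.
            mixed = (1.0 - gamma)[:, None] * p_ego[None, :] + gamma[:, None] * p_allo[None, :]
            base = np.where(both[None, :], mixed, (p_ego + p_allo)[None, :])
            if 0.0 in grid.b_levels:
                ll0 = np.log((1.0 - mu) * base + flat).sum(axis=1)
                for ci, c in enumerate(grid.c_levels):
                    table[(m, c, 0.0)] = float(ll0[ci])
                    best_tau[(m, c, 0.0)] = None
            if b_pos:
                # ll[c, b] maximized over candidate targets.
                best_ll = np.full((len(c_arr), len(b_arr)), NEG_INF)
                best_ti = np.zeros((len(c_arr), len(b_arr)), dtype=int)
                for t in range(len(taus)):
                    beta = b_arr[None, :, None] * tau_in[t][None, None, :]
                    q = (1.0 - beta) * base[:, None, :] + beta * is_tau[t][None, None, :]
                    ll = np.log((1.0 - mu) * q + flat).sum(axis=2)
                    better = ll > best_ll
                    best_ll = np.where(better, ll, best_ll)
                    best_ti = np.where(better, t, best_ti)
                for ci, c in enumerate(grid.c_levels):
                    for bi, b in enumerate(b_pos):
                        table[(m, c, b)] = float(best_ll[ci, bi])
                        best_tau[(m, c, b)] = taus[best_ti[ci, bi]] if taus else None
    return FitResult(
        society_id=d.society_id,
        concept_id=d.concept_id,
        loglik_table=table,
        best_tau=best_tau,
        grid=grid,
    )


def ml_settings_frame(fits: list[FitResult]) -> pd.DataFrame:
    """One row per data structure with its ML setting and family maxima."""
    rows = []
    for fit in fits:
        rec = fit.to_record()
        fam = rec.pop("family_maxima")
        rec.update({f"loglik_{name}": value for name, value in fam.items()})
        rows.append(rec)
    return pd.DataFrame(rows)
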