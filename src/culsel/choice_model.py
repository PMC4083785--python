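"""Mixed probabilistic model of communicative-variant choice.

A participant about to produce a variant carries a *history*: the ordered
list of variants they produced themselves (ego / E-entries) and the ordered
list of variants they witnessed a partner produce (allo / A-entries). The
model turns that history into a probability distribution over the variant
universe through four mechanisms:

memory size ``m``
    Only the last ``m/2`` ego entries and last ``m/2`` allo entries can
    influence the choice. Relative frequencies within each window give an
    egocentric distribution ``f(h|E,m)`` and an allocentric one ``f(h|A,m)``.
coordination bias ``c`` in [-1, 1]
    Mixes the two window distributions with weight ``gamma = (c + 1) / 2``
    on the allocentric side: ``c = -1`` is fully egocentric (re-use your own
    variants), ``c = +1`` fully allocentric (copy your partner), ``c = 0``
    treats all remembered variants as equally worthy of reproduction —
    the drift / neutral-copying baseline.
content bias ``(tau, b)``
    An intrinsic preference of level ``b`` for a specific target variant
    ``tau``, effective only when ``tau`` is present in the memory windows
    (you must be familiar with a representation before you can prefer it):
    the memory-based distribution is scaled by ``(1 - beta)`` and ``beta``
    is added to ``tau``'s probability, where ``beta = b`` if ``tau`` is in
    memory and 0 otherwise.
mutation rate ``mu``
    With probability ``mu`` the choice is instead a uniformly random draw
    from the whole variant universe, so novel variants can appear.

The resulting choice probability for variant ``x`` given history ``h`` is

    P(x | h) = (1 - mu) * [ (1 - beta) * ((1 - gamma) * f(h|E,m)(x)
                                          + gamma * f(h|A,m)(x))
                            + beta * delta_tau(x) ]
               + mu / |universe|

with the convention that if exactly one memory window is empty the whole
coordination weight goes to the non-empty one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .datamodel import VariantLabel

__all__ = [
    "History",
    "ParameterSetting",
    "ChoiceDistribution",
    "memory_windows",
    "relative_freq",
    "combine_memory",
    "effective_beta",
    "choice_distribution",
]


@dataclass(frozen=True)
class History:
    """Ego-produced and witnessed variant lists, oldest first."""

    ego: tuple[VariantLabel, ...] = ()
    allo: tuple[VariantLabel, ...] = ()

    def is_empty(self) -> bool:
        return not self.ego and not self.allo


@dataclass(frozen=True)
class ParameterSetting:
    """One point (m, c, b, tau, mu) of the choice model's parameter space.

    ``m`` must be a positive even integer; ``c`` lies in [-1, 1]; ``b`` in
    [0, 1] with a target ``tau`` required (at evaluation time) whenever
    ``b > 0``; ``mu`` in [0, 1]. The drift (neutral) model is ``b = 0,
    c = 0``. ``tau`` may be left unset on a setting with ``b > 0`` that
    serves as a template whose target is chosen later (e.g. per simulated
    structure); evaluating such a setting raises.
    """

    m: int
    c: float
    b: float
    tau: Optional[VariantLabel] = None
    mu: float = 0.02

    def __post_init__(self) -> None:
        if self.m <= 0 or self.m % 2 != 0:
            raise ValueError(f"memory size m must be a positive even integer, got {self.m}")
        if not -1.0 <= self.c <= 1.0:
            raise ValueError(f"coordination bias c must be in [-1, 1], got {self.c}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"content-bias level b must be in [0, 1], got {self.b}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mutation rate mu must be in [0, 1], got {self.mu}")

    @property
    def gamma(self) -> float:
        """Allocentric weight: the affine map of c onto [0, 1]."""
        return (self.c + 1.0) / 2.0

    def is_drift(self) -> bool:
        return self.b == 0.0 and self.c == 0.0


ChoiceDistribution = Mapping[VariantLabel, float]


def memory_windows(
    h: History, m: int
) -> tuple[tuple[VariantLabel, ...], tuple[VariantLabel, ...]]:
    """Return the last ``m/2`` ego entries and last ``m/2`` allo entries."""
    if m <= 0 or m % 2 != 0:
        raise ValueError(f"memory size m must be a positive even integer, got {m}")
    half = m // 2
    return tuple(h.ego[-half:]), tuple(h.allo[-half:])


def relative_freq(window: Sequence[VariantLabel]) -> dict[VariantLabel, float]:
    """Map a window onto the relative frequencies of its items.

    An empty window yields an empty mapping; callers (``combine_memory``)
    must handle that sentinel.
    """
    n = len(window)
    if n == 0:
        return {}
    return {label: count / n for label, count in Counter(window).items()}


def combine_memory(
    ego_dist: ChoiceDistribution, allo_dist: ChoiceDistribution, c: float
) -> dict[VariantLabel, float]:
    """Mix egocentric and allocentric distributions with weight gamma=(c+1)/2.

    If exactly one input is empty, the other is returned unchanged (all
    coordination weight renormalized onto the non-empty window) so that the
    result always sums to 1.
    """
    if not ego_dist and not allo_dist:
        raise ValueError("cannot combine two empty memory distributions")
    if not ego_dist:
        return dict(allo_dist)
    if not allo_dist:
        return dict(ego_dist)
    gamma = (c + 1.0) / 2.0
    combined: dict[VariantLabel, float] = {}
    for label, p in ego_dist.items():
        combined[label] = (1.0 - gamma) * p
    for label, p in allo_dist.items():
        combined[label] = combined.get(label, 0.0) + gamma * p
    return combined


def effective_beta(
    tau: Optional[VariantLabel],
    b: float,
    ego_window: Sequence[VariantLabel],
    allo_window: Sequence[VariantLabel],
) -> float:
    """Content bias is effective (beta = b) only when tau is in memory."""
    if b == 0.0 or tau is None:
        return 0.0
    if tau in ego_window or tau in allo_window:
        return b
    return 0.0


def choice_distribution(
    h: History,
    p: ParameterSetting,
    universe: frozenset[VariantLabel] | set[VariantLabel],
) -> dict[VariantLabel, float]:
    """Probability of each variant in ``universe`` being produced next.

    Raises ``ValueError`` if the history is empty while ``mu < 1`` (the
    model does not define a memory-free choice; the likelihood layer never
    evaluates first-generation productions) or if the memory windows contain
    labels outside ``universe``.
    """
    if not universe:
        raise ValueError("variant universe must be non-empty")
    if p.b > 0 and p.tau is None:
        raise ValueError("content-bias target tau required when b > 0")
    k = len(universe)
    if h.is_empty():
        if p.mu < 1.0:
            raise ValueError("cannot evaluate a choice with an empty history and mu < 1")
        return {label: 1.0 / k for label in universe}

    ego_w, allo_w = memory_windows(h, p.m)
    for label in (*ego_w, *allo_w):
        if label not in universe:
            raise ValueError(f"memory label {label!r} not in universe")

    base = combine_memory(relative_freq(ego_w), relative_freq(allo_w), p.c)
    beta = effective_beta(p.tau, p.b, ego_w, allo_w)

    dist: dict[VariantLabel, float] = {}
    mut = p.mu / k
    for label in universe:
        q = (1.0 - beta) * base.get(label, 0.0)
        if beta and label == p.tau:
            q += beta
        dist[label] = (1.0 - p.mu) * q + mut
    return dist
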