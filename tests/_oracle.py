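"""Independent brute-force oracle for the variant-choice model.

Deliberately naive re-derivation of the choice probabilities and the
data-structure likelihood, written directly from the verbal model
description with plain loops and no shared code with the package. Used to
cross-check the library implementation value by value.
"""

from __future__ import annotations

import math


def oracle_choice_probs(ego, allo, m, c, b, tau, mu, universe):
    """P(x | history) for every x in universe, by direct arithmetic."""
    assert m > 0 and m % 2 == 0
    half = m // 2
    ego_w = list(ego)[len(ego) - half:] if len(ego) > half else list(ego)
    allo_w = list(allo)[len(allo) - half:] if len(allo) > half else list(allo)
    assert ego_w or allo_w, "empty history has no defined choice distribution"

    gamma = (c + 1.0) / 2.0
    universe = sorted(universe)

    def freq(window, x):
        if not window:
            return 0.0
        return sum(1 for item in window if item == x) / len(window)

    probs = {}
    for x in universe:
        if ego_w and allo_w:
            base = (1.0 - gamma) * freq(ego_w, x) + gamma * freq(allo_w, x)
        elif ego_w:
            base = freq(ego_w, x)
        else:
            base = freq(allo_w, x)
        beta = b if (tau is not None and (tau in ego_w or tau in allo_w)) else 0.0
        combined = (1.0 - beta) * base + (beta if x == tau else 0.0)
        probs[x] = (1.0 - mu) * combined + mu / len(universe)
    return probs


def oracle_structure_loglik(productions, pairs_by_gen, seconds_by_gen, m, c, b, tau, mu,
                            universe):
    """Log-likelihood of a production grid by explicit event enumeration.

    ``productions[g][p]``; ``pairs_by_gen[g]`` lists (a, b) pairs;
    ``seconds_by_gen[g]`` lists the second drawer of each pair.
    """
    n_gen = len(productions)
    n_part = len(productions[0])

    def partner(p, g):
        for x, y in pairs_by_gen[g]:
            if p == x:
                return y
            if p == y:
                return x
        raise AssertionError

    total = 0.0
    for g in range(1, n_gen):
        for p in range(n_part):
            ego = [productions[gg][p] for gg in range(g)]
            allo = [productions[gg][partner(p, gg)] for gg in range(g)]
            if p in seconds_by_gen[g]:
                allo = allo + [productions[g][partner(p, g)]]
            prob = oracle_choice_probs(ego, allo, m, c, b, tau, mu, universe)[
                productions[g][p]
            ]
            if prob <= 0.0:
                return float("-inf")
            total += math.log(prob)
    return total


def oracle_grid_search(productions, pairs_by_gen, seconds_by_gen, universe,
                       m_levels, c_levels, b_levels, taus, mu):
    """Nested-loop exhaustive search; tau maximized inside each (m, c, b)."""
    table = {}
    for m in m_levels:
        for c in c_levels:
            for b in b_levels:
                if b == 0.0:
                    table[(m, c, b)] = oracle_structure_loglik(
                        productions, pairs_by_gen, seconds_by_gen,
                        m, c, b, None, mu, universe,
                    )
                else:
                    table[(m, c, b)] = max(
                        oracle_structure_loglik(
                            productions, pairs_by_gen, seconds_by_gen,
                            m, c, b, tau, mu, universe,
                        )
                        for tau in taus
                    )
    return table
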