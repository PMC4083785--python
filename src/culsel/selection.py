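"""Best-account Bayes factors and bias classification.

Evidence for a bias in a data structure is quantified by a *best-account
Bayes factor*: the maximum likelihood over models containing the bias
divided by the maximum likelihood over models lacking it. With a uniform
grid of candidate models this is a maximum-likelihood ratio, formally akin
to a Bayes factor under point-mass priors. The default evidence threshold
is 19 (in keeping with a 0.05-style criterion; 20 would match Kass &
Raftery's "strong support" convention).

Three headline factors are computed per data structure:

* ``bf_content``      — models with b > 0 vs. models with b = 0;
* ``bf_coordination`` — models with c != 0 vs. models with c = 0;
* ``bf_any``          — any biased model (b > 0 or c != 0) vs. drift
  (b = 0 and c = 0).

``bf_both_vs_drift`` (models with both biases active vs. drift) is exposed
as well, since "evidence for the biases together" admits either reading.
Because the biased family excludes the unbiased one rather than containing
it, these ratios are not bounded below by 1: when drift is the global
maximum-likelihood account, the factors fall (slightly) below 1 and the
structure is classified as drift-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .likelihood import FitResult

__all__ = ["BayesFactors", "BiasCategory", "bayes_factors", "classify", "summarize_corpus"]

DEFAULT_THRESHOLD = 19.0


class BiasCategory(str, Enum):
    CONTENT_ONLY = "content_only"
    COORDINATION_ONLY = "coordination_only"
    BOTH = "both"
    INDETERMINATE_BIAS = "indeterminate_bias"
    DRIFT_CONSISTENT = "drift_consistent"


@dataclass(frozen=True)
class BayesFactors:
    bf_content: float
    bf_coordination: float
    bf_any: float
    bf_both_vs_drift: float
    threshold: float = DEFAULT_THRESHOLD


def _ratio(log_with: float, log_without: float) -> float:
    if log_without == float("-inf"):
        return float("inf") if log_with > log_without else 1.0
    return math.exp(log_with - log_without)


def bayes_factors(fit: FitResult, threshold: float = DEFAULT_THRESHOLD) -> BayesFactors:
    """Best-account Bayes factors from a fit's family maxima."""
    fam = fit.family_maxima
    for name in ("content", "no_content", "coordination", "no_coordination", "any_bias", "drift"):
        if name not in fam or fam.get(name) is None:
            raise ValueError(f"fit result is missing family maximum {name!r}")
    return BayesFactors(
        bf_content=_ratio(fam["content"], fam["no_content"]),
        bf_coordination=_ratio(fam["coordination"], fam["no_coordination"]),
        bf_any=_ratio(fam["any_bias"], fam["drift"]),
        bf_both_vs_drift=_ratio(fam["both_biases"], fam["drift"]),
        threshold=threshold,
    )


def classify(bf: BayesFactors) -> BiasCategory:
    """Assign one bias category from the evidence thresholds.

    Significant evidence for content bias alone, coordination bias alone,
    or both; or for *some* bias without being able to pinpoint which
    (indeterminate); otherwise the structure is indistinguishable from
    drift.
    """
    t = bf.threshold
    content = bf.bf_content >= t
    coordination = bf.bf_coordination >= t
    if content and coordination:
        return BiasCategory.BOTH
    if content:
        return BiasCategory.CONTENT_ONLY
    if coordination:
        return BiasCategory.COORDINATION_ONLY
    if bf.bf_any >= t:
        return BiasCategory.INDETERMINATE_BIAS
    return BiasCategory.DRIFT_CONSISTENT


def summarize_corpus(
    fits: list[FitResult],
    bfs: list[BayesFactors],
    diversity: list[list[int]] | None = None,
) -> dict:
    """Corpus-level summary of best-fit parameters and bias evidence.

    Returns histograms of the best-fit memory size, coordination bias and
    content-bias level; counts and proportions per bias category; median
    Bayes factors (over all structures, drift-consistent ones included);
    and, when per-structure ``diversity`` trajectories are supplied, a
    per-generation mean/s.d./max/min table of variant-type counts.
    """
    if not fits:
        raise ValueError("cannot summarize an empty corpus")
    if len(fits) != len(bfs):
        raise ValueError("fits and Bayes factors are not aligned")

    settings = [f.ml_setting for f in fits]
    categories = [classify(bf) for bf in bfs]
    n = len(fits)

    def hist(values) -> dict:
        out: dict = {}
        for v in values:
            out[v] = out.get(v, 0) + 1
        return dict(sorted(out.items()))

    summary: dict = {
        "n_structures": n,
        "histogram_m": hist(s.m for s in settings),
        "histogram_c": hist(s.c for s in settings),
        "histogram_b": hist(s.b for s in settings),
        "category_counts": {cat.value: categories.count(cat) for cat in BiasCategory},
        "category_proportions": {
            cat.value: categories.count(cat) / n for cat in BiasCategory
        },
        "median_bf_content": float(np.median([bf.bf_content for bf in bfs])),
        "median_bf_coordination": float(np.median([bf.bf_coordination for bf in bfs])),
        "median_bf_any": float(np.median([bf.bf_any for bf in bfs])),
        "median_bf_both_vs_drift": float(np.median([bf.bf_both_vs_drift for bf in bfs])),
        "threshold": bfs[0].threshold,
    }
    if diversity is not None:
        arr = np.asarray(diversity, dtype=float)
        summary["diversity_by_generation"] = {
            "mean": [round(x, 4) for x in arr.mean(axis=0)],
            "sd": [round(x, 4) for x in arr.std(axis=0, ddof=1)] if len(arr) > 1 else None,
            "max": [int(x) for x in arr.max(axis=0)],
            "min": [int(x) for x in arr.min(axis=0)],
        }
    return summary


def summary_to_text(summary: dict) -> str:
    """Human-readable rendering of :func:`summarize_corpus` output."""
    lines = [f"Corpus summary ({summary['n_structures']} data structures)"]
    lines.append(f"  evidence threshold: {summary['threshold']}")
    for key, title in (
        ("histogram_m", "best-fit memory size m"),
        ("histogram_c", "best-fit coordination bias c"),
        ("histogram_b", "best-fit content-bias level b"),
    ):
        body = ", ".join(f"{k}: {v}" for k, v in summary[key].items())
        lines.append(f"  {title}: {body}")
    lines.append("  bias categories:")
    for cat, count in summary["category_counts"].items():
        pct = 100.0 * summary["category_proportions"][cat]
        lines.append(f"    {cat}: {count} ({pct:.1f}%)")
    lines.append(
        "  median Bayes factors: content {:.2f}, coordination {:.2f}, any {:.2f}".format(
            summary["median_bf_content"],
            summary["median_bf_coordination"],
            summary["median_bf_any"],
        )
    )
    if summary.get("diversity_by_generation"):
        div = summary["diversity_by_generation"]
        table = pd.DataFrame(
            {k: v for k, v in div.items() if v is not None},
        ).T
        table.columns = [f"G{i + 1}" for i in range(table.shape[1])]
        lines.append("  variant types per generation:")
        lines.extend("    " + row for row in table.to_string().splitlines())
    return "\n".join(lines)
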