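"""Behavioural diversity index and behaviour-profile comparisons.

Field observations are tallied into four broad categories per group —
Travel, Mill, Social, Other — and summarised by a Simpson-type diversity
index D over the category proportions d_i. The printed form of the index,
D = 1 − ((Σ d_i² · n) / n − 1), is typographically ambiguous in the final
division; both readings are provided:

* ``unbiased`` (default): D = 1 − (n Σ d_i² − 1) / (n − 1), the unbiased
  finite-sample Simpson diversity, equal to
  1 − Σ n_i (n_i − 1) / (n (n − 1)). It is 0 whenever all observations fall
  in one category and lies in [0, 1].
* ``literal``: D = 1 − n Σ d_i² / (n − 1), the expression exactly as
  printed; it can be negative (e.g. −0.25 for five observations in one
  category).

Both converge to 1 − Σ d_i² as n grows.
"""

from __future__ import annotations

from scipy import stats

from .core import BehaviourTally
from .errors import ArgumentError, UndefinedEstimateError


def behaviour_diversity_D(tally: BehaviourTally, mode: str = "unbiased") -> float:
    """Diversity index D of a behaviour tally (see module docstring)."""
    n = tally.n
    if n < 2:
        raise UndefinedEstimateError(f"D undefined for n={n} (< 2 observations)")
    sum_d2 = sum((c / n) ** 2 for c in tally.counts)
    if mode == "unbiased":
        return 1.0 - (n * sum_d2 - 1.0) / (n - 1.0)
    if mode == "literal":
        return 1.0 - n * sum_d2 / (n - 1.0)
    raise ArgumentError(f"unknown mode {mode!r}")


def compare_behaviour_profiles(tally_a: BehaviourTally, tally_b: BehaviourTally,
                               category: str) -> float:
    """Two-sided Fisher's exact p for one category's frequency between two
    groups (2×2: category vs rest × group a vs b)."""
    if category not in BehaviourTally.CATEGORIES:
        raise ArgumentError(f"unknown category {category!r}")
    if tally_a.n == 0 or tally_b.n == 0:
        raise ArgumentError("both tallies must have at least one observation")
    ca = getattr(tally_a, category)
    cb = getattr(tally_b, category)
    table = [[ca, tally_a.n - ca], [cb, tally_b.n - cb]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pairwise_behaviour_comparisons(tallies: dict, category: str,
                                   correction: str = "none") -> dict:
    """Fisher p for every unordered pair of groups, optionally corrected.

    ``correction``: ``none`` (per-comparison p-values, the conventional
    presentation), ``bonferroni`` or ``holm``.
    """
    names = sorted(tallies)
    pairs = [
        (a, b) for i, a in enumerate(names) for b in names[i + 1:]
    ]
    raw = {
        (a, b): compare_behaviour_profiles(tallies[a], tallies[b], category)
        for a, b in pairs
    }
    if correction == "none":
        return raw
    m = len(raw)
    if correction == "bonferroni":
        return {k: min(1.0, p * m) for k, p in raw.items()}
    if correction == "holm":
        ordered = sorted(raw.items(), key=lambda kv: kv[1])
        out, running = {}, 0.0
        for rank, (k, p) in enumerate(ordered):
            running = max(running, min(1.0, (m - rank) * p))
            out[k] = running
        return out
    raise ArgumentError(f"unknown correction {correction!r}")
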