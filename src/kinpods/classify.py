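"""Maximum-likelihood classification of dyads into PO / FS / HS / U.

Each genealogical relationship fixes the IBD-sharing coefficients
(k0, k1, k2) — the probabilities that a dyad shares 0, 1 or 2 alleles
identical by descent at a locus:

    PO = (0, 1, 0)      FS = (0.25, 0.5, 0.25)
    HS = (0.5, 0.5, 0)  U  = (1, 0, 0)

HS pools half-sibs with grandparent–grandchild (and avuncular) dyads, which
share the same coefficients. The per-locus likelihood of an observed ordered
genotype pair (g1, g2) under a category is the k-mixture of the
pair probabilities given m shared IBD alleles, assuming Hardy–Weinberg
genotype frequencies:

    P_0 = P_HWE(g1) P_HWE(g2)
    P_1 = P_HWE(g1) T(g1 -> g2)       (one allele passed from g1, the
                                       other drawn from the population)
    P_2 = P_HWE(g1) if g1 == g2 else 0

Genotyping error is modelled as an independent per-member per-locus event of
probability e that replaces the recorded genotype by a fresh Hardy–Weinberg
draw. Mixing over the four error patterns gives the per-locus likelihood

    L_e = (1−e)^2 L_cat(g1, g2) + (1 − (1−e)^2) P_HWE(g1) P_HWE(g2)

since any pattern with at least one erroneous member renders the two observed
genotypes independent HWE draws. At e = 0 this reduces exactly to the
error-free likelihood; at e > 0 a single zero-sharing locus no longer forces
L(PO) = 0, which is what rescues true parent–offspring dyads carrying one
mistyped locus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from math import log
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (
    MISSING,
    AlleleFrequencyTable,
    IndividualRecord,
    MultilocusGenotype,
)
from .errors import ArgumentError, InsufficientDataError

#: (k0, k1, k2) per category.
IBD_COEFFICIENTS: Dict[str, Tuple[float, float, float]] = {
    "PO": (0.0, 1.0, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "HS": (0.5, 0.5, 0.0),
    "U": (1.0, 0.0, 0.0),
}

CATEGORIES = ("PO", "FS", "HS", "U")
#: Tie-break preference, least related first (conservative calls).
_TIE_ORDER = ("U", "HS", "FS", "PO")


def hwe_genotype_prob(pair: Tuple[int, int], locus_freqs: Dict[int, float]) -> float:
    a, b = pair
    pa = locus_freqs.get(a, 0.0)
    pb = locus_freqs.get(b, 0.0)
    return pa * pa if a == b else 2.0 * pa * pb


def _transition_prob(g1: Tuple[int, int], g2: Tuple[int, int],
                     locus_freqs: Dict[int, float]) -> float:
    """P(observe g2 | one allele of g2 is a random allele of g1, the other a
    population draw)."""
    a, b = g1
    c, d = g2
    pc = locus_freqs.get(c, 0.0)
    pd = locus_freqs.get(d, 0.0)
    drop_c = 0.5 * ((a == c) + (b == c))  # P(transmitted allele is c)
    drop_d = 0.5 * ((a == d) + (b == d))
    if c == d:
        return drop_c * pc
    return drop_c * pd + drop_d * pc


def locus_likelihood(pair1: Tuple[int, int], pair2: Tuple[int, int],
                     locus_freqs: Dict[int, float], category: str,
                     error_rate: float = 0.0) -> float:
    """Likelihood of one ordered genotype pair at one locus under a category."""
    k0, k1, k2 = IBD_COEFFICIENTS[category]
    p1 = hwe_genotype_prob(pair1, locus_freqs)
    p2 = hwe_genotype_prob(pair2, locus_freqs)
    same = tuple(sorted(pair1)) == tuple(sorted(pair2))
    p_ibd0 = p1 * p2
    p_ibd1 = p1 * _transition_prob(pair1, pair2, locus_freqs)
    p_ibd2 = p1 if same else 0.0
    clean = k0 * p_ibd0 + k1 * p_ibd1 + k2 * p_ibd2
    if error_rate == 0.0:
        return clean
    ok2 = (1.0 - error_rate) ** 2
    return ok2 * clean + (1.0 - ok2) * p_ibd0


@dataclass
class RelationshipCall:
    """Per-dyad log-likelihoods over the four categories and the ML call."""

    id1: str
    id2: str
    log_likelihoods: Dict[str, float]
    best: str
    error_rate: float


def dyad_category_likelihoods(g1: MultilocusGenotype, g2: MultilocusGenotype,
                              freqs: AlleleFrequencyTable,
                              error_rate: float = 0.0,
                              min_shared_loci: int = 6) -> Dict[str, float]:
    """Multilocus log-likelihood per category (loci assumed unlinked).

    −inf is a legitimate value (e.g. PO with a zero-sharing locus at
    error_rate 0).
    """
    if not 0.0 <= error_rate <= 0.5:
        raise ArgumentError(f"error_rate must be in [0, 0.5], got {error_rate}")
    shared = g1.shared_typed_loci(g2)
    if len(shared) < min_shared_loci:
        raise InsufficientDataError(
            f"{len(shared)} loci typed in both members, need {min_shared_loci}"
        )
    out = {}
    for cat in CATEGORIES:
        total = 0.0
        for i in shared:
            locus = g1.loci[i]
            lik = locus_likelihood(
                g1.alleles[i], g2.alleles[i], freqs[locus], cat, error_rate
            )
            total += log(lik) if lik > 0.0 else float("-inf")
        out[cat] = total
    return out


def classify_dyad(g1: MultilocusGenotype, g2: MultilocusGenotype,
                  freqs: AlleleFrequencyTable, error_rate: float = 0.0,
                  min_shared_loci: int = 6,
                  id1: str = "", id2: str = "") -> RelationshipCall:
    """ML relationship call; likelihood ties resolve toward the less related
    category (U over HS over FS over PO)."""
    ll = dyad_category_likelihoods(g1, g2, freqs, error_rate, min_shared_loci)
    best = max(_TIE_ORDER, key=lambda c: ll[c])  # max is stable: first of ties
    return RelationshipCall(id1, id2, ll, best, error_rate)


def classify_all_pairs(records: Sequence[IndividualRecord],
                       freqs: AlleleFrequencyTable, error_rate: float = 0.0,
                       min_shared_loci: int = 6) -> List[RelationshipCall]:
    """Classify every unordered pair meeting the shared-loci threshold."""
    records = list(records)
    calls = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            r1, r2 = records[i], records[j]
            try:
                calls.append(
                    classify_dyad(
                        r1.genotype, r2.genotype, freqs, error_rate,
                        min_shared_loci, id1=r1.id, id2=r2.id,
                    )
                )
            except InsufficientDataError:
                continue
    return calls


def exclude_po_pairs(records: Sequence[IndividualRecord],
                     freqs: AlleleFrequencyTable, error_rate: float = 0.0,
                     min_shared_loci: int = 6) -> List[IndividualRecord]:
    """Greedily remove one member of every PO-classified pair.

    While any remaining pair classifies PO, the member with fewer typed loci
    is removed (tie: the lexicographically larger id), so e.g. a mother with
    two offspring can be resolved by removing the mother alone. Input order
    of the survivors is preserved.
    """
    records = list(records)
    if len(records) < 2:
        return records
    by_id = {r.id: r for r in records}
    po_pairs = sorted(
        (c.id1, c.id2)
        for c in classify_all_pairs(records, freqs, error_rate, min_shared_loci)
        if c.best == "PO"
    )
    removed = set()
    for id1, id2 in po_pairs:
        if id1 in removed or id2 in removed:
            continue
        n1 = by_id[id1].genotype.n_typed
        n2 = by_id[id2].genotype.n_typed
        if n1 < n2:
            removed.add(id1)
        elif n2 < n1:
            removed.add(id2)
        else:
            removed.add(max(id1, id2))
    return [r for r in records if r.id not in removed]


def write_calls_csv(calls: Sequence[RelationshipCall], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id1", "id2", "logL_PO", "logL_FS", "logL_HS", "logL_U", "best",
             "error_rate"]
        )
        for c in calls:
            w.writerow(
                [c.id1, c.id2]
                + [repr(c.log_likelihoods[k]) for k in CATEGORIES]
                + [c.best, repr(c.error_rate)]
            )
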