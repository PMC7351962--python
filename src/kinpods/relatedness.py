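"""Pairwise relatedness estimators and whole-dataset relatedness matrices.

Two estimators are provided:

* ``r_QG`` — the Queller–Goodnight moment estimator in its symmetric
  multilocus form. For a dyad (x, y) with x = (a, b) and y = (c, d) at a
  locus, the x→y directional terms are

      num = 0.5 (δ_ac + δ_ad + δ_bc + δ_bd) − p_a − p_b
      den = 1 + δ_ab − p_a − p_b

  and r is the ratio of the sums of both directional numerators over all
  usable loci to the corresponding sum of denominators. Loci where both
  directional denominators vanish carry no information and are skipped.
  r_QG is centred at 0 for unrelated dyads and has expectation equal to the
  relatedness coefficient (0.5 PO/FS, 0.25 HS).

* ``M_xy`` — the genotype-sharing index: per locus the size of a maximum
  matching between the two allele pairs (0, 1 or 2) divided by 2, averaged
  over loci typed in both individuals. Bounded in [0, 1] and positive in
  expectation even for unrelated dyads (background allele sharing).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    AlleleFrequencyTable,
    IndividualRecord,
    MultilocusGenotype,
    genotypes_to_array,
)
from .errors import ArgumentError, InsufficientDataError, UndefinedEstimateError

ESTIMATORS = ("r_QG", "M_xy")


def freq_lookup_array(G: np.ndarray, freqs: AlleleFrequencyTable, loci: Sequence[str]) -> np.ndarray:
    """Per-element population frequency of each observed allele.

    Shape matches ``G`` ((..., L, 2)); missing slots get 0.0. Alleles absent
    from the table also get 0.0 (they carry no frequency information).
    """
    P = np.zeros(G.shape, dtype=float)
    for j, locus in enumerate(loci):
        table = freqs[locus]
        col = G[..., j, :]
        out = np.zeros(col.shape, dtype=float)
        for allele, p in table.items():
            out[col == allele] = p
        P[..., j, :] = out
    return P


def rqg_dyads(G1: np.ndarray, G2: np.ndarray, P1: np.ndarray, P2: np.ndarray,
              min_shared_loci: int = 1):
    """Vectorised r_QG for matched dyad arrays of shape (m, L, 2).

    Returns ``(r, loci_used)``; ``r`` is NaN where fewer than
    ``min_shared_loci`` loci are typed in both members or where every shared
    locus is degenerate (both directional denominators zero).
    """
    typed = (G1[..., 0] >= 0) & (G2[..., 0] >= 0)  # (m, L)
    a, b = G1[..., 0], G1[..., 1]
    c, d = G2[..., 0], G2[..., 1]
    s4 = ((a == c).astype(float) + (a == d) + (b == c) + (b == d))
    pa = P1.sum(axis=-1)  # p_a + p_b
    pc = P2.sum(axis=-1)
    num_xy = 0.5 * s4 - pa
    den_xy = 1.0 + (a == b) - pa
    num_yx = 0.5 * s4 - pc
    den_yx = 1.0 + (c == d) - pc
    degenerate = (np.abs(den_xy) < 1e-12) & (np.abs(den_yx) < 1e-12)
    use = typed & ~degenerate
    num = np.where(use, num_xy + num_yx, 0.0).sum(axis=-1)
    den = np.where(use, den_xy + den_yx, 0.0).sum(axis=-1)
    loci_used = typed.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r = np.where((loci_used >= min_shared_loci) & (use.any(axis=-1)), r, np.nan)
    return r, loci_used


def mxy_dyads(G1: np.ndarray, G2: np.ndarray, min_shared_loci: int = 1):
    """Vectorised M_xy for matched dyad arrays of shape (m, L, 2)."""
    typed = (G1[..., 0] >= 0) & (G2[..., 0] >= 0)
    a, b = G1[..., 0], G1[..., 1]
    c, d = G2[..., 0], G2[..., 1]
    # maximum matching between {a,b} and {c,d}: best of the two pairings
    m1 = (a == c).astype(int) + (b == d)
    m2 = (a == d).astype(int) + (b == c)
    shared = np.maximum(m1, m2)
    loci_used = typed.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(typed, shared, 0).sum(axis=-1) / (2.0 * loci_used)
    m = np.where(loci_used >= min_shared_loci, m, np.nan)
    return m, loci_used


def _as_dyad_arrays(g1: MultilocusGenotype, g2: MultilocusGenotype):
    G = genotypes_to_array([g1, g2])
    return G[0:1], G[1:2]


def r_qg_pair(g1: MultilocusGenotype, g2: MultilocusGenotype,
              freqs: AlleleFrequencyTable, min_shared_loci: int = 6) -> float:
    """Queller–Goodnight relatedness for one dyad.

    Raises :class:`InsufficientDataError` when fewer than ``min_shared_loci``
    loci are typed in both members, and :class:`UndefinedEstimateError` when
    every shared locus is degenerate.
    """
    G1, G2 = _as_dyad_arrays(g1, g2)
    P1 = freq_lookup_array(G1, freqs, g1.loci)
    P2 = freq_lookup_array(G2, freqs, g1.loci)
    shared = len(g1.shared_typed_loci(g2))
    if shared < min_shared_loci:
        raise InsufficientDataError(
            f"{shared} loci typed in both members, need {min_shared_loci}"
        )
    r, _ = rqg_dyads(G1, G2, P1, P2, min_shared_loci=min_shared_loci)
    if np.isnan(r[0]):
        raise UndefinedEstimateError("all shared loci degenerate for this dyad")
    return float(r[0])


def m_xy_pair(g1: MultilocusGenotype, g2: MultilocusGenotype,
              min_shared_loci: int = 6) -> float:
    """Genotype-sharing index M_xy in [0, 1] for one dyad."""
    G1, G2 = _as_dyad_arrays(g1, g2)
    shared = len(g1.shared_typed_loci(g2))
    if shared < min_shared_loci:
        raise InsufficientDataError(
            f"{shared} loci typed in both members, need {min_shared_loci}"
        )
    m, _ = mxy_dyads(G1, G2, min_shared_loci=min_shared_loci)
    return float(m[0])


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise relatedness with per-pair shared-locus counts.

    ``values[i, j]`` is NaN for absent pairs (below the shared-loci threshold
    or degenerate) and on the diagonal.
    """

    ids: tuple
    estimator: str
    values: np.ndarray
    loci_used: np.ndarray
    min_shared_loci: int

    def __post_init__(self):
        self.ids = tuple(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n) or self.loci_used.shape != (n, n):
            raise ArgumentError("matrix shapes do not match id count")
        self._index = {x: i for i, x in enumerate(self.ids)}

    def pair_value(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def has_pair(self, id1: str, id2: str) -> bool:
        return not np.isnan(self.values[self._index[id1], self._index[id2]])

    def stored_pairs(self, subset: Optional[Sequence[str]] = None):
        """Yield (id1, id2, r) over stored unordered pairs, optionally within
        a subset of ids."""
        idx = (
            sorted(self._index[x] for x in subset)
            if subset is not None
            else range(len(self.ids))
        )
        idx = list(idx)
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                v = self.values[i, j]
                if not np.isnan(v):
                    yield self.ids[i], self.ids[j], float(v)

    def pair_values(self, subset: Optional[Sequence[str]] = None) -> np.ndarray:
        return np.array([v for _, _, v in self.stored_pairs(subset)])

    def write_long_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id1", "id2", "estimator", "r", "loci_used"])
            for i in range(len(self.ids)):
                for j in range(i + 1, len(self.ids)):
                    if np.isnan(self.values[i, j]):
                        continue
                    w.writerow(
                        [
                            self.ids[i],
                            self.ids[j],
                            self.estimator,
                            repr(float(self.values[i, j])),
                            int(self.loci_used[i, j]),
                        ]
                    )

    def write_square_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id"] + list(self.ids))
            for i, x in enumerate(self.ids):
                row = [x]
                for j in range(len(self.ids)):
                    v = self.values[i, j]
                    row.append("" if np.isnan(v) else repr(float(v)))
                w.writerow(row)


def relatedness_matrix(records: Sequence[IndividualRecord], estimator: str,
                       freqs: Optional[AlleleFrequencyTable] = None,
                       min_shared_loci: int = 6) -> RelatednessMatrix:
    """All-pairs relatedness over a dataset.

    Pairs with fewer than ``min_shared_loci`` loci typed in both members are
    absent (NaN), not zero. ``freqs`` is required for ``r_QG``.
    """
    records = list(records)
    if len(records) < 2:
        raise ArgumentError("need at least 2 records")
    if estimator not in ESTIMATORS:
        raise ArgumentError(f"unknown estimator {estimator!r}")
    G = genotypes_to_array(records)
    n, L = G.shape[0], G.shape[1]
    I, J = np.triu_indices(n, 1)
    if estimator == "r_QG":
        if freqs is None:
            raise ArgumentError("r_QG requires allele frequencies")
        loci = records[0].genotype.loci
        P = freq_lookup_array(G, freqs, loci)
        r, used = rqg_dyads(G[I], G[J], P[I], P[J], min_shared_loci)
    else:
        r, used = mxy_dyads(G[I], G[J], min_shared_loci)
    values = np.full((n, n), np.nan)
    loci_used = np.zeros((n, n), dtype=int)
    values[I, J] = r
    values[J, I] = r
    loci_used[I, J] = used
    loci_used[J, I] = used
    return RelatednessMatrix(
        ids=tuple(rec.id for rec in records),
        estimator=estimator,
        values=values,
        loci_used=loci_used,
        min_shared_loci=min_shared_loci,
    )
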