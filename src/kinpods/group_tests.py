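"""Group-level kinship statistics.

Three analyses quantify whether observed groupings are kin-structured:

* a within- versus between-matriline relatedness contrast — the difference in
  mean pairwise r between same-haplotype and different-haplotype dyads,
  referenced against a permutation null built by shuffling haplotype labels
  across group members;
* simulation-calibrated sibship frequency tests — relatedness thresholds
  separating FS/HS/U are placed where simulated gamete-dropped dyad
  distributions cross, and the observed proportion of sibling-scoring pairs
  in a group is compared by χ² against the expectation among randomly
  generated unrelated individuals of the same sample size;
* per-group relatedness summaries (mean, median, IQR, range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .classify import classify_all_pairs
from .core import AlleleFrequencyTable, IndividualRecord, genotypes_to_array
from .errors import (
    ArgumentError,
    CalibrationError,
    InsufficientDataError,
    UntestableError,
)
from .relatedness import (
    RelatednessMatrix,
    freq_lookup_array,
    mxy_dyads,
    rqg_dyads,
)
from .simulate import hwe_genotypes, sim_dyad_arrays


@dataclass
class GroupRelatednessSummary:
    mean: float
    median: float
    iqr: float
    min: float
    max: float
    n_pairs: int
    n_absent: int


def group_mean_r_summary(matrix: RelatednessMatrix,
                         member_ids: Sequence[str]) -> GroupRelatednessSummary:
    """Summary statistics over the stored within-group pairwise r values."""
    member_ids = list(member_ids)
    if len(member_ids) < 2:
        raise InsufficientDataError("need at least 2 members")
    values = matrix.pair_values(member_ids)
    total = len(member_ids) * (len(member_ids) - 1) // 2
    if values.size == 0:
        raise InsufficientDataError("no stored pairs among these members")
    q75, q25 = np.percentile(values, [75, 25])
    return GroupRelatednessSummary(
        mean=float(values.mean()),
        median=float(np.median(values)),
        iqr=float(q75 - q25),
        min=float(values.min()),
        max=float(values.max()),
        n_pairs=int(values.size),
        n_absent=int(total - values.size),
    )


@dataclass
class MatrilineContrastResult:
    mean_within: float
    mean_between: float
    observed_diff: float
    quantiles: Dict[int, Tuple[float, float]]
    p: float
    n_permutations: int
    n_within: int
    n_between: int


def matriline_contrast_test(matrix: RelatednessMatrix,
                            members: Sequence[IndividualRecord],
                            n_permutations: int = 50_000,
                            seed: int = 0,
                            batch: int = 2_000) -> MatrilineContrastResult:
    """Within- minus between-matriline mean relatedness, with permutation null.

    The observed difference Δ = mean r(same haplotype) − mean r(different
    haplotype) is compared to the distribution of Δ under random reassignment
    of the haplotype labels across the same members. The two-tailed p-value
    uses the add-one convention and is never 0; 90/95/99% bands of the
    permuted distribution are reported. Only the same/different partition
    matters, so the test is invariant to relabelling haplotypes.
    """
    members = [m for m in members if m.mtdna is not None]
    haps = [m.mtdna for m in members]
    if len(set(haps)) < 2:
        raise UntestableError("fewer than 2 distinct haplotypes; no between pairs")

    ids = [m.id for m in members]
    index = {x: k for k, x in enumerate(ids)}
    pi, pj, r = [], [], []
    for a, b, v in matrix.stored_pairs(ids):
        pi.append(index[a])
        pj.append(index[b])
        r.append(v)
    if not r:
        raise InsufficientDataError("no stored pairs among these members")
    pi = np.array(pi)
    pj = np.array(pj)
    r = np.array(r)
    # labels are opaque: only the same/different partition enters the test
    codes = np.unique(np.array(haps, dtype=object), return_inverse=True)[1]

    within = codes[pi] == codes[pj]
    n_within = int(within.sum())
    n_between = int((~within).sum())
    if n_within == 0 or n_between == 0:
        raise UntestableError(
            f"degenerate pair counts (within={n_within}, between={n_between})"
        )
    mean_within = float(r[within].mean())
    mean_between = float(r[~within].mean())
    observed = mean_within - mean_between

    rng = np.random.default_rng(seed)
    diffs = []
    done = 0
    while done < n_permutations:
        p = min(batch, n_permutations - done)
        labels = rng.permuted(np.tile(codes, (p, 1)), axis=1)
        W = labels[:, pi] == labels[:, pj]
        w = W.sum(axis=1)
        b = len(r) - w
        valid = (w > 0) & (b > 0)
        with np.errstate(invalid="ignore"):
            d = (W @ r) / w - ((~W) @ r) / b
        diffs.append(d[valid])
        done += p
    diffs = np.concatenate(diffs)
    if diffs.size == 0:
        raise UntestableError("no valid permutations")

    p_value = (1 + int((np.abs(diffs) >= abs(observed)).sum())) / (diffs.size + 1)
    quantiles = {
        q: (
            float(np.percentile(diffs, (100 - q) / 2)),
            float(np.percentile(diffs, 100 - (100 - q) / 2)),
        )
        for q in (90, 95, 99)
    }
    return MatrilineContrastResult(
        mean_within=mean_within,
        mean_between=mean_between,
        observed_diff=float(observed),
        quantiles=quantiles,
        p=float(p_value),
        n_permutations=int(diffs.size),
        n_within=n_within,
        n_between=n_between,
    )


# ---------------------------------------------------------------------------
# Sibship frequency machinery


def _score_dyad_arrays(G1, G2, freqs: AlleleFrequencyTable, estimator: str,
                       min_shared_loci: int = 1) -> np.ndarray:
    loci = freqs.loci
    if estimator == "r_QG":
        P1 = freq_lookup_array(G1, freqs, loci)
        P2 = freq_lookup_array(G2, freqs, loci)
        s, _ = rqg_dyads(G1, G2, P1, P2, min_shared_loci)
    elif estimator == "M_xy":
        s, _ = mxy_dyads(G1, G2, min_shared_loci)
    else:
        raise ArgumentError(f"unknown estimator {estimator!r}")
    return s[~np.isnan(s)]


def _optimal_cut(lower: np.ndarray, upper: np.ndarray) -> Tuple[float, float]:
    """Threshold minimising total misclassification between two samples.

    Scores strictly above the threshold are assigned to the ``upper`` sample.
    Returns (threshold at the midpoint of the optimal interval,
    misclassification rate at that threshold).
    """
    values = np.unique(np.concatenate([lower, upper]))
    if values.size < 2:
        raise CalibrationError("score distributions are a single point")
    # candidate cuts: midpoints between adjacent distinct values
    cuts = (values[:-1] + values[1:]) / 2.0
    n_lo, n_hi = len(lower), len(upper)
    mis_lo = n_lo - np.searchsorted(np.sort(lower), cuts, side="right")
    mis_hi = np.searchsorted(np.sort(upper), cuts, side="right")
    errors = mis_lo + mis_hi
    best = int(np.argmin(errors))
    # midpoint of the full optimal plateau, for a symmetric, stable choice
    plateau = np.flatnonzero(errors == errors[best])
    t = float((cuts[plateau[0]] + cuts[plateau[-1]]) / 2.0)
    rate = float(errors[best]) / (n_lo + n_hi)
    return t, rate


@dataclass
class SibshipThresholds:
    estimator: str
    t_hs_u: float
    t_fs_hs: float
    misclass_hs_u: float
    misclass_fs_hs: float
    n_sim: int


def calibrate_sibship_thresholds(freqs: AlleleFrequencyTable, estimator: str,
                                 n_sim: int = 1_000,
                                 seed: int = 0,
                                 max_misclass: float = 0.45) -> SibshipThresholds:
    """Place the HS/U and FS/HS relatedness thresholds from simulated dyads.

    ``n_sim`` gamete-dropped dyads per category (FS, HS, U) are scored with
    the chosen estimator; each threshold sits at the misclassification-
    minimising crossing of the two adjacent empirical distributions. A panel
    whose distributions overlap almost completely (misclassification rate at
    the optimum ≥ ``max_misclass``, i.e. barely better than a coin flip)
    fails calibration, as does a crossing that violates t_FS/HS > t_HS/U.
    """
    if n_sim < 200:
        raise ArgumentError("n_sim must be >= 200 per category")
    rng = np.random.default_rng(seed)
    scores = {}
    for cat in ("FS", "HS", "U"):
        G1, G2 = sim_dyad_arrays(freqs, cat, n_sim, rng)
        scores[cat] = _score_dyad_arrays(G1, G2, freqs, estimator)
    t_hs_u, m_hs_u = _optimal_cut(scores["U"], scores["HS"])
    t_fs_hs, m_fs_hs = _optimal_cut(scores["HS"], scores["FS"])
    if m_hs_u >= max_misclass or m_fs_hs >= max_misclass:
        raise CalibrationError(
            "estimator distributions too overlapped to calibrate "
            f"(misclassification {m_hs_u:.2f} HS/U, {m_fs_hs:.2f} FS/HS)"
        )
    if not t_fs_hs > t_hs_u:
        raise CalibrationError(
            f"threshold ordering violated (t_FS/HS={t_fs_hs:.3f} <= "
            f"t_HS/U={t_hs_u:.3f})"
        )
    return SibshipThresholds(estimator, t_hs_u, t_fs_hs, m_hs_u, m_fs_hs, n_sim)


@dataclass
class SibshipTestResult:
    estimator: str
    thresholds: SibshipThresholds
    n_individuals: int
    n_pairs: int
    observed_fs: int
    observed_hs: int
    observed_sib_proportion: float
    expected_sib_proportion: float
    chi2: float
    p: float
    n_randomizations: int


def sibship_frequency_test(records: Sequence[IndividualRecord],
                           freqs: AlleleFrequencyTable,
                           estimator: str,
                           thresholds: SibshipThresholds,
                           n_randomizations: int = 100,
                           seed: int = 0,
                           min_shared_loci: int = 6,
                           check_po: bool = True) -> SibshipTestResult:
    """Observed versus expected sibling (FS + HS) pair frequencies in a group.

    Callers must have removed one member of every parent–offspring pair
    beforehand (the test targets sibships, not PO); with ``check_po`` the
    precondition is verified by reclassifying all pairs. The expectation is
    the mean sibling-scoring proportion over ``n_randomizations`` samples of
    the same size drawn unrelated from the reference allele frequencies
    (``n_randomizations=1`` gives single-draw mode); χ² compares sibling and
    non-sibling pair counts on 1 df. Observed proportions vary across
    calibration runs only through threshold randomness.
    """
    records = list(records)
    if len(records) < 10:
        raise InsufficientDataError(
            f"need at least 10 individuals, got {len(records)}"
        )
    if check_po:
        po = [
            c for c in classify_all_pairs(records, freqs, 0.0, min_shared_loci)
            if c.best == "PO"
        ]
        if po:
            raise ArgumentError(
                f"records contain {len(po)} unexcluded PO pair(s), "
                f"e.g. ({po[0].id1}, {po[0].id2}); run exclude_po_pairs first"
            )

    G = genotypes_to_array(records)
    I, J = np.triu_indices(len(records), 1)
    obs = _score_dyad_arrays(G[I], G[J], freqs, estimator, min_shared_loci)
    n_pairs = int(obs.size)
    if n_pairs == 0:
        raise InsufficientDataError("no pairs meet the shared-loci threshold")
    obs_sib = int((obs > thresholds.t_hs_u).sum())
    obs_fs = int((obs > thresholds.t_fs_hs).sum())
    obs_hs = obs_sib - obs_fs

    rng = np.random.default_rng(seed)
    props = []
    for _ in range(n_randomizations):
        H = hwe_genotypes(freqs, len(records), rng)
        s = _score_dyad_arrays(H[I], H[J], freqs, estimator)
        props.append(float((s > thresholds.t_hs_u).mean()))
    expected_prop = float(np.mean(props))

    e_sib = max(expected_prop * n_pairs, 1e-9)
    e_non = max((1.0 - expected_prop) * n_pairs, 1e-9)
    o_non = n_pairs - obs_sib
    chi2 = (obs_sib - e_sib) ** 2 / e_sib + (o_non - e_non) ** 2 / e_non
    p = float(stats.chi2.sf(chi2, df=1))
    return SibshipTestResult(
        estimator=estimator,
        thresholds=thresholds,
        n_individuals=len(records),
        n_pairs=n_pairs,
        observed_fs=obs_fs,
        observed_hs=obs_hs,
        observed_sib_proportion=obs_sib / n_pairs,
        expected_sib_proportion=expected_prop,
        chi2=float(chi2),
        p=p,
        n_randomizations=n_randomizations,
    )
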