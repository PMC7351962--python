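"""Core data model: genotypes, individuals, groups, allele frequencies.

An individual carries an unordered pair of integer allele labels at each of a
fixed panel of microsatellite loci (a locus is either fully typed or missing —
half-typed loci are rejected upstream), plus metadata: sex, age class, an
opaque mtDNA haplotype label (maternally inherited), group membership,
location and date.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ArgumentError, InsufficientDataError, ValidationError

#: Sentinel for an untyped locus.
MISSING = None

SEXES = ("F", "M", "unknown")
AGE_CLASSES = ("adult", "juvenile", "calf", "unknown")
SOCIAL_GROUP_TYPES = ("A", "A1", "B", "C", "D", "E")
HERD_GROUP_TYPES = ("F", "G", "H", "I")
GROUP_TYPES = SOCIAL_GROUP_TYPES + HERD_GROUP_TYPES


def _normalise_pair(pair):
    if pair is MISSING:
        return MISSING
    a, b = pair
    if a is None or b is None:
        raise ValidationError(f"half-typed locus: {pair!r}")
    a, b = int(a), int(b)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class MultilocusGenotype:
    """Unordered allele pairs at an ordered panel of named loci.

    ``alleles[i]`` is either a sorted ``(a, b)`` integer tuple or ``MISSING``.
    Equality is order-independent in the allele pair because pairs are stored
    sorted.
    """

    loci: tuple
    alleles: tuple

    def __post_init__(self):
        loci = tuple(self.loci)
        alleles = tuple(_normalise_pair(p) for p in self.alleles)
        if len(loci) != len(alleles):
            raise ValidationError(
                f"{len(loci)} loci but {len(alleles)} allele pairs"
            )
        object.__setattr__(self, "loci", loci)
        object.__setattr__(self, "alleles", alleles)

    @classmethod
    def from_mapping(cls, loci: Sequence[str], mapping: Mapping) -> "MultilocusGenotype":
        return cls(tuple(loci), tuple(mapping.get(l, MISSING) for l in loci))

    def get(self, locus: str):
        return self.alleles[self.loci.index(locus)]

    @property
    def n_typed(self) -> int:
        return sum(1 for p in self.alleles if p is not MISSING)

    @property
    def typed_loci(self) -> tuple:
        return tuple(l for l, p in zip(self.loci, self.alleles) if p is not MISSING)

    def shared_typed_loci(self, other: "MultilocusGenotype") -> tuple:
        """Indices of loci typed in both genotypes (panels must match)."""
        if self.loci != other.loci:
            raise ArgumentError("genotypes are on different locus panels")
        return tuple(
            i
            for i, (p, q) in enumerate(zip(self.alleles, other.alleles))
            if p is not MISSING and q is not MISSING
        )


@dataclass(frozen=True)
class IndividualRecord:
    id: str
    genotype: MultilocusGenotype
    mtdna: Optional[str] = None
    sex: str = "unknown"
    age_class: str = "unknown"
    group_id: Optional[str] = None
    location: str = ""
    date: Optional[str] = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"{self.id}: unknown sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(f"{self.id}: unknown age class {self.age_class!r}")

    def with_genotype(self, genotype: MultilocusGenotype) -> "IndividualRecord":
        return replace(self, genotype=genotype)


@dataclass
class BehaviourTally:
    """Observation counts over the four broad behaviour categories."""

    travel: int = 0
    mill: int = 0
    social: int = 0
    other: int = 0

    CATEGORIES = ("travel", "mill", "social", "other")

    def __post_init__(self):
        for c in self.CATEGORIES:
            if getattr(self, c) < 0:
                raise ArgumentError(f"negative behaviour count for {c}")

    @property
    def counts(self) -> tuple:
        return tuple(getattr(self, c) for c in self.CATEGORIES)

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass
class GroupRecord:
    group_id: str
    group_type: str
    member_ids: list
    size_observed: Optional[int] = None
    behaviour: Optional[BehaviourTally] = None

    def __post_init__(self):
        if self.group_type not in GROUP_TYPES:
            raise ValidationError(
                f"group {self.group_id}: unknown type {self.group_type!r}"
            )
        if self.size_observed is not None:
            if self.group_type in SOCIAL_GROUP_TYPES and not (
                2 <= self.size_observed <= 50
            ):
                raise ValidationError(
                    f"group {self.group_id}: social group size "
                    f"{self.size_observed} outside 2..50"
                )
            if self.group_type in ("F", "G") and self.size_observed <= 50:
                raise ValidationError(
                    f"group {self.group_id}: herd size {self.size_observed} "
                    "must exceed 50"
                )


class AlleleFrequencyTable:
    """Per-locus allele frequencies, summing to one at each locus."""

    def __init__(self, freqs: Mapping[str, Mapping[int, float]]):
        self._freqs = {}
        for locus, f in freqs.items():
            f = {int(a): float(p) for a, p in f.items()}
            if not f:
                raise ValidationError(f"locus {locus}: empty frequency map")
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"locus {locus}: frequencies sum to {total}, not 1"
                )
            if any(p <= 0 for p in f.values()):
                raise ValidationError(f"locus {locus}: non-positive frequency")
            self._freqs[locus] = f

    @property
    def loci(self) -> tuple:
        return tuple(self._freqs)

    def __getitem__(self, locus: str) -> dict:
        return self._freqs[locus]

    def __contains__(self, locus: str) -> bool:
        return locus in self._freqs

    def freq(self, locus: str, allele: int) -> float:
        """Frequency of ``allele``; 0.0 for an allele never observed."""
        return self._freqs[locus].get(int(allele), 0.0)

    def n_alleles(self, locus: str) -> int:
        return len(self._freqs[locus])

    def alleles(self, locus: str) -> tuple:
        return tuple(sorted(self._freqs[locus]))

    def as_dict(self) -> dict:
        return {l: dict(f) for l, f in self._freqs.items()}

    @classmethod
    def equifrequent(cls, loci: Sequence[str], n_alleles: int) -> "AlleleFrequencyTable":
        """Uniform frequencies over ``n_alleles`` labelled 1..n at every locus."""
        # Exact rationals avoid sum-to-one drift for any n_alleles.
        from fractions import Fraction

        p = Fraction(1, n_alleles)
        return cls({l: {a: p for a in range(1, n_alleles + 1)} for l in loci})


def filter_min_loci(records: Iterable[IndividualRecord], min_loci: int) -> list:
    """Keep records typed at ``min_loci`` or more loci, preserving order.

    The field convention is that reliable relatedness estimation needs at
    least six of the eight loci typed; network analyses raise this to seven.
    """
    records = list(records)
    if not records:
        return []
    n_loci = len(records[0].genotype.loci)
    if not 1 <= min_loci <= n_loci:
        raise ArgumentError(f"min_loci must be in [1, {n_loci}], got {min_loci}")
    return [r for r in records if r.genotype.n_typed >= min_loci]


def compute_allele_frequencies(records: Iterable[IndividualRecord]) -> AlleleFrequencyTable:
    """Observed allele frequencies over all typed copies, per locus.

    Missing loci contribute no copies; a locus typed in nobody is an error.
    """
    records = list(records)
    if not records:
        raise InsufficientDataError("no records")
    loci = records[0].genotype.loci
    counts = {l: {} for l in loci}
    for r in records:
        if r.genotype.loci != loci:
            raise ValidationError(f"{r.id}: locus panel differs from first record")
        for locus, pair in zip(loci, r.genotype.alleles):
            if pair is MISSING:
                continue
            for a in pair:
                counts[locus][a] = counts[locus].get(a, 0) + 1
    freqs = {}
    for locus in loci:
        total = sum(counts[locus].values())
        if total == 0:
            raise InsufficientDataError(f"locus {locus}: no typed individuals")
        freqs[locus] = {a: c / total for a, c in counts[locus].items()}
    return AlleleFrequencyTable(freqs)


def genotypes_to_array(records_or_genotypes) -> np.ndarray:
    """Stack genotypes into an ``(n, L, 2)`` int array, missing coded as -1.

    Accepts IndividualRecords or bare MultilocusGenotypes on a common panel.
    """
    genos = [
        r.genotype if isinstance(r, IndividualRecord) else r
        for r in records_or_genotypes
    ]
    if not genos:
        return np.empty((0, 0, 2), dtype=np.int64)
    loci = genos[0].loci
    out = np.full((len(genos), len(loci), 2), -1, dtype=np.int64)
    for i, g in enumerate(genos):
        if g.loci != loci:
            raise ArgumentError("genotypes are on different locus panels")
        for j, pair in enumerate(g.alleles):
            if pair is not MISSING:
                out[i, j] = pair
    return out


def array_to_genotypes(arr: np.ndarray, loci: Sequence[str]) -> list:
    """Inverse of :func:`genotypes_to_array`."""
    out = []
    for row in arr:
        pairs = tuple(
            MISSING if row[j, 0] < 0 else (int(row[j, 0]), int(row[j, 1]))
            for j in range(len(loci))
        )
        out.append(MultilocusGenotype(tuple(loci), pairs))
    return out
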