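"""Synthetic genotype, pedigree, group and behaviour generators.

Everything downstream of the field data is testable against this module: it
produces multilocus microsatellite genotypes under Hardy–Weinberg equilibrium
at user-set allele frequencies, Mendelian inheritance by explicit gamete
dropping, strictly maternal mtDNA haplotype transmission, an observation
model (per-locus genotyping error and missingness), and group compositions
matching the field group types (A adult–calf dyad, A1 triad, B adults with
calves, C juveniles only, D adults only, E mixed-age groups; F adult-only
and G mixed-age herds).

Dyads for estimator validation and threshold calibration are generated by
explicit pedigree gamete dropping — parents are drawn from HWE and gametes
segregate independently per locus — never by sampling IBD states from the
category's k-coefficients. This keeps the generator an independent oracle
for the likelihood machinery, which *is* built from k-coefficients.

The default panel (8 unlinked loci, 10 equifrequent alleles each) mirrors an
informative microsatellite panel of the kind used for odontocete kinship
work; frequencies are configurable to stress-test low-information panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    AlleleFrequencyTable,
    BehaviourTally,
    GroupRecord,
    IndividualRecord,
    MultilocusGenotype,
    array_to_genotypes,
)
from .errors import ArgumentError, GenerationError

DEFAULT_LOCI = tuple(f"L{i}" for i in range(1, 9))


@dataclass
class SimulationConfig:
    """All knobs for the generators; ``seed`` fixes every downstream draw."""

    n_loci: int = 8
    n_alleles: int = 10
    allele_freqs: Optional[AlleleFrequencyTable] = None
    n_founders: int = 60
    n_generations: int = 2
    offspring_per_generation: int = 60
    n_haplotypes: int = 8
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ArgumentError(f"{name} must be in [0, 1], got {v}")
        if self.n_loci < 1 or self.n_alleles < 2:
            raise ArgumentError("need at least 1 locus and 2 alleles")

    @property
    def loci(self) -> tuple:
        if self.allele_freqs is not None:
            return tuple(self.allele_freqs.loci)
        return tuple(f"L{i}" for i in range(1, self.n_loci + 1))

    def freqs(self) -> AlleleFrequencyTable:
        if self.allele_freqs is not None:
            return self.allele_freqs
        return AlleleFrequencyTable.equifrequent(self.loci, self.n_alleles)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _freq_arrays(freqs: AlleleFrequencyTable):
    out = []
    for locus in freqs.loci:
        items = sorted(freqs[locus].items())
        alleles = np.array([a for a, _ in items])
        probs = np.array([p for _, p in items], dtype=float)
        out.append((alleles, probs / probs.sum()))
    return out


def hwe_genotypes(freqs: AlleleFrequencyTable, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """``(n, L, 2)`` genotype array of HWE draws, allele pairs sorted."""
    arrays = _freq_arrays(freqs)
    G = np.empty((n, len(arrays), 2), dtype=np.int64)
    for j, (alleles, probs) in enumerate(arrays):
        G[:, j, :] = rng.choice(alleles, size=(n, 2), p=probs)
    return np.sort(G, axis=-1)


def mendelian_offspring(mothers: np.ndarray, fathers: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """One offspring per mother/father row by independent gamete dropping."""
    n, L, _ = mothers.shape
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    gm = mothers[rows, cols, rng.integers(0, 2, size=(n, L))]
    gf = fathers[rows, cols, rng.integers(0, 2, size=(n, L))]
    return np.sort(np.stack([gm, gf], axis=-1), axis=-1)


def sim_dyad_arrays(freqs: AlleleFrequencyTable, category: str, n: int,
                    rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """``n`` gamete-dropped dyads of a true category, as genotype arrays.

    Categories: PO, FS, HS (maternal half-sibs), GG (grandmother–grandchild,
    pooled with HS downstream) and U.
    """
    if n < 1:
        raise ArgumentError("n must be >= 1")
    if category == "U":
        return hwe_genotypes(freqs, n, rng), hwe_genotypes(freqs, n, rng)
    mothers = hwe_genotypes(freqs, n, rng)
    fathers = hwe_genotypes(freqs, n, rng)
    if category == "PO":
        return mothers, mendelian_offspring(mothers, fathers, rng)
    if category == "FS":
        return (
            mendelian_offspring(mothers, fathers, rng),
            mendelian_offspring(mothers, fathers, rng),
        )
    if category == "HS":
        fathers2 = hwe_genotypes(freqs, n, rng)
        return (
            mendelian_offspring(mothers, fathers, rng),
            mendelian_offspring(mothers, fathers2, rng),
        )
    if category == "GG":
        grandmothers = hwe_genotypes(freqs, n, rng)
        mums = mendelian_offspring(grandmothers, hwe_genotypes(freqs, n, rng), rng)
        kids = mendelian_offspring(mums, fathers, rng)
        return grandmothers, kids
    raise ArgumentError(f"unknown category {category!r}")


def sim_dyads(config: SimulationConfig, category: str, n: int,
              rng: Optional[np.random.Generator] = None) -> List[tuple]:
    """Gamete-dropped dyads as pairs of :class:`MultilocusGenotype`."""
    rng = config.rng() if rng is None else rng
    freqs = config.freqs()
    G1, G2 = sim_dyad_arrays(freqs, category, n, rng)
    loci = freqs.loci
    return list(zip(array_to_genotypes(G1, loci), array_to_genotypes(G2, loci)))


@dataclass
class SimulatedPedigree:
    """Individuals with true parent links and derived true dyad categories."""

    individuals: List[IndividualRecord]
    mother: Dict[str, Optional[str]]
    father: Dict[str, Optional[str]]
    generation: Dict[str, int]
    config: SimulationConfig

    def __post_init__(self):
        self._by_id = {r.id: r for r in self.individuals}

    def record(self, ind_id: str) -> IndividualRecord:
        return self._by_id[ind_id]

    def _parents(self, x: str) -> set:
        return {p for p in (self.mother[x], self.father[x]) if p is not None}

    def _grandparents(self, x: str) -> set:
        out = set()
        for p in self._parents(x):
            out |= self._parents(p)
        return out

    def _ancestors(self, x: str) -> set:
        out, stack = set(), [x]
        while stack:
            for p in self._parents(stack.pop()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def true_category(self, a: str, b: str) -> str:
        """True dyad category: PO, FS, HS (incl. grandparent–grandchild),
        'other' (more distant kin), or U."""
        if a == b:
            raise ArgumentError("a dyad needs two distinct individuals")
        pa, pb = self._parents(a), self._parents(b)
        if a in pb or b in pa:
            return "PO"
        if pa and pa == pb and len(pa) == 2:
            return "FS"
        if pa & pb:
            return "HS"
        if a in self._grandparents(b) or b in self._grandparents(a):
            return "HS"
        if (self._ancestors(a) | {a}) & (self._ancestors(b) | {b}):
            return "other"
        return "U"

    def truth_table(self) -> Dict[frozenset, str]:
        ids = [r.id for r in self.individuals]
        return {
            frozenset((x, y)): self.true_category(x, y)
            for i, x in enumerate(ids)
            for y in ids[i + 1:]
        }


def sim_population(config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None) -> SimulatedPedigree:
    """Founders from HWE; later generations by gamete dropping.

    Founders are unrelated adults (half F, half M) carrying mtDNA labels from
    a pool of ``n_haplotypes``; each offspring generation samples a mother
    and father from earlier generations, inherits the mother's haplotype, and
    is aged by depth (intermediate generations juvenile, the last calves).
    """
    rng = config.rng() if rng is None else rng
    freqs = config.freqs()
    loci = freqs.loci
    haplotype_pool = [f"H{i}" for i in range(1, config.n_haplotypes + 1)]

    individuals: List[IndividualRecord] = []
    mother: Dict[str, Optional[str]] = {}
    father: Dict[str, Optional[str]] = {}
    generation: Dict[str, int] = {}
    genos: Dict[str, np.ndarray] = {}

    nf = config.n_founders
    G0 = hwe_genotypes(freqs, nf, rng)
    sexes = np.array(["F"] * (nf // 2) + ["M"] * (nf - nf // 2))
    rng.shuffle(sexes)
    for i in range(nf):
        ind = f"I{len(individuals):04d}"
        genos[ind] = G0[i]
        individuals.append(
            IndividualRecord(
                id=ind,
                genotype=MultilocusGenotype(
                    loci, tuple(tuple(G0[i, j]) for j in range(len(loci)))
                ),
                mtdna=str(rng.choice(haplotype_pool)),
                sex=str(sexes[i]),
                age_class="adult",
            )
        )
        mother[ind] = father[ind] = None
        generation[ind] = 0

    for gen in range(1, config.n_generations + 1):
        females = [r.id for r in individuals if r.sex == "F" and generation[r.id] < gen]
        males = [r.id for r in individuals if r.sex == "M" and generation[r.id] < gen]
        if not females or not males:
            raise GenerationError("pedigree needs founders of both sexes")
        age = "calf" if gen == config.n_generations else "juvenile"
        for _ in range(config.offspring_per_generation):
            m = str(rng.choice(females))
            f = str(rng.choice(males))
            child_geno = mendelian_offspring(
                genos[m][None], genos[f][None], rng
            )[0]
            ind = f"I{len(individuals):04d}"
            genos[ind] = child_geno
            individuals.append(
                IndividualRecord(
                    id=ind,
                    genotype=MultilocusGenotype(
                        loci,
                        tuple(tuple(child_geno[j]) for j in range(len(loci))),
                    ),
                    mtdna=next(r.mtdna for r in individuals if r.id == m),
                    sex="F" if rng.random() < 0.5 else "M",
                    age_class=age,
                )
            )
            mother[ind] = m
            father[ind] = f
            generation[ind] = gen

    return SimulatedPedigree(individuals, mother, father, generation, config)


#: sex/age templates per group type: (allowed sexes, allowed age classes)
_GROUP_TEMPLATES = {
    "C": (("F", "M"), ("juvenile",)),
    "D": (("M",), ("adult",)),
    "E": (("F", "M"), ("adult", "juvenile", "calf")),
    "F": (("M",), ("adult",)),
    "G": (("F", "M"), ("adult", "juvenile", "calf")),
}


def _mother_calf_pairs(pedigree: SimulatedPedigree) -> List[tuple]:
    pairs = []
    for r in pedigree.individuals:
        if r.age_class != "calf":
            continue
        m = pedigree.mother[r.id]
        if m is not None and pedigree.record(m).age_class == "adult":
            pairs.append((m, r.id))
    return pairs


def sim_groups(pedigree: SimulatedPedigree, group_type: str, size: int,
               kin_mode: str = "mixed",
               rng: Optional[np.random.Generator] = None,
               group_id: str = "sim") -> GroupRecord:
    """Sample a group whose composition matches the field group type.

    ``kin_mode``: ``matrilineal`` draws members from one maternal line
    (single mtDNA label), ``unrelated`` draws pairwise true-U members,
    ``mixed`` imposes no kin constraint.
    """
    rng = pedigree.config.rng() if rng is None else rng
    if kin_mode not in ("matrilineal", "mixed", "unrelated"):
        raise ArgumentError(f"unknown kin_mode {kin_mode!r}")

    if group_type in ("A", "A1", "B"):
        pairs = _mother_calf_pairs(pedigree)
        rng.shuffle(pairs)
        if group_type == "A":
            if not pairs:
                raise GenerationError("no mother–calf pair in pedigree")
            members = list(pairs[0])
        elif group_type == "A1":
            by_mother: Dict[str, list] = {}
            for m, c in pairs:
                by_mother.setdefault(m, []).append(c)
            twos = [(m, cs) for m, cs in by_mother.items() if len(cs) >= 2]
            if not twos:
                raise GenerationError("no mother with two calves in pedigree")
            m, cs = twos[0]
            members = [m] + cs[:2]
        else:  # B: adults with calves
            need = max(1, size // 2)
            chosen, used = [], set()
            for m, c in pairs:
                if m in used or c in used:
                    continue
                chosen.append((m, c))
                used.update((m, c))
                if len(chosen) == need:
                    break
            if len(chosen) < need:
                raise GenerationError(
                    f"only {len(chosen)} disjoint mother–calf pairs available"
                )
            members = [x for pair in chosen for x in pair]
    else:
        try:
            sexes, ages = _GROUP_TEMPLATES[group_type]
        except KeyError:
            raise ArgumentError(f"unknown group type {group_type!r}") from None
        pool = [
            r.id
            for r in pedigree.individuals
            if r.sex in sexes and r.age_class in ages
        ]
        if kin_mode == "matrilineal":
            by_hap: Dict[str, list] = {}
            for x in pool:
                by_hap.setdefault(pedigree.record(x).mtdna, []).append(x)
            candidates = [xs for xs in by_hap.values() if len(xs) >= size]
            if not candidates:
                raise GenerationError(
                    f"no maternal line with {size} eligible members"
                )
            xs = candidates[int(rng.integers(len(candidates)))]
            members = list(rng.choice(xs, size=size, replace=False))
        elif kin_mode == "unrelated":
            order = list(rng.permutation(pool))
            members = []
            for x in order:
                if all(pedigree.true_category(x, y) == "U" for y in members):
                    members.append(x)
                if len(members) == size:
                    break
            if len(members) < size:
                raise GenerationError(
                    f"could not assemble {size} pairwise-unrelated members"
                )
        else:
            if len(pool) < size:
                raise GenerationError(
                    f"only {len(pool)} eligible members for type {group_type}"
                )
            members = list(rng.choice(pool, size=size, replace=False))

    return GroupRecord(
        group_id=group_id,
        group_type=group_type,
        member_ids=[str(m) for m in members],
        size_observed=None,
        behaviour=None,
    )


def apply_observation_model(records: Sequence[IndividualRecord],
                            freqs: AlleleFrequencyTable, error_rate: float,
                            missing_rate: float, seed: int) -> List[IndividualRecord]:
    """Per individual per locus: drop to missing with ``missing_rate``, else
    replace the genotype by a fresh HWE draw with ``error_rate``."""
    for name, v in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= v <= 1.0:
            raise ArgumentError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed)
    arrays = _freq_arrays(freqs)
    out = []
    for r in records:
        pairs = list(r.genotype.alleles)
        for j, (alleles, probs) in enumerate(arrays):
            u = rng.random()
            if u < missing_rate:
                pairs[j] = None
            elif u < missing_rate + (1 - missing_rate) * error_rate:
                draw = np.sort(rng.choice(alleles, size=2, p=probs))
                pairs[j] = (int(draw[0]), int(draw[1]))
        out.append(
            r.with_genotype(MultilocusGenotype(r.genotype.loci, tuple(pairs)))
        )
    return out


def sim_behaviour_tallies(proportions: Sequence[float], n: int,
                          seed: int) -> BehaviourTally:
    """Multinomial draw of ``n`` observations over Travel/Mill/Social/Other."""
    p = np.asarray(proportions, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ArgumentError("proportions must be 4 non-negative values summing to 1")
    if n < 1:
        raise ArgumentError("n must be >= 1")
    counts = np.random.default_rng(seed).multinomial(n, p)
    return BehaviourTally(*(int(c) for c in counts))


# ---------------------------------------------------------------------------
# Structured fixtures used by the group-level tests


def sim_matriline_herd(freqs: AlleleFrequencyTable, n_matrilines: int,
                       members_per_matriline: int,
                       rng: np.random.Generator) -> List[IndividualRecord]:
    """A herd of distinct maternal lines: each line is a matriarch plus her
    offspring by random sires (a mix of FS and HS sharing her mtDNA label);
    lines are mutually unrelated."""
    loci = freqs.loci
    records = []
    for k in range(n_matrilines):
        hap = f"M{k + 1}"
        matriarch = hwe_genotypes(freqs, 1, rng)
        n_off = members_per_matriline - 1
        # a couple of sires reused across offspring -> FS and HS mixture
        sires = hwe_genotypes(freqs, max(2, n_off // 3), rng)
        mothers = np.repeat(matriarch, n_off, axis=0)
        sire_idx = rng.integers(0, len(sires), size=n_off)
        kids = mendelian_offspring(mothers, sires[sire_idx], rng)
        genos = np.concatenate([matriarch, kids], axis=0)
        for i, g in enumerate(array_to_genotypes(genos, loci)):
            records.append(
                IndividualRecord(
                    id=f"{hap}_{i:02d}",
                    genotype=g,
                    mtdna=hap,
                    sex="F" if i == 0 else ("F" if rng.random() < 0.5 else "M"),
                    age_class="adult" if i == 0 else "juvenile",
                )
            )
    return records


def sim_unrelated_individuals(freqs: AlleleFrequencyTable, n: int,
                              rng: np.random.Generator,
                              haplotype_pool: Optional[Sequence[str]] = None,
                              prefix: str = "U") -> List[IndividualRecord]:
    """``n`` mutually unrelated HWE individuals, optionally with random
    haplotype labels from a pool (for null matriline tests)."""
    G = hwe_genotypes(freqs, n, rng)
    haps = (
        [str(h) for h in rng.choice(list(haplotype_pool), size=n)]
        if haplotype_pool is not None
        else [None] * n
    )
    return [
        IndividualRecord(id=f"{prefix}{i:03d}", genotype=g, mtdna=haps[i])
        for i, g in enumerate(array_to_genotypes(G, freqs.loci))
    ]


def write_demo_dataset(out_dir, seed: int = 0) -> dict:
    """Write a small self-contained demo dataset (genotypes.csv, groups.csv).

    The dataset exercises every pipeline stage: an adult–calf dyad (type A),
    a juvenile group (C), an adult-male group (D), a mixed-age group (E), a
    mixed-age herd (G) large enough for the sibship test, plus a matrilineal
    herd with planted maternal-line structure. Some genotypes carry missing
    loci so the loci filters have work to do. Returns the file paths and the
    underlying pedigree.
    """
    import pathlib

    from .io import write_genotype_csv, write_groups_csv

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(
        n_founders=80, offspring_per_generation=80, n_generations=2, seed=seed
    )
    rng = config.rng()
    pedigree = sim_population(config, rng)
    freqs = config.freqs()

    groups = []
    specs = [
        ("A", "grp_A_dyad", 2, "mixed"),
        ("C", "grp_C_juv", 4, "mixed"),
        ("D", "grp_D_males", 6, "mixed"),
        ("E", "grp_E_mixed", 8, "mixed"),
        ("G", "herd_G_mixed", 20, "mixed"),
    ]
    used = set()
    for gtype, gid, size, mode in specs:
        g = sim_groups(pedigree, gtype, size, mode, rng, group_id=gid)
        g.size_observed = 60 if gtype == "G" else size
        groups.append(g)
        used.update(g.member_ids)

    # planted matrilineal herd appended as extra individuals
    matri = sim_matriline_herd(freqs, 3, 8, rng)
    groups.append(
        GroupRecord("herd_matriline", "G", [r.id for r in matri],
                    size_observed=55)
    )

    behaviour_props = {
        "grp_A_dyad": (0.6, 0.0, 0.1, 0.3),
        "grp_C_juv": (0.1, 0.1, 0.8, 0.0),
        "grp_D_males": (0.5, 0.1, 0.4, 0.0),
        "grp_E_mixed": (0.4, 0.2, 0.3, 0.1),
        "herd_G_mixed": (0.4, 0.25, 0.25, 0.1),
        "herd_matriline": (0.45, 0.25, 0.2, 0.1),
    }
    for g in groups:
        g.behaviour = sim_behaviour_tallies(
            behaviour_props[g.group_id], 40, seed=(seed * 977 + len(g.group_id))
        )

    grouped = set().union(*(g.member_ids for g in groups))
    records = [r for r in pedigree.individuals if r.id in grouped] + matri
    for g in groups:  # tag records with their group for the CSV round trip
        for i, r in enumerate(records):
            if r.id in g.member_ids and r.group_id is None:
                records[i] = IndividualRecord(
                    id=r.id, genotype=r.genotype, mtdna=r.mtdna, sex=r.sex,
                    age_class=r.age_class, group_id=g.group_id,
                    location="sim", date=None,
                )
    # sprinkle missingness so loci filters are exercised (kept mild so the
    # demo groups survive the >= 6-locus filter)
    records = apply_observation_model(records, freqs, 0.0, 0.03, seed + 13)

    genotype_path = out / "genotypes.csv"
    groups_path = out / "groups.csv"
    write_genotype_csv(records, genotype_path)
    write_groups_csv(groups, groups_path)
    return {
        "genotypes": genotype_path,
        "groups": groups_path,
        "pedigree": pedigree,
        "n_individuals": len(records),
    }


def sim_sib_families(freqs: AlleleFrequencyTable, n_families: int,
                     family_size: int, rng: np.random.Generator,
                     prefix: str = "S") -> List[IndividualRecord]:
    """Full-sib families (children only); families mutually unrelated."""
    loci = freqs.loci
    records = []
    for k in range(n_families):
        mother = hwe_genotypes(freqs, 1, rng)
        father = hwe_genotypes(freqs, 1, rng)
        kids = mendelian_offspring(
            np.repeat(mother, family_size, axis=0),
            np.repeat(father, family_size, axis=0),
            rng,
        )
        for i, g in enumerate(array_to_genotypes(kids, loci)):
            records.append(
                IndividualRecord(id=f"{prefix}{k}_{i:02d}", genotype=g)
            )
    return records
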