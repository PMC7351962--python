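"""ML relationship classification: likelihood table, error model, PO exclusion."""

import itertools
import math

import numpy as np
import pytest

from kinpods import (
    AlleleFrequencyTable,
    IndividualRecord,
    classify_dyad,
    dyad_category_likelihoods,
    exclude_po_pairs,
)
from kinpods.classify import CATEGORIES, locus_likelihood
from kinpods.core import array_to_genotypes
from kinpods.errors import ArgumentError, InsufficientDataError
from kinpods.simulate import SimulationConfig, sim_dyad_arrays, sim_population

from conftest import make_genotype


def _all_genotypes(alleles):
    return [
        (a, b) for a, b in itertools.combinations_with_replacement(alleles, 2)
    ]


class TestLocusLikelihood:
    def test_biallelic_shared_homozygote_values(self):
        # single locus, equifrequent alleles; exact mixture values
        f = {1: 0.5, 2: 0.5}
        g = (1, 1)
        assert locus_likelihood(g, g, f, "PO") == pytest.approx(0.125)
        assert locus_likelihood(g, g, f, "U") == pytest.approx(0.0625)
        assert locus_likelihood(g, g, f, "FS") == pytest.approx(0.140625)
        assert locus_likelihood(g, g, f, "HS") == pytest.approx(0.09375)

    @pytest.mark.parametrize("n_alleles", [2, 3, 4])
    @pytest.mark.parametrize("category", CATEGORIES)
    @pytest.mark.parametrize("error_rate", [0.0, 0.05])
    def test_likelihood_sums_to_one_over_ordered_pairs(
        self, n_alleles, category, error_rate
    ):
        """Per-locus likelihoods are a probability distribution over
        ordered genotype pairs (exhaustive enumeration)."""
        alleles = list(range(1, n_alleles + 1))
        # uneven frequencies so the test is not special to the uniform case
        raw = np.arange(1, n_alleles + 1, dtype=float)
        probs = raw / raw.sum()
        f = dict(zip(alleles, probs))
        total = sum(
            locus_likelihood(g1, g2, f, category, error_rate)
            for g1 in _all_genotypes(alleles)
            for g2 in _all_genotypes(alleles)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_error_rate_zero_equals_plain_likelihood(self):
        f = {1: 0.3, 2: 0.2, 3: 0.5}
        for g1 in _all_genotypes([1, 2, 3]):
            for g2 in _all_genotypes([1, 2, 3]):
                for cat in CATEGORIES:
                    assert locus_likelihood(g1, g2, f, cat, 0.0) == (
                        locus_likelihood(g1, g2, f, cat)
                    )

    def test_symmetric_in_members(self):
        f = {1: 0.6, 2: 0.3, 3: 0.1}
        for g1 in _all_genotypes([1, 2, 3]):
            for g2 in _all_genotypes([1, 2, 3]):
                for cat in CATEGORIES:
                    assert locus_likelihood(g1, g2, f, cat, 0.05) == (
                        pytest.approx(locus_likelihood(g2, g1, f, cat, 0.05))
                    )


class TestDyadLikelihoods:
    def test_zero_sharing_locus_gives_minus_inf_po(self):
        f = AlleleFrequencyTable.equifrequent(["L1"], 4)
        g1 = make_genotype([(1, 2)])
        g2 = make_genotype([(3, 4)])
        ll = dyad_category_likelihoods(g1, g2, f, 0.0, min_shared_loci=1)
        assert ll["PO"] == -math.inf
        assert math.isfinite(ll["U"])

    def test_error_rate_keeps_po_finite(self):
        f = AlleleFrequencyTable.equifrequent(["L1"], 4)
        g1 = make_genotype([(1, 2)])
        g2 = make_genotype([(3, 4)])
        ll = dyad_category_likelihoods(g1, g2, f, 0.05, min_shared_loci=1)
        assert math.isfinite(ll["PO"])

    def test_error_rate_out_of_range(self):
        f = AlleleFrequencyTable.equifrequent(["L1"], 4)
        g = make_genotype([(1, 2)])
        with pytest.raises(ArgumentError):
            dyad_category_likelihoods(g, g, f, 0.7, min_shared_loci=1)

    def test_insufficient_shared_loci(self, freqs8x10):
        g1 = make_genotype([(1, 2)] + [None] * 7)
        g2 = make_genotype([(1, 2)] * 8)
        with pytest.raises(InsufficientDataError):
            dyad_category_likelihoods(g1, g2, freqs8x10)


def _perturbed_po_dyads(freqs, n, rng):
    """True PO dyads with one locus of member 2 forced to share no alleles."""
    G1, G2 = sim_dyad_arrays(freqs, "PO", n, rng)
    n_alleles = len(freqs[freqs.loci[0]])
    for i in range(n):
        avoid = set(G1[i, 0]) | set(G2[i, 0])
        novel = next(a for a in range(1, n_alleles + 1) if a not in avoid)
        G2[i, 0] = (novel, novel)
    return G1, G2


class TestClassifyDyad:
    def test_mistyped_po_locus_calls_non_po_without_error_model(
        self, freqs8x10, rng
    ):
        G1, G2 = _perturbed_po_dyads(freqs8x10, 200, rng)
        loci = freqs8x10.loci
        best = [
            classify_dyad(
                array_to_genotypes(G1[i][None], loci)[0],
                array_to_genotypes(G2[i][None], loci)[0],
                freqs8x10, 0.0,
            ).best
            for i in range(200)
        ]
        assert all(b in ("FS", "HS", "U") for b in best)
        # the conservative call is typically the half-sib category
        assert best.count("HS") > 100

    def test_error_model_rescues_po_in_majority(self, freqs8x10, rng):
        G1, G2 = _perturbed_po_dyads(freqs8x10, 200, rng)
        loci = freqs8x10.loci
        best = [
            classify_dyad(
                array_to_genotypes(G1[i][None], loci)[0],
                array_to_genotypes(G2[i][None], loci)[0],
                freqs8x10, 0.05,
            ).best
            for i in range(200)
        ]
        assert best.count("PO") > 100

    def test_unrelated_dyads_mostly_called_u(self, freqs8x10, rng):
        G1, G2 = sim_dyad_arrays(freqs8x10, "U", 1000, rng)
        loci = freqs8x10.loci
        n_u = sum(
            classify_dyad(
                array_to_genotypes(G1[i][None], loci)[0],
                array_to_genotypes(G2[i][None], loci)[0],
                freqs8x10, 0.0,
            ).best
            == "U"
            for i in range(1000)
        )
        assert n_u >= 800

    def test_classification_symmetric(self, freqs8x10, rng):
        G1, G2 = sim_dyad_arrays(freqs8x10, "FS", 50, rng)
        loci = freqs8x10.loci
        for i in range(50):
            ga = array_to_genotypes(G1[i][None], loci)[0]
            gb = array_to_genotypes(G2[i][None], loci)[0]
            assert (
                classify_dyad(ga, gb, freqs8x10, 0.0).best
                == classify_dyad(gb, ga, freqs8x10, 0.0).best
            )

    def test_more_loci_improve_category_recovery(self, rng):
        """Raising the panel from 4 to 8 loci improves mean recovery of
        every true category."""
        rates = {}
        for n_loci in (4, 8):
            loci = [f"L{i}" for i in range(n_loci)]
            f = AlleleFrequencyTable.equifrequent(loci, 10)
            for cat in CATEGORIES:
                G1, G2 = sim_dyad_arrays(f, cat, 400, rng)
                hits = sum(
                    classify_dyad(
                        array_to_genotypes(G1[i][None], tuple(loci))[0],
                        array_to_genotypes(G2[i][None], tuple(loci))[0],
                        f, 0.0,
                        min_shared_loci=n_loci,
                    ).best
                    == cat
                    for i in range(400)
                )
                rates[(n_loci, cat)] = hits / 400
        for cat in CATEGORIES:
            assert rates[(8, cat)] > rates[(4, cat)]


class TestExcludePoPairs:
    def _mother_calf_records(self, freqs, rng, extra_unrelated=4):
        from kinpods.simulate import hwe_genotypes, mendelian_offspring

        loci = freqs.loci
        mother = hwe_genotypes(freqs, 1, rng)
        father = hwe_genotypes(freqs, 1, rng)
        calf = mendelian_offspring(mother, father, rng)
        others = hwe_genotypes(freqs, extra_unrelated, rng)
        genos = array_to_genotypes(
            np.concatenate([mother, calf, others]), loci
        )
        ids = ["mom", "calf"] + [f"u{i}" for i in range(extra_unrelated)]
        return [IndividualRecord(id=i, genotype=g) for i, g in zip(ids, genos)]

    def test_one_member_of_po_pair_removed(self, freqs8x10, rng):
        records = self._mother_calf_records(freqs8x10, rng)
        kept = exclude_po_pairs(records, freqs8x10)
        kept_ids = {r.id for r in kept}
        assert len({"mom", "calf"} & kept_ids) == 1
        assert len(records) - len(kept) >= 1

    def test_no_po_pairs_is_a_no_op(self, freqs8x10, rng):
        from kinpods.simulate import hwe_genotypes

        genos = array_to_genotypes(hwe_genotypes(freqs8x10, 6, rng), freqs8x10.loci)
        records = [
            IndividualRecord(id=f"u{i}", genotype=g) for i, g in enumerate(genos)
        ]
        calls_po = [
            c for c in __import__("kinpods").classify_all_pairs(records, freqs8x10)
            if c.best == "PO"
        ]
        if not calls_po:  # unrelated draws can rarely classify PO by chance
            assert exclude_po_pairs(records, freqs8x10) == records

    def test_mother_with_two_offspring_needs_at_most_two_removals(
        self, freqs8x10, rng
    ):
        from kinpods.simulate import hwe_genotypes, mendelian_offspring

        loci = freqs8x10.loci
        mother = hwe_genotypes(freqs8x10, 1, rng)
        f1 = hwe_genotypes(freqs8x10, 1, rng)
        f2 = hwe_genotypes(freqs8x10, 1, rng)
        kids = np.concatenate(
            [mendelian_offspring(mother, f1, rng),
             mendelian_offspring(mother, f2, rng)]
        )
        genos = array_to_genotypes(np.concatenate([mother, kids]), loci)
        records = [
            IndividualRecord(id=i, genotype=g)
            for i, g in zip(["mom", "kid_a", "kid_b"], genos)
        ]
        kept = exclude_po_pairs(records, freqs8x10)
        assert len(records) - len(kept) <= 2
        # no PO pair remains among the survivors
        from kinpods import classify_all_pairs

        assert all(
            c.best != "PO" for c in classify_all_pairs(kept, freqs8x10)
        )
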