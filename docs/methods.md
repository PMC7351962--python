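# Methods

This note documents the models, procedures and design choices behind
`kinpods`, in the order the pipeline runs them.

## Data model and quality control

An individual carries an unordered pair of integer allele labels at each of
a fixed panel of microsatellite loci; a locus is either fully typed or
missing — half-typed loci are rejected at parse time because no downstream
estimator can use them unambiguously. mtDNA haplotypes are opaque labels
compared only for identity (no sequence handling). Dates are metadata and
are parsed leniently to ISO or dropped.

Two loci thresholds matter. Individuals typed at fewer than **6 of the 8
loci** are excluded from relatedness estimation altogether; the network
stage raises the bar to **≥ 7 loci**, since spurious edges at low marker
overlap distort topology more than they distort averages. The shared-loci
threshold for a *pair* defaults to 6 loci typed in **both** members — a
per-individual threshold alone does not guarantee informative overlap.

Allele frequencies are estimated by allele counting over all typed copies
in the reference sample, which defaults to every individual passing the
6-locus filter; callers may supply an explicit reference (the intended
reference is the source population of the group under study). No bias
correction excludes the focal dyad's alleles: the reference is fixed once,
which keeps every downstream quantity reproducible.

## Relatedness estimators

`r_QG` uses the symmetric multilocus form: per locus and direction x→y with
x = (a, b), y = (c, d),

    num = ½(δ_ac + δ_ad + δ_bc + δ_bd) − p_a − p_b
    den = 1 + δ_ab − p_a − p_b,

summing both directional numerators over usable loci and dividing by the
summed denominators. Loci where both directional denominators are zero (a
heterozygote of two alleles at frequency ½ each, or a monomorphic-in-
practice locus) carry no information and are skipped per pair rather than
failing the pair; a dyad with every locus degenerate has no estimate and is
reported absent. Denominators are never negative when frequencies sum to 1,
so the skipped-locus rule is the only zero-handling needed.

`M_xy` is the per-locus maximum-matching share: 2 if the genotypes are
equal as multisets, 1 if they share at least one allele, 0 otherwise,
divided by 2 and averaged over loci typed in both. It is bounded in [0, 1]
and positive in expectation even for unrelated pairs; that background
sharing shrinks as allele number grows, which the tests verify at 2 versus
10 alleles.

Validation is by parameter recovery against gamete-dropped dyads (an
independent pedigree simulation, not an IBD-coefficient shortcut): mean
r_QG over 1,000 dyads per category recovers 0.5 / 0.5 / 0.25 / 0.0 for
PO / FS / HS / U within ±0.02 on the 8 × 10 panel.

## Relationship classification

Per-locus likelihoods under a category with IBD coefficients (k0, k1, k2)
mix the pair probabilities P_0 = P_HWE(g1)P_HWE(g2),
P_1 = P_HWE(g1)·T(g1→g2) (one allele transmitted from g1, the partner
allele a population draw) and P_2 = P_HWE(g1)·[g1 = g2]. These per-locus
likelihoods are exact probability distributions over ordered genotype
pairs — the tests verify the unit sum by exhaustive enumeration at 2–4
alleles and the match to gamete-dropped empirical pair frequencies by
goodness of fit at n = 10⁴. Loci are assumed unlinked; multilocus
log-likelihoods sum over loci shared by the dyad.

Genotyping error is modelled as an independent per-member per-locus event
of probability e that replaces the recorded genotype by a fresh HWE draw.
The four error patterns collapse to

    L_e = (1−e)² L + (1 − (1−e)²) P_HWE(g1) P_HWE(g2)

because any erroneous member makes the two observations independent with
HWE marginals. At e = 0 this is exactly the error-free likelihood; PO gets
−∞ at any zero-sharing locus. At e = 0.05 a true PO dyad carrying one
mistyped locus is classified PO again in the large majority of replicates —
the qualitative behaviour the error model exists to produce. Exact internal
details of established ML kinship software are not reproduced here; this
minimal replacement model is fully specified and testable.

Ties in the maximum are broken toward the less related category
(U > HS > FS > PO), the conservative convention.

**PO exclusion** (a precondition of the sibship test) is greedy: while any
remaining pair classifies PO, remove the member with fewer typed loci
(ties: the lexicographically larger id). A mother with several offspring is
usually resolved by removing the mother alone. The classifier runs at
e = 0 for this step by default (configurable); which member to remove is a
package convention, as the procedure only requires that one member of each
PO pair go.

## Matriline contrast

Observed statistic: Δ = mean r over same-haplotype pairs − mean r over
different-haplotype pairs, within a group. The null is built by permuting
the haplotype labels across the group members and recomputing Δ (50,000
permutations by default; tests use 1,000–10,000 for speed). This
label-permutation scheme is the exact-null analogue of a randomization of
the data and is unambiguous to implement; 90/95/99% bands of the permuted
distribution are reported alongside the two-tailed add-one p-value
(p ≥ 1/(n+1), never 0). Permutations that land all stored pairs in one
class (possible when the matrix has absent pairs) are dropped and the
effective permutation count reported. The test depends only on the
same/different partition, so it is invariant to haplotype relabelling.
Calibration: type-I error at α = 0.05 is within [0.03, 0.07] over 500 null
replicates; power on a planted 3-matriline herd of 24 is ≈ 1.

## Sibship frequency test

Thresholds separating U/HS and HS/FS are calibrated per estimator by
simulating n_sim ≥ 200 (default 1,000) gamete-dropped dyads per category
from the reference frequencies and placing each cut where total
misclassification between the two adjacent empirical distributions is
minimal (midpoint of the optimal plateau of the empirical-CDF crossing).
A panel whose optimal cut still misclassifies ≥ 45% — barely better than a
coin flip — fails calibration, as does an inverted ordering
(t_FS/HS ≤ t_HS/U); a single biallelic locus fails this way. Because
thresholds are re-derived from simulations, observed sibling proportions
vary slightly across calibration runs; under a fixed seed everything is
bit-reproducible.

The test scores all within-group pairs (PO pairs must have been excluded;
this is verified by reclassification unless disabled), counts pairs above
t_HS/U as siblings (split FS/HS at t_FS/HS), and compares that count
against the mean sibling proportion among `n_randomizations` (default 100;
1 gives single-draw mode) samples of unrelated HWE individuals of the same
size, by Pearson χ² on sibling/non-sibling counts with 1 df and no Yates
correction — the plainest reading of comparing observed to expected
frequencies. Pairs within a group share individuals, so the χ² variance is
mildly optimistic; measured coverage on unrelated groups of 30 is ≈ 93%
at nominal 95%, which the acceptance suite accepts as "approximately
nominal". Power against 5 planted full-sib families of 4 in a group of 20
is ≈ 0.95 on the 8 × 10 panel.

## Networks

Candidate edges are all stored pairs of a relatedness matrix built at
≥ 7 shared loci (relatedness converts to distance d = 1 − r, but only the
weight order matters). Automatic thresholding adds edges strongest-first
and places the cut at the percolation transition, detected as the maximum
of the susceptibility S = Σ s²·n_s / N over components excluding the
largest; the *last* step attaining the maximum is used, so the network
keeps every edge down to the transition weight while still excluding the
merge that collapses the components. This rule is order-statistic based —
invariant to any monotone transform of the weights — and splits planted
two-family graphs joined by a weak spurious edge essentially always. The
alternative modes keep exactly the edges whose dyad classified PO/FS/HS
("exclude unrelated"), or apply a user threshold globally.

Metrics are computed on the unweighted thresholded graph: degree k;
betweenness bc unnormalised with fractional credit over tied shortest
paths (reduces to integer path counts when shortest paths are unique, and
is verified against exhaustive shortest-path enumeration on all graphs of
≤ 8 nodes); clustering C, reported as 0 with an explicit undefined flag
for k < 2 so group means stay defined. Isolated individuals remain in the
node set (k = 0 is a finding, not an error). Attribute comparisons use a
Welch t-test for two levels and one-way ANOVA for more, applied separately
to k, bc and C; a metric with no variance reports statistic 0, p = 1.

## Behavioural diversity

The printed form of the index, D = 1 − ((Σ d_i²·n)/n − 1), is ambiguous in
its final division. The default is the unbiased-Simpson reading
1 − (n Σ d_i² − 1)/(n − 1), which is 0 for single-category tallies and
bounded in [0, 1]; `literal` mode preserves the as-printed expression
1 − n Σ d_i²/(n − 1), which can be negative (−0.25 for five observations
in one category). Both converge to 1 − Σ d_i² as n grows; the toggle makes
the ambiguity explicit rather than silently resolving it. Fisher exact
tests compare one category against the rest between two groups, reported
per comparison without multiple-testing correction (a correction flag
exists but is off by default, matching how such pairwise comparisons are
conventionally reported in this literature — see limitations).

## Synthetic data

The generator emulates what the analyses assume: Hardy–Weinberg founders at
user-set allele frequencies (default 8 unlinked loci × 10 equifrequent
alleles, an informative panel of the kind used for odontocete kinship
work), Mendelian inheritance by explicit per-locus gamete dropping,
strictly maternal haplotype transmission, 50:50 sexes, age classes from
pedigree depth, and an observation model of per-locus missingness and
HWE-redraw genotyping error. Group templates mirror the field group types
(adult–calf dyad, adults-with-calves, juvenile-only, adult-male-only,
mixed groups and herds) with matrilineal / mixed / unrelated kin modes.

Deliberately, dyads are generated by pedigree gamete dropping and never by
sampling IBD states from k-coefficients — the classifier's likelihood
table *is* built from k-coefficients, so the generator remains an
independent oracle rather than a circular one.

What the generator does not emulate: linkage, mutation, null alleles,
population structure and allele-frequency drift between reference and
group, non-random mating, and spatial/temporal association structure.
Passing tests therefore demonstrate correctness of the machinery under the
stated population-genetic idealisations, not robustness of the field
inferences to their violation.

## Numerical and scale choices

* Default permutation count 50,000 (the analysis-scale value); tests and
  the demo config use 1,000–10,000, and the acceptance script states its
  sizes in its output. Simulated calibration uses 1,000 dyads per category.
* Permutation p-values use the add-one convention.
* Degenerate inputs fail loudly with typed exceptions (insufficient data,
  untestable null, calibration failure) and the pipeline records those
  sections as unavailable/untestable instead of aborting the run.
* All randomness flows from explicit seeds; the pipeline derives stage
  seeds deterministically from the run seed, and its JSON report contains
  no timestamps, so repeated runs are byte-identical.
* Seeds derived internally stay below 2³¹.

## Known limitations

* The r_wang dyadic-likelihood estimator and likelihood-ratio confidence
  for relationship calls are not implemented; r_QG and M_xy cover the
  moment and sharing families actually contrasted.
* No null-allele or allelic-dropout modelling in the classifier.
* The sibship χ² ignores pair dependence (see above); its p-values are
  mildly anti-conservative.
* Fisher comparisons are reported per pair without correction by default.
* Network betweenness uses the unweighted thresholded graph; weighted-path
  betweenness and community detection beyond connected components are out
  of scope.
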