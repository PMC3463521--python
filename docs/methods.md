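# Methods

## Karyomorph representation

A karyomorph is a multiset of four chromosome codes over the alphabet
{M, T, m, St}. It is *balanced* when exactly two codes belong to the
chromosome-1 complement {M, T} (and hence two to {m, St}); the nine
balanced multisets map to Roman labels through the grid
I = MM/mm, II = MM/mSt, III = MT/mm, IV = MT/mSt, V = MT/StSt,
VI = MM/StSt, VII = TT/mm, VIII = TT/mSt, IX = TT/StSt. The ten
genically unbalanced multisets reachable from heterozygote gametes use a
systematic label, the codes joined in canonical order (M < T < m < St),
e.g. `MMTm`. Labels are pure functions of the sorted multiset, so any
input ordering or within-pair homolog swap yields the same karyomorph.

## Morphometric classification

Centromere position follows Levan's arm-ratio (AR = long arm / short arm)
nomenclature with half-open intervals, lower bound inclusive:
metacentric [1.0, 1.7), submetacentric [1.7, 3.0), subtelocentric
[3.0, 7.0), telocentric [7.0, ∞). Size class is large iff relative length
(RL) ≥ 7.0% (configurable); the default cutoff cleanly separates the
largest small chromosome (RL 6.09) from the smallest large one (RL 8.19)
in both packaged reference idiograms.

**Relative-length scale.** RL is stored as percent of one haploid
complement, so a cell's 26 values sum to ≈ 200. Published idiogram columns
normalize over different entry sets (a homomorphic column over its 13 pair
entries, a heteromorphic column over 15 entries counting each heteromorphic
homolog singly), so their raw per-cell sums differ by up to ~20%.
Classification therefore rescales each cell to the common scale before size
calls, making the result scale-invariant; a sanity check rejects cells
whose per-haploid sum is outside 100 ± 25 (catching wrong-unit input such
as fractions instead of percent) and can be tightened or disabled via
`KaryoConfig`.

**Whole-cell karyotyping.** A cell must have exactly 26 records forming 13
homolog pairs (2n = 26 enforced). The chr-1 slot is the pair carrying 5S
FISH signals when flags are present (the 5S locus rides on both M and T, so
the flags are authoritative even if pair numbering is shuffled); otherwise
pair 1 by karyotype numbering, or — with `infer_slots` or when numbering is
unusable — the largest pair whose members are both large and
metacentric/telocentric-like, with an `AmbiguityError` naming candidate
pairs when the runner-up is within 1 RL% (configurable margin). The chr-6
slot is pair 6, or by morphology the unique pair containing a
subtelocentric member, else the largest small-metacentric pair.

Within an identified focal pair, a homolog is called translocated (T or
St) when its AR ≥ 1.7, i.e. anything beyond the metacentric range. We do
not require the exact Levan class here: at the reference measurement noise
the T homolog (AR 7.11 ± 0.11) sits ~1 SD from the telocentric boundary
and St (3.35 ± 0.31) ~1 SD from the subtelocentric one, so exact-class
calls would misname ~15% of homologs, while the 1.7 rule is ≥ 4.8 SD from
every focal mean. This is what makes the ≥ 99% round-trip property hold;
the per-chromosome report still contains the exact Levan class of every
chromosome.

## Segregation and crosses

Only the double heterozygote (type IV) forms a quadrivalent; its gamete
distribution puts (mode weight)/2 on each of the mode's two gametes, with
mode probabilities (p_alt, p_adj1, p_adj2) on the 2-simplex (tolerance
1e-9). Every other genotype has at most one heteromorphic slot and is
modelled as independent bivalents: one chromosome per slot, uniform.
Whether adjacent-1 gametes are equiprobable within their mode is not
empirically constrained; the equal split is assumed throughout. For
completeness, unbalanced genotypes whose four chromosomes all fall in one
slot contribute uniform same-slot pairs; under the default viability these
genotypes never reproduce, so this choice is inert.

Offspring enumeration forms all unordered gamete pairings (self-pairings
included) and collapses karyologically identical multisets: zygotes that
are karyologically MT/mSt arise from three different pairings (balanced ×
balanced, adjacent-1 × adjacent-1, adjacent-2 × adjacent-2) and are merged
as type IV — the package counts karyology, and genic balance can be
tracked separately through `Gamete.balanced`.

Crosses convolve the two parental gamete distributions, weight each
zygote class by its viability, and renormalize over the surviving mass
(fecundity compensation — observed frequencies are among living animals).
An unnormalized mode reports zygotic mortality instead. A cross with zero
surviving mass is signalled (`CrossResult.sterile`), not raised. The
default viability map sets types I–V to 1 and the other fourteen
enumerable karyomorphs (VI–IX and all unbalanced multisets) to 0,
encoding the observed lethal set.

## Population dynamics

Random mating, non-overlapping generations, autosomal inheritance, equal
sex contribution, no selfing. The deterministic step convolves the
mating-pair distribution with per-genotype gamete distributions and
filters by viability. When a state carries integer counts, mating pairs
are drawn without replacement of individuals (`n_a(n_b − δ_ab)` weights):
a class represented by a single individual — a fresh migrant — cannot pair
with itself. This is why a lone type IV arrival among type I residents
produces F1 support {I, II, III, IV} exactly (type V needs two
heterozygote-lineage parents) while V appears from F2 on. Subsequent
deterministic generations carry frequencies only and use f_a·f_b pairing.
The finite-N mode resamples N offspring multinomially each generation from
an explicit `numpy.random.default_rng(seed)`; no global RNG state is
touched, and runs are bit-reproducible from the seed.

`reachable_types` is the set-valued counterpart used for dispersal
analysis: generation 1 is the viable offspring support of migrant ×
resident, and each later generation the viable offspring of all pairs from
the previous set plus the resident type.

## Gamete-pool likelihood

Zygote probabilities under random union of a gamete pool (f₁, f₂, f₃, f₄)
for {M,m}, {T,St}, {M,St}, {m,T} are the nine-type grid given in the
README; type IV collects both 2f₁f₂ and 2f₃f₄ because two distinct gamete
unions are karyologically identical. The likelihood restricts and
renormalizes over types with positive viability and treats observed counts
as multinomial. The reported log-likelihood is in frequency form
(Σ nₖ log pₖ, no multinomial coefficient), hence always ≤ 0.

Optimization runs SLSQP over (f₁, f₂, f₃) with f₄ by complement, bounds
[0, 1] and a simplex inequality, from 16 deterministic starts (centre,
near-vertices, a survey-like point, and Dirichlet draws from a fixed
internal seed so fitting is reproducible). Non-convergence is flagged with
the best point still reported; estimates within 1e-6 of the boundary set
the `boundary` flag — expected for monomorphic or near-monomorphic counts,
where the optimum genuinely lies on the simplex edge. Tests cross-check
the optimizer against a dense simplex grid search (step 0.005) to within
1e-3 log-likelihood. Pooled fitting treats all individuals as one
panmictic sample; per-population fits of small monomorphic samples will
hit the boundary and are reported as such, not suppressed. Profile
confidence intervals are not implemented.

## Arm-length conservation test

For each measured heterozygote cell, S_het = l(1−1) + l(1−2) + l(6−1) +
l(6−2) and S_norm = 2 × (l(1−1) + l(6−1)); a two-sided paired t-test
(scipy `ttest_rel`) across cells compares them. Under a reciprocal
exchange with no loss of material the two sums estimate the same total, so
a non-significant difference (p > 0.05) is consistent with conservation.
Identical sums short-circuit to t = 0, p = 1 (the paired t-statistic is
undefined at zero variance). At least two cells are required. The packaged
ten-cell table recomputes the per-cell sums from the homolog lengths
rather than trusting printed summary rows, which carry 0.01-level rounding
slips; the means agree at two decimals either way (17.72 vs 18.07 μm).

## Synthetic data

`generate_cells` draws each chromosome's RL and AR from truncated normals
(RL > 0, AR ≥ 1) at a reference idiogram's means and SDs, renormalizes
RLs per cell to the 200% scale, and flags chr-1 homologs as 5S-positive.
The packaged moments cover types I and IV; other balanced karyomorphs are
composed from the type IV column by substituting focal-homolog moments
(M = 1-1, T = 1-2, m = 6-1, St = 6-2), per-cell renormalization absorbing
the columns' scale difference. Noise is independent across chromosomes;
real metaphases correlate measurements within a cell (condensation state),
which the generator captures only through RL renormalization — so passing
round-trip tests demonstrate robustness to independent noise at the
published SDs, not to systematic preparation artefacts.

`generate_counts` samples individuals multinomially from the
viability-filtered random-union distribution of a specified gamete pool,
with sexes assigned independently 50/50 — emulating the structure of a
multi-population survey under the model's own null, without spatial
structure or drift between demes. `generate_lengths` multiplies
length-conserving base lengths (defaults 6.5/4.2/2.5/4.8 μm, chosen in the
measured cells' range with l(1−2)+l(6−2) = l(1−1)+l(6−1) exactly) by a
lognormal per-cell scale factor (σ = 0.25, matching the ~2× spread of
total length across real cells) and adds Gaussian noise (0.2 μm), flooring
at 0.05 μm. All generators take a mandatory integer seed and are
byte-reproducible.

## Problem sizes and numerical choices

Enumeration and reachability are exact and instantaneous (≤ 21 gamete
pairings per cross). Test problem sizes — 1000 cells for round-trip
classification, 5000 individuals for parameter recovery, 10⁵ for the
convergence check, grid step 0.005 for the likelihood oracle — are chosen
so each check's sampling error is an order of magnitude below the margin
it asserts. Probability simplex checks use tolerance 1e-9; the
deterministic step matches an explicit double-sum oracle to 1e-12.

## Known limitations

* Chiasma/recombination within the quadrivalent and chain-vs-ring
  multivalent geometry are abstracted into the three mode probabilities.
* No spatially explicit migration, Hardy–Weinberg testing, exact tests, or
  Bayesian fitting.
* Image analysis of metaphase spreads and banding interpretation are out
  of scope: input is tabulated morphometrics.
* Sex is tracked only as survey metadata; karyomorphs are treated as
  strictly autosomal.
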