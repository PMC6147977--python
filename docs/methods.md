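# Methods

This note documents the models, estimators and numerical choices behind
phagekit, what the synthetic-data generator does and does not emulate, and
the known limitations of the procedures.

## Growth/kill model

Liquid infection assays are modelled with deterministic ODE dynamics over
susceptible cells S, m sequential infected stages I_1..I_m, phage-resistant
cells R and free phage P (all per ml):

    dS/dt  = (1 − μ) g S − δ S P − κ_S S
    dI_1   = δ S P − (m/τ) I_1 − κ_I I_1
    dI_j   = (m/τ)(I_{j−1} − I_j) − κ_I I_j      j = 2..m
    dR/dt  = g R + μ g⁺ S − κ_R R
    dP/dt  = β (m/τ) I_m − δ S P

with logistic per-capita growth g = r (1 − N/K), N = S + ΣI + R, and the
observed OD590 = α N + od0. The latent period is Erlang-distributed with
mean τ across m = 5 stages rather than a hard delay: it is smooth,
ODE-friendly, and m is configurable (m → ∞ approaches a fixed delay).
Antibiotic killing is Hill-type, κ = emax·C^h/(ec50^h + C^h), applied to
the dividing compartments S and R in the meropenem-like mode
(`kill_mode="dividing"`; cell-wall synthesis inhibitors kill growing
cells) or to every cell compartment in the colistin-like mode (`"all"`;
membrane disruption is growth-independent). Phage resistance arises as a
fraction μ of divisions; resistant cells are assumed not to adsorb phage.

Defaults (per-ml units, hours): r = 1.4, K = 1e9, δ = 3e-9 ml/h,
β = 39, τ = 0.5 h, emax = 2/h, ec50 = 64 mg/l, h = 2, μ = 1e-10,
α = 4.5e-10 OD·ml/cell, od0 = 0.05, inoculum 2.5e8 cfu/ml. These put the
untreated culture at OD ≈ 0.5 after 16 h, give the phage a burst size of
39 and a 30-min latent period, and make an MOI of 0.1 clear the culture
within a few hours. The burst size and latent period mirror one-step
growth measurements of a T4-like *Acinetobacter* myovirus; the adsorption
constant is chosen so the coupled system stays well resolved on the
integration grid below (in a well-mixed microplate the effective rate is
far below the theoretical diffusion limit). μ = 1e-10 describes a strain
that stays suppressed over 16 h; μ = 1e-6 produces the
decline-then-regrowth phenotype of phage-tenacious strains, and is the
scenario used for the synergy power study.

Integration is fixed-step classical RK4 with 20 substeps per 20-min output
interval (configurable), compartments clamped at 0 after each substep.
At the default parameters the trajectory agrees with an adaptive
stiff-capable reference integrator to better than 1e-6 OD at all output
times; the test suite asserts 1e-3. Cumulative lysis and adsorption
integrals are carried along so the phage balance
P(t) = P(0) + β·lysed − adsorbed is assertable to integrator tolerance.
End-OD is non-increasing in MOI and in antibiotic concentration for the
μ = 0 model; with μ > 0 earlier clearance leaves more time for resistant
regrowth, so dose-monotonicity of end-OD is *not* guaranteed — that is a
feature of the biology, not a numerical artifact.

Observation noise is multiplicative Gaussian on OD (σ = 0.01 by default,
plate-reader-like), clipped at zero. Identical seeds give bit-identical
output; replicates differ only through this noise.

The generator does not model spatial structure or biofilms,
pharmacokinetics, delayed lysis variance beyond the Erlang stages, or
demographic stochasticity (no Gillespie engine): passing recovery tests
shows the estimators invert the generator's assumptions, not that real
cultures obey them. The resistant-subpopulation formulation of regrowth is
this package's stand-in for a mechanism the source assays do not resolve.

## One-step growth and adsorption

The one-step curve is a plateau at titer0 rising sigmoidally (normal CDF,
midpoint τ, width 2 min) to β·titer0, sampled every 5 min for 30 min then
every 10 min to 120 min; plaque counts are Poisson with expectation
titer × 0.1 ml. The burst estimator takes the mean of the first/last k = 3
samples as plateaus ("begin and end of the experiment" made explicit and
tunable) and reports the per-replicate final/initial ratio, mean ± sd.
With ~100-plaque initial counts the Poisson ratio bias is ≈ β/300, well
inside the recovery band asserted in the tests. The latent-period rule
(first sampled time above rise_factor = 2 × the initial plateau) reports at
sampling resolution by design, as does the adsorption t99 (first sampled
time with ≤1% free phage; the threshold is inclusive so an exact 1%
crossing counts).

Free-phage decay is exponential at rate k·cells; the rate estimator is a
weighted least-squares slope of ln(fraction free) against time with
weights proportional to mean counts — the variance-stabilizing choice for
Poisson counts, without which the low-count late samples dominate the fit
and roughly double its error.

## Ortholog clustering

A desk-scale surrogate replaces heuristic all-vs-all BLAST + Markov
clustering pipelines: global (Needleman–Wunsch, unit-cost) alignments for
every gene pair, identity = matches / alignment columns (gap columns in
the denominator — identity definitions vary, so this one is fixed
explicitly), coverage = aligned fraction of the shorter sequence; an edge
requires identity ≥ 0.5 and coverage ≥ 0.5, and families are connected
components (single linkage; a greedy complete-linkage mode exists).
Deterministic given input order; pairs whose length ratio already bounds
identity below threshold are skipped unaligned. On synthetic pan-genomes
the clustering recovers truth families essentially perfectly up to a
per-branch divergence of ~0.1; by ~0.15–0.2 the deepest leaf pairs fall
below the identity threshold and families fragment (the generator warns
when its settings make families unrecoverable by design). Real-data users
analysing more divergent proteomes should lower `min_identity` or expect
family splitting relative to e-value-based clusterers. Singletons are
counted as families private to one genome, not genes — paralogous copies
of a private family count once.

## Trees

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion; ties go to the lowest (i, j) index pair, and negative limb
lengths are clamped to zero with the deficit moved to the sister branch
(at the terminal three-node star the deficit is spread equally over the
other two limbs). Both rules are required for determinism and are
exercised by the additive-recovery tests (exact topology, lengths to
1e-9). Core-gene trees use p-distances on aligned positions, gaps
excluded (the synthetic generator emits no indels); a Poisson correction
−ln(1 − p) is available behind a flag.

"Grouped together" in the consensus is operationalized as cherry
membership: counts(i, j) = number of gene trees in which {i, j} form a
sister pair, turned into distances by the minimal monotone map
1 − count/n_trees, then NJ. This is the only unambiguous pairing notion
for small unrooted trees, but it has a real identifiability limit that the
recovery experiments quantify: the consensus can only firmly recover
splits that *are* cherries of the target topology. For a 6-leaf guide
whose three non-trivial splits are all cherries, recovery under 20% NNI
(nearest-neighbor-interchange) gene-tree noise is essentially certain
(100/100 experiments). For the 2-cherry shape with two lone taxa, the
deep attachment of the lone taxa is informed only by the bias structure of
the error trees: under uniform NNI noise recovery is ~85–90%, and under
NJ-reconstruction noise (gene trees rebuilt from simulated sequences) the
dominant error mode is precisely the lone-taxa cherry, which the consensus
then amplifies into the wrong topology. Consensus trees of this shape
should therefore be read as reliable about sister pairs and suggestive,
at best, about deeper structure — consistent with such consensus trees
differing from presence/absence dendrograms in practice.

Gene-tree "20% topology noise" in the recovery studies means each tree is
independently replaced, with probability 0.2, by a uniformly chosen NNI
neighbor of the guide — the local way reconstruction actually errs; a
uniform-random-topology model is available for comparison.

## Synergy statistics

End-OD is the final-grid-point reading; the AUC is the trapezoid rule over
the n−1 observed intervals with Δt as an exact rational (1/3 h for the
20-min grid — 0.33 is treated as display rounding). A printed summation
formula that indexes one point past the observed grid is resolved in
favour of the self-consistent trapezoid over measured points.

The combination test is one-tailed (alternative: the combination's mean
metric is below the baseline's), Welch unequal-variance by default since
the variance assumption is unverifiable from triplicates; the Student
equal-variance variant sits behind a flag. At n = 3 per arm Welch is
conservative: its measured one-sided type-I rate under an equal-variance
null is ≈ 0.037 at α = 0.05, versus ≈ 0.05 for the exact Student test —
the calibration study checks the Student variant against the
[0.04, 0.06] band and checks Welch against the ≤ 6% control bound. Both
arms constant and equal is reported as t = 0, p = 0.5, flagged degenerate.
No multiple-testing correction is applied by default (matching common
practice in these assays); a Holm option exists in the statistics layer
users can apply to the returned p-values. Baselines follow either rule —
phage alone at the same MOI, or the best-acting single agent at the same
dosage — because published figure legends and methods sections differ on
which applies where; both are implemented and the choice is a parameter.

## Genome records

Record statistics (length, GC%, CDS and tRNA counts) are computed from
GenBank flat files; GC is (G+C)/(A+C+G+T)·100 with ambiguity codes
excluded from numerator and denominator, rounded half-up to two decimals.
Feature counting trusts the record's annotation — no gene prediction is
performed.

## Problem sizes and seeds

Recovery studies run at desk scale chosen to make the suite quick while
keeping Monte-Carlo error small relative to the asserted bands: 200
one-step simulations, 100 adsorption seeds, 100 random additive trees,
100 consensus experiments × 111 gene trees, 10,000 null t-tests, 500
power experiments, and a default synthetic pan-genome of 6 genomes ×
~55–60 families (40 single-copy core, Poisson gains/losses, ~9 private
singletons per genome, 200-aa proteins, divergence 0.1). Every stochastic
stage derives its generator from a single global seed via
`SeedSequence(seed, spawn_key=(crc32(stage),))`, so partial re-runs
reproduce exactly.
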