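# Methods

## The model

`teworld` is a forward-time, agent-based simulation of transposable-element
(TE) proliferation in an asexual host population. Each host carries one
spatially explicit chromosome: a fixed set of genes (500 or 5000 under the
standard configurations), an intergenic block, and a growing set of
fixed-length TE copies. Coordinates are 0-based and half-open; the canonical
layout puts the genes first in index order, then the intergenic block, and
every TE insertion splices `te_length` bp into that layout, shifting
downstream coordinates. Gene and TE lengths default to 1,000 bp and the
initial intergenic block to 10% of the genic bp; none of these three
constants is dictated by the biology being modelled beyond "genes and
non-genic DNA both exist", so they are plain configuration.

Each generation proceeds in a fixed order (the order itself is a
reproducibility choice, not a biological claim):

1. **Replication.** Every live host produces one offspring that inherits
   its survival likelihood L and a copy of its genome; the pool is the
   parents plus offspring (parents also undergo the mutation and TE steps
   by default; `step_parents=False` restricts stepping to offspring).
2. **Background mutation.** Each host draws a Poisson-distributed count of
   gene-hit events with mean `corrected_mutation_rate` and applies each
   exactly like a genic TE insertion. The Poisson choice is standard for
   per-generation event counts; the mechanism behind this rate is isolated
   in one operation so an alternative reading costs one function.
3. **TE lifecycle.** Every active copy first risks death
   (`te_death_rate`, exclusive — a dying copy does not transpose), then
   transposes with `te_excision_rate`, producing `te_progeny` new copies.
   Transposition is replicative (copy-and-paste): copy number can only
   reach the thousands observed in persistent runs if the source copy
   remains. Each new copy draws an insertion site; landing in a gene draws
   an effect class, landing inside another TE or in intergenic DNA has no
   fitness consequence.
4. **Selection.** Candidate i survives with
   `P(s_i) = min(1, L_i / sum_j L_j * C)` where C is the carrying
   capacity. Survival draws are independent Bernoulli by default (matching
   the per-individual probability framing; `selection_mode="exact"` draws
   exactly C weighted without replacement). The uniform effect-magnitude
   term in the survival equation is interpreted as the beneficiary's
   already-applied fitness bump inside L_i rather than fresh additive noise
   for every host: this keeps the sum of survival probabilities exactly C
   and reproduces both printed approximations (55% and 50.5%).

**Insertion effects.** A genic hit is lethal with probability 0.30,
deleterious with 0.20, beneficial with the experimental variable BP
(0–20%), and neutral with the remainder. Deleterious/beneficial hits scale
L multiplicatively by (1 ∓ Δ), applied once and inherited but never
re-applied; lethal hits kill the host in that generation (the step still
completes, so event logs are whole). By default Δ = Me·U(0,1) with
Me ∈ {0.1, 0.01} (`uniform` mode); `fixed` mode uses Δ = Me and exists
because the closed-form survival values quote the full magnitude. The
multiplicative reading is used throughout (the additive form coincides with
it at L ≈ 1); the mode switch documents the ambiguity.

**Insertion bias.** `insertion_bias` ∈ [0, 1] is the relative per-bp
sampling weight of genic DNA: 1 is uniform over all bp, 0 never hits a
gene, so P(genic) = bias·G/(bias·G + NG). The direction (away from genes)
and the per-bp weighting are this package's definition; nothing else in
the model constrains it.

**TE death.** A dying copy is deactivated in place and its bp remain as
non-genic DNA by default (`dead_te_retains_bp=True`): accumulated dead
copies are precisely the "engineered" neutral insertion space that dilutes
the genic target. Setting it to `False` excises the bp instead. Removal of
a copy that contains nested copies re-anchors the nested copies to the
surrounding region rather than deleting them.

## Outcomes

A run ends TE_EXTINCT when no active copy remains in any live host,
HOST_EXTINCT when no live host remains, and PERSIST when both are present
at the generation budget `g_max`. Persistence is therefore always relative
to a horizon; the shipped default is 1,000 generations, and the miniature
experiment uses 200.

## The branching-process analytics

A fresh beneficiary in a homogeneous pool of 2C hosts survives one
generation with ≈ (1+Me)/2 — 55% at Me = 0.1, 50.5% at Me = 0.01, versus
50% for the null host. Afterwards the carrier count follows a cascaded
binomial process: each carrier is doubled and each candidate survives
independently with p, i.e. offspring ~ Binomial(2, p).
`lineage_size_distribution` computes the exact finite-horizon law by the
recursion size(t+1) | size(t)=n ~ Binomial(2n, p), truncating upper-tail
mass below 1e-15 per generation (total truncation < 1e-12 over the T ≤ 20
cap, far inside the 1e-9 normalization tolerance). The ultimate extinction
probability is the smallest fixed point of q = (1−p+pq)²; extinction is
certain for 2p ≤ 1 (the mean-offspring criterion), and for p > 1/2 the
fixed-point iteration from 0 converges geometrically to ((1−p)/p)². Note
(1+Me)/2 quotes the full magnitude; under the uniform-magnitude draw the
expected one-generation survival would be (1+Me/2)/2. The calculator
implements the quoted form; the simulator's default remains the uniform
draw.

Note the finite-horizon/asymptotic gap: at p = 0.55 the exact extinction
mass at T = 20 is 0.6438 while the ultimate value is 0.6694, so Monte-Carlo
cross-checks at modest horizons are compared against the exact finite-T
distribution, not the fixed point.

## The sweep experiment

Eleven 8-character H/L condition codes over (TE_progeny, TE_excision_rate,
TE_death_rate, Insertion_bias, Corrected_mutation_rate, NP_BP,
Mutation_effect, Carrying_capacity) are crossed with six beneficial
probabilities {20, 15, 10, 5, 1, 0}% and replicated, 11×6×3 = 198 runs by
default. The last condition code (LLLLLLHL) is reconstructed from an
ambiguous listing and flagged as such in the source. Per-run seeds are
derived from (base seed, condition index, bp index, replicate index) via
`numpy` seed sequences, so adding conditions or levels never shifts the
streams of existing runs, and results are independent of worker count.

**Level calibration.** The sources that define the condition codes never
print the numeric H/L values. The shipped `LevelMap` is therefore a
calibration chosen once, by simulation regime rather than by fit to any
number: progeny (2, 1), excision rate (0.10, 0.03), death rate
(0.05, 0.005), insertion bias (1.0, 0.5), background mutation rate
(0.1, 0.01), gene count (5000, 500), effect magnitude (0.1, 0.01),
carrying capacity (1000, 100). The excision low level is the load-bearing
choice: at 0.02 host extinction essentially never occurs at desk scale,
while at 0.05 persistence without beneficial insertions vanishes; 0.03
sits where the model shows the reported phenomenology — a majority of runs
losing either their TEs or their hosts, persistence arising at every
beneficial probability including zero, and no monotone relationship
between BP and persistence. Printed full-scale persistence counts identify
this regime, not an exact target, because the original horizons and levels
are unknown.

**Miniature experiment.** Desk-scale work uses `MINIATURE_LEVEL_MAP`
(identical except carrying capacity (150, 50)) and `miniature_plan()`:
all 11 conditions, BP ∈ {20%, 0%}, 10 replicates, 200 generations —
220 runs in roughly ten minutes on one CPU. These sizes are the package's
own default trade-off between statistical resolution and turnaround.

## What the generator does and does not emulate

The simulated genome has no nucleotide sequence, no TE families or decay
of transposition competence with age, no host silencing machinery, no
recombination, sex or horizontal transfer, and gene disruption carries no
fitness cost beyond the one-time insertion effect. Passing tests
demonstrate the internal consistency of this model and the reproducibility
of its qualitative persistence regime; they say nothing about real
genomes, where insertion-effect distributions are neither stationary nor
categorical and population sizes dwarf the carrying capacities used here.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.Generator` (PCG64); every
  public entry point takes a seed or generator, and repeated runs with the
  same seed are bit-identical.
- A pool whose total likelihood is zero raises a population-extinct signal
  rather than dividing by zero; zero carrying capacity yields immediate
  host extinction; a zero generation budget with TEs and hosts present is
  PERSIST by definition.
- `make_effect_model` rejects BP > 0.5 (the neutral class would be
  negative under the fixed 30/20 lethal/deleterious rates).
- Genome length bookkeeping is exact integer arithmetic; an internal
  invariant check recomputes total length from the segment list.

## Known limitations

- Bernoulli selection lets the realized population fluctuate around C;
  runs with tiny C can drift extinct even without TEs. This matches the
  per-individual survival framing but differs from fixed-size resampling
  (available as `selection_mode="exact"`).
- The per-bp insertion-bias definition is one of several defensible
  readings of a bias parameter that was never specified numerically.
- Desk-scale persistence counts depend on the calibration and horizon;
  only the qualitative regime (persistence at BP = 0, non-monotonicity in
  BP, majority non-persistence) is asserted by the tests.
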