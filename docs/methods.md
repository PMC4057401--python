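# Methods

This note documents the models, conventions and design choices behind
`aptaclass`, in the order the pipeline runs them.

## Pool conventions

Pools are FASTA (canonical) or 2-column TSV with `R<round>#<clone>`
identifiers. Sequences must be 40 ± 2 nt (strict by default, overridable
for edge-case testing); `U` is transliterated to `T` with a warning, since
the pools are DNA. Filtering applies two rules before any analysis: a
sequence string occurring in several rounds is kept only in its highest
round (the most evolved copy — within one round the first occurrence wins,
with a warning), and records whose MFE structure has zero base pairs are
removed, since no loop can be extracted from them. The training set is
rounds 1 (label 1, low affinity) and 10 (label 2, high affinity); rounds
2–9 form the unlabeled test pool.

## Secondary-structure model

`fold_mfe` is an exact dynamic program over a nearest-neighbor model:
stacked base pairs contribute tabulated stack free energies (37 °C,
kcal/mol; unified DNA Watson–Crick values), and hairpin, bulge, internal
and multibranch loops contribute length-dependent penalties with
Jacobson–Stockmayer log-extrapolation (prefactor 1.75·R·T ≈ 1.08 kcal/mol)
beyond the tabulated sizes. Conventions: minimum hairpin loop 3 nt;
Watson–Crick pairs plus G·T wobble (toggleable), with stack steps that
involve a wobble pair assigned a single conservative term (−0.30);
multibranch loops cost a + b per branch + c per unpaired nucleotide
(3.4 / 0.4 / 0.1); no dangling ends, no coaxial stacking, no pseudoknots;
bulges do not carry a flanking stack term. Interior loops are capped at 14
unpaired nucleotides total — exhaustive for sequences ≤ 15 nt (the largest
feasible interior loop there is 9) and never binding at 40 nt, where such
loops cost ≳ 5 kcal/mol. The open chain (E = 0) is always admissible, so
E ≤ 0.

`evaluate_energy` is the model definition on a given structure;
`fold_mfe` provably minimizes it (tested against exhaustive enumeration of
all non-crossing structures for short sequences). The parameter table
ships as a versioned plain-text file and is swappable per run, which is
also the plug-in point for users who prefer an external folding engine's
parameters. Absolute E values therefore depend on the configured table;
the pipeline only requires E to be consistent across a pool, and no claim
is made that they match any specific published folder (RNA-parameter
tables, dangles and coaxial terms all shift E by ~10–30%).

Reverse-complement energy symmetry holds for the pure Watson–Crick table;
wobble pairing breaks it by construction (G·T maps to C·A).

## Loop taxonomy and selection

Loops are classified hairpin / bulge / internal, plus `multi` for the
unpaired stretches of a multibranch loop, so that loops + exterior
unpaired positions exactly partition the unpaired nucleotides. The
descriptor loop is chosen by: (1) among loops of 5–7 nt, hairpins first,
then the 5′-most; (2) otherwise the loop nearest 6 nt (ties: smaller,
then 5′-most). The 5–7 window reflects the loop sizes relevant for
protein recognition; the tie-breaks are package conventions and are
deterministic. The loop fragment passed to graph building is loop-only
with 5′-OH/3′-OH termini; a flag can include the closing base pair's
nucleotides (without the hydrogen bond, which topological descriptors
ignore anyway).

## Molecular graphs and descriptors

Each base has a fixed hydrogen-suppressed deoxyribonucleoside template
(base + 2′-deoxyribose heavy atoms: A 18, G 19, C 16, T 17). Fragments
are joined 5′→3′ by phosphodiester bridges (O3′—P—O5′ plus two
non-bridging phosphate oxygens), so V(n) = Σ template atoms + 3(n−1) and
E(n) = Σ template bonds + 4(n−1). 3-D geometry is never needed: PW4, X3A
and JGI2 are functions of the topological graph only. Bond orders are
recorded in the template file for chemical fidelity but all descriptors
use the simple unweighted graph with plain vertex degrees (no
valence-delta heteroatom corrections), matching the degree-based
definitions of the implemented families.

Path counting: χ-type indices use undirected simple paths, each counted
once; atomic path counts for PWk are per starting atom (directional);
walk counts are row sums of Aᵏ, with unrestricted (backtracking) walks.
Dragon's exact walk convention is not published, so absolute PWk values
may differ from Dragon's by a convention factor; within-pipeline ranking
is the contract. JGIk (and XkA, PWk) are defined as 0 when no vertex pair
at distance k (no k-path) exists, keeping descriptor vectors total.
All three families are verified against independent brute-force oracles
(networkx path enumeration, recursive walk counts, definitional
loop-computed charge-term matrices) to 1e-10 on random graphs, and are
permutation-invariant by construction.

## Stepwise descriptor selection

`stepwise_mlr` is classic forward-entry (smallest partial-F p-value,
gate p_enter = 0.05) / backward-removal (gate p_remove = 0.10) multiple
linear regression with the round index as a numeric response — a faithful
reproduction of the conventional stepwise procedure, ordinal response and
all. Constant columns are excluded; candidates with R² > 0.9999 against
the in-model set are skipped as collinear; p-value ties break by column
name, making selection deterministic and column-order invariant. Note the
well-known property of stepwise selection: with ~20 pure-noise candidates
the best null p-value falls below 0.05 in roughly 60% of steps, so an
occasional decoy enters after the true signal; tests assert exactly this
behaviour rather than an idealised zero false-positive rate.

## SVM and genetic algorithm

Features are min–max scaled to [0, 1] on the training set (stored in the
model); with γ up to 1000 and descriptor scales spanning three orders of
magnitude, unscaled training is meaningless. Labels map {1→−1, 2→+1}; the
soft-margin RBF dual is solved by libsvm (scikit-learn `SVC`, tolerance
1e-6), and the model stores support vectors, dual coefficients αᵢyᵢ, bias
and (C, γ). Trained models satisfy the KKT conditions (Σαᵢyᵢ = 0,
0 < αᵢ ≤ C, unit margins at unbounded support vectors) and match a
generic SLSQP solve of the dual to 1e-4 on small problems. Prediction is
the sign of the decision function; the measure-zero f(x) = 0 case maps to
label 1.

The (C, γ) search is a real-coded GA on [1, 1000]²: population 20,
200 generations, tournament selection (size 2), BLX-0.5 blend crossover
(rate 0.8), Gaussian mutation (σ = 5% of range, rate 0.1), elitism 1,
out-of-bounds clipped. Fitness is stratified 5-fold CV accuracy, fully
seeded; the best-so-far history is non-decreasing by elitism. The GA at
full scale matters: CV accuracy is a noisy fitness, and short searches
can settle on over-sharp γ that memorizes the ~5% of round-10 sequences
that are not true binders, degrading round-wise fractions. A fixed preset
(C = 705.933, γ = 749.802) ships for running the deterministic stages
without the stochastic search; with min–max-scaled features that γ is in
the memorization regime (every training point its own kernel island), so
it reproduces training labels nearly perfectly but the GA path should be
preferred for test-round predictions.

## Enrichment summaries

Per round: winning fraction = fraction of records predicted label 2
(training rounds use model predictions, not their assigned labels) and
mean E. The fraction series is fitted by nonlinear least squares
(multistart over the rate) with f(r) = a·(1 − e^(−b(r−1))): a is the
plateau fraction, b the per-round rate, and the curve is anchored so the
naive round-1 pool starts at 0. The anchoring is deliberate: fitting the
unanchored variant a·(1 − e^(−br)) to a ten-round series that starts near
0.01 forces a to its bound (R² ≈ 0.95 vs ≈ 0.99 anchored). A logistic
alternative is available via `form="logistic"`. The mean-E trend reports
the fraction of adjacent round pairs with decreasing mean E; it
approaches 1 only while the pool is still enriching — once the binder
fraction saturates, sampling noise flips roughly half the adjacent pairs,
which is expected behaviour, not a defect.

## Synthetic campaign generator

The generator emulates the study conditions: 10 rounds × 100 clones of
40-mer DNA. Binders are 5′pad — GC stem (default 6 bp) — loop (5–7 nt,
A/C alphabet by default) — reverse-complement stem — 3′pad; A/C loops
cannot base-pair internally, so the designed hairpin survives in the MFE
structure. Candidates are folded at generation time and resampled (rarely
needed, ~1%) until the MFE structure carries ≥ stem−1 pairs and a 5–7-nt
hairpin, so the structural guarantee holds for every emitted binder.
Non-binders are uniform random 40-mers. Substitution noise (0.01/base)
applies to pad regions only — selection conserves the motif — and the
planted binder fraction per round is a binomial draw at
f(r) = a·(1 − e^(−b(r−1))) with defaults a = 0.95, b = 0.6: round 1 is
the naive, binder-free pool, matching how SELEX campaigns start and how
the training construction (round 1 = low affinity) is meant to work.
Ground-truth labels are emitted in a separate file so no stage can
consume them accidentally.

What the generator does not model: PCR amplification bias, sequencing
error, clone-frequency structure, or binders whose affinity arises from
tertiary contacts rather than a stable stem-loop. Passing end-to-end
tests therefore demonstrate that the pipeline recovers a planted
structure-affinity signal of the kind the method assumes — not that the
method succeeds on any real selection.

## Problem sizes and determinism

Default analyses run at the study scale (1000 sequences, full 20×200 GA);
unit tests use smaller pools (10 rounds × 12) and short GA runs, chosen
as the smallest sizes at which each contract is meaningfully exercised.
Every stochastic component (generator, CV folds, GA) is seeded; reruns
with the same configuration are bit-identical, and the pipeline manifest
records the input hash, seeds and parameter provenance.

## Known limitations

- The energy model is deliberately minimal; E values are internally
  consistent, not transferable to other folders' scales.
- The descriptor set is the four-vector the pipeline needs plus the
  surrounding XkA/JGIk/PWk families; it is not a general descriptor
  catalogue.
- The round index used as a numeric regression response is ordinal; this
  mirrors the original analysis design rather than best statistical
  practice.
- With the shipped preset (C, γ) the classifier memorizes; quantitative
  test-round fractions should come from the GA path.
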