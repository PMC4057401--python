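# aptaclass

Structure-based classification of SELEX aptamer pools.

SELEX (Systematic Evolution of Ligands by EXponential enrichment) selects
target-binding oligonucleotides — aptamers — through iterative rounds of
affinity partitioning and PCR amplification. Sequencing the most frequent
clones of each round yields pools of ~40-nt candidates whose binding
quality is unknown without wet-lab assays. `aptaclass` implements a
quantitative structure–activity (QSAR-style) pipeline that classifies
candidates as low- or high-affinity from sequence alone, for computational
chemists and aptamer screeners who want to triage candidates before
synthesis:

1. **Folding** — each candidate's minimum-free-energy (MFE) secondary
   structure is computed with an exact Zuker-style dynamic program over a
   DNA nearest-neighbor model, giving the free energy **E** (kcal/mol).
2. **Loop extraction** — the binding loop is selected from the structure,
   with priority to loops of 5–7 nucleotides (the size range relevant for
   protein binding).
3. **Descriptors** — the loop's hydrogen-suppressed molecular graph is
   assembled from deoxyribonucleotide templates and three topological
   descriptors are computed from first principles, giving the vector
   (PW4, X3A, JGI2, E):
   - **X3A** — average Randić connectivity index of order 3:
     χ₃ = Σ_paths (Π δᵢ)^(−1/2) over 3-edge simple paths, divided by the
     number of such paths (δᵢ = heavy-atom vertex degree);
   - **JGI2** — mean Gálvez topological charge index of order 2:
     GGI₂ = ½ Σ_{d(i,j)=2} |CTᵢⱼ| normalised per vertex pair, with
     CT = antisym(A·Q) + diag(δ), Q the reciprocal square distance matrix;
   - **PW4** — Randić path/walk-4 shape index: the atom-average of
     (simple 4-paths from the atom)/(4-walks from the atom).
4. **Classification** — an RBF-kernel soft-margin SVM
   (K(x,z) = exp(−γ‖x−z‖²)) is trained on round 1 (label 1, low affinity)
   vs round 10 (label 2, high affinity), with (C, γ) ∈ [1, 1000]² tuned by
   a real-coded genetic algorithm (population 20, 200 generations) under
   stratified 5-fold cross-validation.
5. **Evolution** — per round, the fraction of predicted "winning" aptamers
   (label 2) and the mean E are reported, and the fraction series is fitted
   with the saturating exponential f(r) = a·(1 − e^(−b(r−1))).

A fully tested synthetic-data generator emulates the study conditions
(10 rounds × 100 clones of 40-mer DNA, binders carrying a GC stem with a
5–7-nt loop, enrichment following a planted saturating schedule), so the
whole pipeline is exercised end to end without proprietary pool data.

## Worked example

```sh
aptaclass simulate --rounds 10 --size 30 --seed 7 --out demo
aptaclass run --in demo/pools.fasta --out demo/run --ga --seed 7
```

prints

```
wrote 300 records to demo/pools.fasta
done: training accuracy 1.0000, fit a=0.953 b=1.162 -> demo/run
```

and `demo/run/round_summary.csv` contains

```
round,n_sequences,winning_fraction,mean_E
1,21,0.0000,-1.341
2,27,0.7037,-5.106
3,29,0.8276,-6.296
...
10,29,1.0000,-6.792
```

Reading: the GA-tuned SVM perfectly separates the round-1/round-10
training rounds; across rounds the predicted winning fraction climbs from
0 (naive pool) toward the fitted plateau a = 0.95, while the mean fold
energy E drops from −1.3 to about −7 kcal/mol as structured binders take
over the pool — the expected SELEX enrichment signature. (Rounds with
fewer than 30 records lost members to the "no pair structure" filter.)

The same stages are available as `aptaclass pools / fold / descriptors /
select / train / predict / evolve`, and programmatically via
`aptaclass.synthetic_data.end_to_end_recovery()`.

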