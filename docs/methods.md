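# Methods

## Model and assumptions

The working hypothesis is that essential and non-essential genes differ in
the local statistical organization of their DNA — enough that a classifier
over information-theoretic summaries of the sequence alone can separate
them. All features are plug-in estimates over a 4-letter alphabet
Ω = {A, C, G, T}; no reading-frame, codon-usage or protein-level
information is used, and input sequences are assumed to already be
coding-strand gene sequences (no strand inference, no GFF parsing).

### Probability estimation conventions

- All k-mer statistics use **overlapping windows** (step 1), for pairs,
  triplets and background distributions alike. Sliding windows use all of
  the data and keep the pair and triplet estimators consistent with each
  other; a codon-frame alternative would tie the features to the reading
  frame, which the feature set deliberately ignores.
- Marginals are always **derived from the estimated joint** (row/column
  sums), never recounted separately. This makes the plug-in MI and CMI
  nonnegative by construction and avoids boundary-effect inconsistencies
  between joint and marginal counts.
- 0·log(0/q) = 0 throughout. Logarithms are base 2 for Shannon entropy,
  MI, CMI, KLD and Markov scores (features in bits) and natural for the
  Gibbs entropy.

### Gibbs entropy

States are the overlapping N-mers of a gene (N = 2, 3). The state
probability is Boltzmann-weighted by stability:
P_G(i) ∝ n_i·exp(−E(i)/k_B T), where n_i is the N-mer count and E(i) the
nearest-neighbor stacking free energy (for N = 3, the sum of the two
constituent dinucleotide energies). The bundled energy table is the
unified nearest-neighbor set of SantaLucia (PNAS 1998), ΔG°37 in kcal/mol;
a user table can be substituted via a 16-line TSV. Energies are converted
to J/molecule so the Boltzmann constant (1.38×10⁻²³ J/K) applies directly;
the default temperature is 310.15 K (37 °C), the standard condition of the
energy set. The reported feature is −Σ P_G ln P_G, i.e. the entropy in
units of k_B: dividing out k_B keeps feature magnitudes O(1), and any
monotone rescaling is irrelevant to threshold-based tree splits. With a
constant energy table the Boltzmann weights cancel and the Gibbs entropy
reduces to ln 2 × Shannon entropy — a closed-form identity the tests
exercise.

### Markov features

Class-conditional chains MC+ and MC− are fitted on the essential and
non-essential training pools with the Lidstone estimator
P_{v,a} = (N(va)+δ)/(N(v)+4δ), δ = 0.001 by default (exposed as
configuration). Counts are pooled across training sequences and never span
sequence boundaries; context counts N(v) count transitions out of v, so
the estimator is exactly row-stochastic. The score of a gene against a
chain sums P(word)·log₂(P(a|v)/P(a)) over all positions, where the
unconditional word and symbol probabilities are estimated from the same
training pool under the same Lidstone convention — the training pool is
the only self-consistent source that also guarantees strictly positive
probabilities. The chain order is fixed at m = 1 by default; an optional
estimator returns the smallest m at which the conditional mutual
information between a symbol and its (m+1)-lagged predecessor, given the m
intervening symbols, stops being significant under a within-context
permutation null (α = 0.05, 199 permutations, seeded). This is a
conservative surrogate for published CMI-based order estimators and is
intended for intra-organism runs only.

**Leakage guard.** When a gene being featurized is itself a member of a
chain's training pool, its counts are subtracted from the pooled counts
before scoring — algebraically identical to refitting the chain without
the gene, at O(1) cost. Test-side genes never enter any training pool; the
evaluation regimes record per-fold train/test gene-ID sets so this can be
audited after the fact.

### KLD background

The background distribution Q is computed from the training organism's
genome when one is supplied, otherwise from the concatenated training gene
sequences (logged). If Q assigns zero mass to a k-mer the gene contains,
Q is floored at ε = 1e-6 and renormalized (logged); gene-side zeros
contribute nothing. ε only matters for tiny or skewed backgrounds and is
configurable.

## Classifier and evaluation

Random Forest with the entropy (information-gain) split criterion;
defaults: 100 trees, unlimited depth, √p features per split, all exposed
as parameters and seeded. Training sets are balanced by random
under-sampling of non-essentials — never over-sampling; if essentials are
the majority the set is left unchanged and logged. The under-sample is
redrawn fresh in every fold/repetition so repeated splits see independent
majority subsets.

Intra-organism evaluation is Monte Carlo cross-validation: each repetition
balances, splits 80/20 stratified by class, refits the Markov chains (and,
absent a genome, the background) on the training side only, extracts
features, trains, and scores the held-out side. Stratification stabilizes
repetitions on small gene sets. AUC uses the Mann–Whitney rank
formulation with midranks, so tied scores contribute ½ exactly; accuracy
and F-measure are reported at a 0.5 score threshold but AUC is the primary
metric since the threshold-dependent measures are arbitrary at any single
operating point. Pooled k-fold CV stratifies folds by organism and label.
Feature ranking uses per-feature information gain at the best single
threshold (exhaustive over the midpoints between consecutive distinct
values), ties broken alphabetically for determinism.

## Synthetic data

The generator makes the Markov-source premise literal: essential genes are
sampled from a positive order-1 source, non-essential genes from
M_neg(d) = (1−d)·M_pos + d·M_alt, and the genome from the 50/50 average of
the two class matrices. The preset matrix pair sets each row to
0.25 ± 0.04 with opposite signs in the two matrices (purine-favoring vs
pyrimidine-favoring continuations), chosen so that full divergence
(d = 1.0) is decisively separable at typical bacterial CDS lengths while
d = 0.3 ("weak") lands in an intermediate-AUC regime and d = 0 ("null")
is exchangeable by construction. Presets use 50 essential / 150
non-essential genes (a 1:3 imbalance exercising the under-sampler), gene
lengths uniform in [300, 1500] nt — the typical bacterial CDS scale —
and a 100 kb genome. Everything is determined by one integer seed.

What the generator does **not** emulate: codon structure, GC skew, operon
organization, length–essentiality correlations, annotation noise, or any
higher-order dependence. Passing the end-to-end recovery tests therefore
shows that the pipeline is correct and leak-free and that it recovers a
planted first-order compositional difference; it does not certify
real-data accuracy, where class differences are weaker and confounded.

## Numerical choices and degenerate inputs

- Sequences are uppercased and stripped of non-ACGT symbols; a gene is
  rejected if more than 10% of its characters were stripped or fewer than
  3 bases remain. Stripping (rather than substituting) ambiguity codes
  perturbs k-mer statistics least.
- Labels file: headerless two-column TSV with values E/NE, chosen for
  trivial hand-authoring; any other value is a format error.
- Gibbs exponentials subtract the maximum exponent before exponentiating.
- Any NaN/inf feature aborts extraction with the gene and feature named —
  fail fast rather than impute.
- Evaluation problem sizes in the bundled acceptance script (10 Monte
  Carlo folds on the full presets; four reduced organisms of 12 E / 36 NE
  genes of 150–400 nt for the cross-organism and taxon regimes) are the
  package's chosen desk-scale defaults; all regimes accept arbitrary
  sizes.

## Known limitations

- Feature scaling is deliberately absent (trees are invariant to monotone
  transforms).
- The order estimator is a permutation-test surrogate, not a reimplementation
  of any specific published estimator; it is consistent but conservative
  on short pools.
- Cross-organism transfer on real genomes depends on evolutionary
  distance and annotation quality; the synthetic regimes share one source
  pair by construction and so represent the favorable end of that spectrum.
- Eukaryotic gene models are supported only insofar as the user supplies
  spliced CDS sequences as FASTA.
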