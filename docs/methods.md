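# Methods

## Model

An aligned family of homologous protein sequences is modelled as i.i.d.
draws from a Potts model (pairwise Markov random field) over the L columns
of the alignment.  Each column variable takes one of q = 21 states (the 20
amino acids in alphabetical one-letter order, then the gap, which is treated
as an ordinary symbol).  A sequence x has probability

    P(x) = (1/Z) exp{ Σ_i h_i(x_i) + Σ_{i<j} e_ij(x_i, x_j) },

with per-column fields h_i(a), per-pair coupling matrices e_ij(a, b) stored
once per unordered pair (e_ij(a,b) = e_ji(b,a) structurally), and a global
partition function Z summing over all q^L sequences.  Columns whose fitted
coupling matrix has a large Frobenius norm

    J_ij = sqrt( Σ_{a,b} e_ij(a,b)² )

are predicted to be in spatial contact.  J is gauge-dependent, so couplings
are shifted to the zero-sum gauge (zero row and column means per pair
matrix, shifts absorbed into the fields; the distribution is unchanged)
before scoring.  Raw-gauge scoring and the average-product correction are
available as flags but off by default, keeping the plain Frobenius norm as
the reference statistic.

## Objectives

Because Z is intractable, estimation maximises a composite-likelihood
surrogate.  Three objectives are implemented as mean per-sequence
log-likelihoods (nats), with exact analytic gradients:

* **exact**: energy minus log Z with Z by brute-force enumeration, guarded
  by a cap (q^L ≤ 5·10⁶).  This is the oracle, not a production estimator.
* **pseudo**: Σ_i log P(x_i | x_rest), one softmax per column.
* **pairwise composite** (the default): Σ_{i<j} log P(x_i, x_j | x_rest),
  each pair conditional normalised over the q² joint states of the pair.
  A general subset-family version covers 3rd- and higher-order composite
  likelihoods at toy scale; the singleton family reproduces the
  pseudo-likelihood, the all-pairs family the pairwise objective, and a
  single full subset the exact likelihood (tested to 1e-12).

The pairwise objective costs O(M·L²·q²) for value and gradient.  The key
bookkeeping is the per-sequence field F_i(a) = h_i(a) + Σ_{k≠i} e_ik(a,x_k)
(one BLAS product against a symmetric block coupling matrix); each pair
conditional then needs only F_i, F_j and an e_ij correction for the doubly
counted in-pair background term, and its partition function factorises as
Σ_ab exp(u_a)·K_ab·exp(v_b) with K = exp(e_ij), so no M×q×q probability
tensor is materialised.  A numba kernel computes value and gradient in one
pass, accumulating per-site marginal sums so the background coupling terms
cost O(M·L²·q) instead of O(M·L³·q); a pure-numpy implementation of the
same quantities is kept as a cross-checked reference (`engine="numpy"`),
and the two agree to 1e-10 in tests.  Log-sum-exp max-subtraction is used
everywhere a normaliser is computed, with exponentials clamped at exp(-700)
to avoid subnormal slow paths.

### Ordering of the surrogates

The pairwise composite likelihood is a tighter surrogate than the
pseudo-likelihood in the following precise sense: counted per variable
occurrence (each column appears in L−1 pair conditionals) and in
expectation under the model,

    E[exact] ≤ E[pairwise]/(L−1) ≤ E[pseudo].

This is the generalised Han inequality for conditional entropies: the
normalised sums −Σ_{|c|=k} H(X_c | X_¬c) / C(L−2, k−1)-style chains are
monotone in subset size.  The chain is a statement about expectations, not
about individual data sets: per-sequence pointwise counterexamples exist in
both directions (the gap between pseudo and exact is a sum of pointwise
mutual informations, which has indefinite sign), and the *unnormalised*
sums are ordered the other way around at independence simply because the
pairwise objective has L(L−1)/2 negative terms against L.  The acceptance
suite therefore verifies the chain in its valid form, computing the
expectations exactly: the "alignment" is the full enumeration of q^L
configurations and the sequence weights are the model probabilities, which
the weighted objectives accept directly.  Fifty random models (L ≤ 6,
q ≤ 3, Gaussian parameters) are checked with tolerance 1e-9.

## Estimation

The regularised objective (objective − λ_h Σh² − λ_e Σe², defaults
λ_h = 0.01, λ_e = 0.1 following pseudo-likelihood DCA conventions; each
pair matrix penalised once) is maximised with L-BFGS-B from an all-zero
start.  All-zero initialisation is deterministic and gauge-neutral; the
limited-memory quasi-Newton family is the only scalable choice at
L·q + L(L−1)/2·q² parameters.  Convergence is projected-gradient max-norm
≤ 1e-5 (default) or the iteration budget (default 500); both are recorded
in the fit result.  Fits are bit-for-bit deterministic given identical
inputs and configuration.

Sequence weights are computed at the conventional 80% identity level:
weight 1 / |{j : identity(i,j) ≥ 0.8}| with the sequence itself counted,
N_eff = Σ weights.  Gap–gap columns count as matches.  Reweighted averages
are the default in every objective; uniform 1/M is a flag.  Note the
neighbour count uses "identity ≥ threshold": counting sequences *below*
the threshold would leave unique sequences with an empty denominator and
invert the meaning of redundancy, so the standard convention is used.

## Evaluation

True contacts are residue pairs whose representative atoms — C-beta, or
C-alpha for glycine (and as a logged fallback for non-glycine residues
missing C-beta in real files) — lie strictly closer than 8 Å.  Predictions
are ranked by J_ij after removing short-range pairs; the two standard
separation bands are |i−j| ≥ 6 and |i−j| > 23.  Precision at top L/k takes
the k = floor(L/denominator) highest-ranked pairs and divides hits by k
even when fewer than k true contacts exist, which keeps the metric
comparable across methods.  When alignment columns and structure residue
numbering differ, the caller must supply the mapping explicitly; no
automatic alignment is attempted.

## Synthetic benchmark

The generator plants a known sparse-coupling Potts model: fields
~ Normal(0, 0.3); n_contacts uniformly chosen pairs receive a random
rank-2 q×q coupling matrix rescaled to Frobenius norm 3.0 (low-rank rather
than i.i.d. entries so the planted norm — and hence the recovery margin —
is exact by construction); every other pair is exactly zero.  Alignments
are drawn by single-site Gibbs sampling, by default one independent chain
per sequence with 100 burn-in sweeps, which removes autocorrelation
between rows; a thinned single-chain mode exists for comparison.  The
sampler is validated against the enumerated distribution on tiny models
(total-variation distance < 0.02 at n = 20,000).

The standard recovery benchmark uses L = 30, q = 8, 40 planted contacts
and 2,000 sampled sequences — a deliberately desk-scale proxy for real
alignments (real proteins are longer, use q = 21 and have phylogenetically
correlated rows; none of that is emulated, so passing recovery says the
estimator works under the model's own assumptions, not that it matches any
particular empirical accuracy).  The benchmark fits with a 100-iteration
budget and gradient tolerance 1e-3, which the coupling ranking has long
stabilised under, ranks all pairs (no separation filter, since planted
pairs are placed without regard to separation) and reports the fraction of
the top n_contacts pairs that were planted.  Across 10 seeds the pairwise
composite objective is required to reach mean precision ≥ 0.8 and at least
match the pseudo-likelihood objective on the same data.

## Numerical and design choices

* Alphabet order fixed (amino acids alphabetically, gap last) so parameter
  files index deterministically; nonstandard letters (B, Z, X, J, U, O, …)
  encode as the gap rather than erroring, since real alignments contain
  them and the gap is already an ordinary symbol.
* Internal indices are 0-based; all file output (CASP RR) is 1-based.
  Ranked output breaks score ties lexicographically by (i, j) so files are
  reproducible.
* Parameter files are plain text with a versioned header and 17 significant
  digits, giving bit-exact float64 round trips.
* The enumeration cap (5·10⁶ states) bounds both the exact objective and
  general-composite subset sizes; exceeding it raises a capacity error that
  names the tractable alternative.
* Degenerate inputs: empty alignments, ragged rows, out-of-range symbol
  codes, zero-length top-k requests and out-of-range contacts all raise
  typed errors rather than propagating bad values.

## Known limitations

* Row independence is assumed by the synthetic generator; reweighting
  mitigates but does not model phylogeny on real alignments.
* The exact objective is an oracle for tests, not usable beyond toy sizes.
* No average-product-corrected or mutual-information comparator scores are
  provided, and no structure-building or deep-learning refinement of the
  contact map is attempted: the package ends at ranked contacts and their
  precision.
* Column-to-residue mapping for real PDB evaluation is the caller's
  responsibility.
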