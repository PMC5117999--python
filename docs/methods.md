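# Methods

## The model

`phitax` quantifies *integrated information*: how far the dynamics of a
system falls short of being decomposable into two non-interacting parts.
The system state at two times, `x0` and `x1`, is described by the joint
distribution `p(x0, x1)`; under a bipartition into parts A and B this is
the rank-4 tensor `p[i, i', j, j']` with `i = x0A`, `i' = x0B`, `j = x1A`,
`j' = x1B`.  The dynamics is the column-stochastic Markov matrix
`M[jj', ii'] = p[ii'jj'] / p[ii'··]`, and a *separable* system is one whose
M is a tensor product `M^A ⊗ M^B`.  Every φ-measure in the package scores
the failure of the best (or a prescribed) separable approximation, and the
capital-Φ of a system is the φ of the "cruelest cut" — the bipartition
minimizing φ.

A measure is selected by a four-letter code:

| axis | letters | meaning |
|---|---|---|
| factorization | `n m o x a` | uniform noising, mild (marginal) noising, optimal with state unknown, optimal at a known state, optimal on average (= `o`, kept as alias) |
| comparison | `t f a p` | two-time joint, future state, future of part A, past of part A (time-reversed) |
| conditioning | `u s k` | present state unknown, separably distributed, or known |
| distance | `k 1 2 h s e m` | KL, L1, L2, Hilbert angle, Shannon–Jensen, earth-mover, mismatched decoding |

Of the nominal 5·4·3·7 = 420 cells, many collapse: `a` ≡ `o` (provable);
the noising factorizations only admit `a/p` comparisons with `s/k`
conditioning; `o` with `a/p` comparisons and `u/s` conditioning is
identically zero (the optimal factors reproduce the subsystem marginals);
`ot k*` ≡ `of k*`; `x` with `t` is undefined and with `a/p`+`k` is zero.
The surviving distinct named measures form the 21-entry roster in
`phitax.measures.NAMED_MEASURES`, including φ^M (= φ^otu), the
Barrett–Seth φ^B, the mismatched-decoding φ^MD (= φ^otum), the
state-dependent family (ofk, oak, opk, nak, npk, mak, mpk, xfk) and the
minima φ^2.5 = min(nak, npk), φ^2.5′ = min(mak, mpk),
φ^2.5″ = min(oak, opk).

Every named measure has a closed form that the test suite checks against
the generic `factorize → build_q → distance` path:

- φ^M = I(x^A, x^B) − I(x0A, x0B), with x^A = (x0A, x1A);
- its time reverse equals Ay's stochastic interaction
  S(x0A|x1A) + S(x0B|x1B) − S(x0|x1);
- φ^B = I(x0, x1) − I(x0A, x1A) − I(x0B, x1B) = φ^M − I(x1A, x1B)
  (the only measure allowed to go negative);
- φ^MD = d_MD(p, q) over the (past, future) bivariate structure, with q
  the optimal separable approximation
  q_{ii'jj'} = p_{ii'··} p_{i·j·} p_{·i'·j'} / (p_{i···} p_{·i'··});
- φ^xfk = I(x1A, x1B | x0), which vanishes for deterministic dynamics.

Discrete measures are in bits; Gaussian measures in nats (a CLI flag
converts).

## k-conditioning for the noising factorizations

There are two defensible conventions for the state-conditioned noising
cells (nak, mak, npk, mpk): condition the *true* distribution on the
subsystem state alone (x0A = k), or on the full state (x0 = kk') while the
noised prediction column is necessarily indexed by the A-part alone.  The
discrete layer uses the full-state convention: it is what makes φ^npk the
IIT-2.0 effective-information measure, and what yields the reference value
φ^2.5 = log2 n for subsystem-swap dynamics (the conditional future is then
a point mass compared against the uniform noised prediction 1/n).  The
Gaussian layer keeps the per-part convention of its closed forms (mak
compares mean Â_A x0A, covariance Σ̂_A against the mild-noised
Ā_A x0A, Σ̄_A), which is the form derivable in closed form from the block
covariance algebra.  The two layers therefore agree on every
state-independent measure and on ofk/oak/opk/xfk, and differ by
convention on mak/mpk; both conventions are exposed deliberately and
documented here rather than silently mixed.

## Gaussian layer

For a stationary zero-mean AR(1) process `x_{t+1} = A x_t + n`,
`<n n^t> = Σ`, everything is a function of the lag-0 covariance
C = <x x^t> and lag-1 cross-covariance B = <x_t x_{t+1}^t>:
A = BᵗC⁻¹, Σ = C − BᵗC⁻¹B, and the backward process has Ã = BC⁻¹,
Σ̃ = C − BC⁻¹Bᵗ with |Σ| = |Σ̃| always.  Example formulas (nats):

    φ^M   = ½ ln( |Σ̂_A| |Σ̂_B| / |Σ| ),   Σ̂_X = C_X − B_XᵗC_X⁻¹B_X
    φ^B   = φ^M − ½ ln( |C_A||C_B| / |C| )
    φ^xfk = ½ ln( |Σ_A| |Σ_B| / |Σ| )

The Gaussian mismatched-decoding measure is computed at β = 1 as the
deficit φ^MD = I(x0, x1) − I*(p, q, 1) = ½ ln(|C|/|Σ|) − I*, where I* is
the information decoded under the block-factorized model
(Â = blockdiag(Â_A, Â_B), Σ̂ = blockdiag(Σ̂_A, Σ̂_B)):

    I* = ½ [ ln|Ĉ| − ln|Σ̂| + tr(Ĉ⁻¹C) − tr(Σ̂⁻¹Σ) − tr(ÁᵗΣ̂⁻¹ÁC) ],
    Á = A − Â,  Ĉ = ÂCÂᵗ + Σ̂.

Written this way the measure vanishes for separable systems and satisfies
0 ≤ φ^MD ≤ I(x0, x1); a fine-grid discretization of a 2-D AR system
cross-checks it against the discrete d_MD at β = 1.  Optimized-β Gaussian
MD is out of scope.  The codes nas/nak/nps/npk/2.5 are rejected at the
Gaussian layer: uniform noising has no normalizable continuous analogue,
so those measures are infinite for continuous systems (they remain
computable in the discrete layer).

Backward k-conditioned codes (opk, mpk) condition on the *future* state
x1 and use the tilde quantities throughout; the conditioning state for any
k-code defaults to the process mean (the zero vector) with a warning,
which nulls the mean-mismatch terms.

## Partition search

Exact Φ enumerates the C(n, n/2)/2 unordered symmetric bipartitions
(complement pairs deduplicated by pinning element 0; guard at n = 20,
i.e. 92,378 cuts).  For Gaussian φ^M all per-cut log-determinants are
evaluated in one batched stacked-solve pass, which makes the n = 16
enumeration (6,435 cuts) take milliseconds per system.  Asymmetric cuts
are excluded from Φ by default — how to normalize them is a genuinely
open modeling question this package does not attempt to answer.

The fast approximation thresholds the coupling matrix: zero all
|A_ij| < ε and pick, by 60 steps of interval halving on
ε ∈ [0, max|A_ij|], the ε whose largest connected component is closest to
n/2 (ties go to the smallest ε, keeping more edges).  The component and
its complement form the candidate cruelest cut, whose φ is the
approximation.  Weak connectivity is used for measures that do not vanish
for afferent/efferent pathways (φ^M and relatives); strong connectivity
for the 2.5-family.  A variant thresholds C instead of A, and a best-of
mode evaluates both candidates and keeps the smaller φ.  Two caveats,
both by construction: when no ε yields a balanced component the returned
cut is asymmetric (flagged `degenerate`), and such a cut can score below
the symmetric exact minimum; the diagonal of the thresholded matrix is
always ignored.

## Synthetic systems

The generators are pure functions of (parameters, seed):

- `random_joint(nA, nB)` — (nA·nB)² iid U(0,1) entries normalized; the
  mean future-subsystem mutual information approaches 1 − 1/(2 ln 2)
  ≈ 0.279 bits for large n (≈ 0.275 at n = 128, the size the acceptance
  script uses).
- `swap_system(n)` — random initial distribution evolved by the
  deterministic subsystem swap; φ^2.5 = log2 n, φ^xfk = 0.
- `random_coding(n)` — exactly n² of the n⁴ probabilities set to 1/n²;
  S(x) = 2 log2 n exactly and φ^M = 2 log2 n − O(1) (the O(1) collision
  overhead is ≈ 2 bits at the sizes the tests use).
- `two_bit_example(name)` — the frozen-correlated (φ^B = −1),
  copy-or-flip (φ^M = 1 bit with I(x0,x1) = 0) and correlated-noise
  (φ^M = 1, φ^MD = 0) systems.
- `ar_random(n, eta)` — A = ηA₀ + blockdiag(A₁, A₂) with iid Gaussian
  matrices each normalized to unit spectral radius ("largest eigenvalue"
  is read as largest eigenvalue *magnitude*, since random real matrices
  have complex spectra), final spectral radius 0.99, Σ = I, C from the
  Lyapunov equation.  η is drawn from {0.1, 0.3, 0.5, 0.7, 1, 2, 10} with
  equal probability in ensemble studies.
- `boolean_coupling_matrix(gates)` — A_ij = P(flipping input bit j flips
  output bit i), averaged over an input distribution; a RANDOM gate is an
  unbiased coin independent of all inputs, so its row is zero.

These emulate the structural features the measures respond to
(separability, planted cuts, deterministic vs noisy dynamics, coupling
strength); they do not emulate non-stationarity, estimation noise from
short recordings, or non-Gaussian continuous data, so passing tests say
nothing about those failure modes on real recordings.

## Numerical choices

- Probability validation at 1e-12 absolute; inputs renormalized to exact
  sum 1.  0·log 0 = 0; d_KL returns +inf (flagged, not raised) when q
  lacks support where p has mass.
- Unreachable Markov columns (zero past-state probability) are filled
  with the uniform column and flagged; they never carry mass.
- Bit-to-state mapping: bit 0 is the most significant bit; a cut reorders
  bits as (sorted part A, sorted part B) before reshaping.
- β search for mismatched decoding: 25-point coarse grid on
  log β ∈ [−6, 6], refined by bounded scalar maximization; β = 1 is the
  default fast path (near-optimal in practice, and exact when q = p).
  The paper-style bounds 0 ≤ d_MD ≤ I(p) are enforced against roundoff.
- Earth-mover distance: exact linear program (HiGHS), guarded to ≤ 256
  states; default ground metric for bit strings is Hamming distance.
- Lyapunov equation: direct solve for n ≤ 200, fixed-point iteration
  (tol 1e-12, cap 1e5) above.
- Covariances are symmetrized and eigenvalue-floored at 1e-10 × the
  largest eigenvalue (with a warning) before use — sample covariances
  from short series are routinely indefinite at roundoff level.
- Stationary distributions come from the unit-eigenvalue eigenvector;
  a numerically repeated unit eigenvalue is flagged and one eigenvector
  returned (uniform for the exact identity).

## Problem sizes

The bundled studies use sizes at which exact enumeration stays cheap
while the statistics are already stable: 200 draws at n = 128 states per
subsystem for the random-joint mutual-information average, and 300
random-AR systems at n = 16 channels (6,435 unordered cuts each, batched)
for the paired exact/approximate Φ comparison.  At these sizes the
approximation study reproduces a ≥ 90% exact-cut hit rate among trials
with Φ_max/Φ_min > 2 and a median overestimation below 15% among the
rest, seed-to-seed.

## Known limitations

- Asymmetric-partition normalization is deliberately not addressed.
- The noising/mild-noising k-conditioning convention differs between the
  discrete and Gaussian layers (see above).
- Non-Markovian dynamics, AR(p>1) fitting, non-stationary processes and
  interventional estimation of M are out of scope.
- φ^3.0 (conceptual-structure machinery over all subsets) is not
  implemented; only the earth-mover distance between whole-system
  distributions is available as a distance code.
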