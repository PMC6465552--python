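# Methods

## Problem

Curated microbe–disease association catalogs are binary, bipartite and very
sparse: a reference catalog of this kind holds 450 associations over
39 diseases and 292 microbes (≈4% density). `bwnet` scores every unobserved
(disease, microbe) pair so that true-but-unrecorded associations rank high.
The model is purely topological: it uses no sequence, taxonomic or symptom
information, only the adjacency matrix `A` (diseases × microbes).

## Model

1. **GIP kernels.** Each node's interaction profile is its row (disease) or
   column (microbe) of `A`. Similarity is the Gaussian interaction-profile
   kernel `K(i,j) = exp(−γ‖IP(i)−IP(j)‖²)` with bandwidth
   `γ = γ′ / mean‖IP‖²`, `γ′ = 1` by default (the standard GIP choice).
   Two kernels result: `KM` (microbes) and `KD` (diseases), symmetric with
   unit diagonal and entries in (0, 1].

2. **Heterogeneous network and node weights.** The block matrix
   `P = [[KD, A], [Aᵀ, KM]]` encodes the three edge classes (d–d, m–m, d–m).
   Node weights are `W_ii = 1/(PPᵀ)_ii`, the reciprocal squared row norm:
   hubs carry less evidence per edge. Unit kernel diagonals guarantee
   `0 < W_ii ≤ 1`. As printed, the defining expression is the reciprocal of
   a matrix; we take the elementwise reciprocal of the diagonal of `P·Pᵀ`,
   the only reading that yields the promised diagonal matrix of per-node
   weights.

3. **Edge normalization.** Kernels become directed edge weights
   `K*(i,j) = K(i,j) / (Σ_k K(k,j) · NZ(i))` (default, `full_denominator`),
   where `NZ(i)` counts the nonzero entries of row `i`. The grouping of this
   expression is ambiguous in its source; the default divides (shrinking
   entries so longer propagation paths cannot outscore shorter ones, which is
   the stated purpose of the normalization), and the alternative grouping
   `(K(i,j)/Σ_k K(k,j)) · NZ(i)` is kept as the `postmultiply` variant.
   `NZ` is computed on the kernel as literally specified; since Gaussian
   kernels are strictly positive, `NZ ≡ N` at any realistic scale and every
   column of `K*` then sums exactly to `1/N`. (Computing `NZ` on the
   adjacency instead would make it a degree penalty, but that reading cannot
   be established from the method's description and is not implemented.)

4. **Bidirectional recommendation.** To densify `A`, each microbe receives at
   most one recommended disease (giving `A_m`) and each disease at most one
   recommended microbe (giving `A_d`). For subject `i`: take its `K = 3`
   most similar same-axis neighbors from the *raw* kernel (ties by ascending
   index), convert their similarities to ratios summing to 1, score each
   opposite-axis candidate by the ratios of the neighbors associated with it,
   and boost candidates also reachable through the neighbors' own top-`K`
   sets by the products of first- and second-order ratios. The top candidate
   is added; a recommendation landing on a known pair is a no-op. The
   first- and second-order sums are restricted to neighbors actually
   associated with the candidate — without that restriction every candidate
   scores identically and the ranking is vacuous. Recommending into an
   already-known pair could alternatively fall through to the next-ranked
   candidate; the literal single-shot reading is implemented.

5. **Propagation and fusion.** The directed network
   `S = [[KD*, A_d], [A_mᵀ, KM*]]` is propagated `n` steps with the node
   weights interleaved: `S₂ = S·W·S`, then either `S_t = S_{t−1}·W·S_{t−1}`
   (`squaring`, the literal recursion) or `S_t = S_{t−1}·W·S` (`stepwise`,
   which matches the "paths of length n" interpretation). Both coincide at
   the default `n = 2`, where the method performs best — with so few edges,
   long paths are noise. There is no damped sum over path lengths. The final
   score is the equal-weight average of the two directed disease–microbe
   blocks, `A*_n = (S_n2 + S_n3ᵀ)/2`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n` | 2 | propagation path length (≥ 2); performance degrades for 3, 4 |
| `k` | 3 | neighbors per node in the recommendation step (capped at N−1) |
| `γ′_m`, `γ′_d` | 1.0 | GIP bandwidth scale per axis |
| `normalization` | `full_denominator` | edge-weight grouping (see above) |
| `recursion` | `squaring` | recursion used for n > 2 |
| `eps` | 0.0 | strict-positivity threshold for the `NZ` counts |

## Cross-validation protocol

Held-out known pairs are ranked against the *candidate* set — every pair
unknown in the original adjacency. LOOCV masks one known pair at a time;
repeated k-fold CV (default 5 folds) masks a fold at a time, the first
`nnz mod folds` folds one pair larger. **Everything** downstream of the
adjacency — kernels, node weights, normalization, recommendations,
propagation — is recomputed from the masked training matrix in every run,
so no test information leaks through the similarity kernels. The AUC is the
Mann–Whitney statistic (ties count ½), averaged per positive against its
own run's candidates; the ROC is built from the pooled per-positive
candidate ranks, a construction under which the curve's area equals that
mean. Per-repeat seeds are spawned deterministically from one master seed.

Note that the leak-free protocol is deliberately stricter than the common
practice in the GIP-kernel literature of computing kernels once on the full
matrix and masking only the adjacency inside `S`. The leaky shortcut
inflates AUC substantially (a degree-1 node's profile vanishes entirely
under honest masking but survives under the shortcut); numbers produced by
the two protocols are not comparable.

## Synthetic data

The generator plants co-clusters: each disease and microbe gets one of
`n_blocks` latent communities (uniformly at random), and a pair is
associated with probability `p_in` (0.35) within matched blocks and `p_out`
(0.01) otherwise — matching the reference catalog's shape (39×292 default)
and its 4–7% density. All-zero profiles are repaired with a single edge to
a matched-block partner. The desk-scale benchmark (`scaled_benchmark`) is
20×60 with 4 blocks, preserving roughly the per-block disease count of the
full-scale default; it was fixed once, before any benchmark results were
inspected.

What the generator does *not* emulate: the heavy-tailed degree
distributions of curated catalogs (a few intensively studied diseases and
taxa account for many associations), name semantics, and evidence
multiplicity. Passing recovery tests on planted blocks therefore shows the
pipeline exploits co-cluster structure under a leak-free protocol; it does
not calibrate expected performance on real catalogs, where degree
concentration alone carries substantial ranking signal.

### Known limitation: degree-1 nodes under masking

In sparse catalogs most microbes have a single known association. When that
association is held out, the microbe's training profile is all-zero: its
GIP column carries no community signal and its adjacency column is empty,
so the held-out pair ranks poorly no matter how strong the planted
structure is. On the 20×60 benchmark roughly a quarter of positives fall in
this stratum, which caps leave-one-out AUC well below what the degree-≥2
stratum achieves. k-fold CV masks more edges at once and is affected more
strongly, so its mean AUC sits below the LOOCV value on the same data.
This is an intrinsic property of profile-kernel methods under leak-free
evaluation, not an implementation artifact: every stage is verified against
independent brute-force oracles (double-loop kernels, exhaustive
recommendation enumeration, explicit path sums) to 1e−10…1e−12.

## Numerical choices

- Kernels are symmetrized (`(K+Kᵀ)/2`) and their diagonal set to exactly 1
  after the vectorized distance computation, so symmetry/diagonal
  invariants hold to the bit.
- All ties — neighbor selection, recommendation argmax, ranking output —
  break by ascending index; the pipeline is fully deterministic.
- Squared distances are clipped at 0 against floating-point roundoff.
- Degenerate inputs fail loudly: all-zero profile sets (undefined
  bandwidth), zero kernel column sums, zero rows in `P`, `n < 2`.
- Scores are printed with 6 significant digits; output files carry their
  configuration in a comment header so identical runs are byte-identical.
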