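# Methods

## The decomposition

Two spatially matched variables — e.g. microtubule and vimentin orientations
at the same pixel, or clathrin and cargo-receptor intensities at the same
detected spot — may co-vary for two distinct reasons: a **global bias**, a
common effector (cell polarity, illumination, expression level) that narrows
both marginal distributions, and a **local interaction**, a genuine
point-wise coupling of the matched pair. The package quantifies each
separately from the *alignment distribution*:

- **orientation mode**: the per-pair axial alignment angle
  θ = |x − y| if |x − y| ≤ 90°, else 180° − |x − y|, on [0°, 90°];
- **co-localization mode**: the per-pair difference of normalized
  intensities x − y, on [−1, 1], after each channel is rescaled to [0, 1]
  by its 5th/95th percentiles (linear-interpolation percentiles; values
  beyond the anchors are clipped).

Three K-bin histograms on the fixed domain are compared with the 1-D Earth
Mover's Distance, EMD(A, B) = Σᵢ |Σ_{j≤i} (aⱼ − bⱼ)| (L1 distance between
cumulative sums, in bin-width units):

- *observed* — alignment values of the actually matched pairs;
- *resampled* — alignment values after drawing N values with replacement
  from each marginal independently and pairing them in draw order, which
  keeps both marginals but destroys every local dependency;
- *uniform* — the analytic flat reference (exactly 1/K per bin, never
  sampled), the expectation under neither bias nor interaction.

Then

    GI = EMD(uniform, resampled)          (global index)
    LI = EMD(uniform, observed) − GI      (local index)

GI ≥ 0 by construction; LI is deliberately never clipped at zero — negative
LI indicates anti-alignment (or anti-colocalization). Limiting cases: for
independent marginals LI → 0; for uniform marginals GI → 0; when all pairs
are identical constants GI = (K−1)/2 exactly and LI = 0; when x is uniform
and y = x, GI → 0 and LI → (K−1)/2. LI is a lower bound on the true local
contribution to the observed alignment, GI the complementary upper bound on
the global one.

### A structural note on the narrow-marginal benchmark

When the observed histogram stochastically dominates the uniform reference
(all mass shifted toward low alignment angles), the EMD equals the
mean-alignment deficit in bin-width units: EMD(uniform, observed) =
(45° − mean θ)/binwidth for the orientation domain. With K = 15 (bin width
6°) a mean observed alignment of ≈19° therefore *forces*
GI + LI ≈ (45 − 19.2)/6 ≈ 4.3. The benchmark scenario σ = 17°, α = 0
reproduces the ≈19° mean alignment and LI ≈ 0, and accordingly reports
GI ≈ 4.3 — the value the identity above dictates.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `k` | histogram bins | 15 (orientation), 19/40 typical for co-localization | GI/LI are comparable **only** at equal K; cross-K operations raise |
| `seed` | resampling seed | required | identical (input, seed, reps) ⇒ bitwise identical result |
| `resample_reps` | resampled histograms averaged | 1 | >1 reduces GI's resampling variance; 1 matches the canonical single-resample definition |
| `normalize` | percentile-normalize channels (co-localization) | `True` | disable for data already on a common [0, 1] scale (e.g. the simulator's output) |

Automatic K selection uses the Freedman–Diaconis rule on the alignment (or
difference) values — the distribution actually being binned — with
bin width = IQR/n^(1/3) and K = ceil(span/width) clamped to [3, 100]; the
clamp guards against degenerate IQRs, and typical choices (15, 19, 40) sit
well inside it. A zero IQR is rejected with advice to set K manually.

Histogram bins are half-open `[edge, next)` with a closed last bin so the
domain maximum (90° or +1) is counted; the convention is otherwise
arbitrary and any sub-bin effect is far below the reported tolerances.

## Synthetic data generators

**Co-orientation.** x, y are drawn i.i.d. from truncated normals on
(−90°, 90°) with mean μ (default 0) and pre-truncation standard deviation σ
per channel (sampled by exact inverse-CDF truncated-normal sampling). σ sets
the global bias: smaller σ → narrower marginals → larger GI. The local
interaction then co-aligns each pair: a fair coin picks one member, which
moves toward the other *along the shortest axial arc* by ζᵢ degrees, where
ζᵢ = α·θᵢ (proportional mode, |α| ≤ 1, θᵢ the pre-interaction alignment) or
ζᵢ = min(ζ, θᵢ) (constant mode). The post-interaction alignment is exactly
θᵢ − ζᵢ, so α = 1 collapses every pair and α = 0 returns the raw draws
bitwise. Negative α moves the selected member away instead; positions wrap
mod 180 into [−90, 90], the consistent treatment for axial quantities
(clamping at ±90 would pile mass onto a boundary that names the same axis
as its opposite end). One seeded generator drives x draws, y draws and the
coin flips in that fixed order.

The axial-arc formulation matters only for wrap-around pairs
(|x − y| > 90°): with it, the σ = 40°, α = 0.5 scenario reproduces the
≈19° mean observed alignment benchmark; a linear shift on raw angle
differences would give ≈21°.

**Co-localization.** xᵢ ~ truncated Normal(μₓ = 0.5, σₓ) on [0, 1]. A
seeded random subset of round(fraction·n) indices interacts:
yᵢ = xᵢ·ζᵢ with ζᵢ ~ Normal(μ_ζ = 1, σ_ζ) redrawn until yᵢ ∈ [0, 1] (true
truncation — clipping would create boundary point masses; with σ_ζ = 0 the
degenerate product is clamped instead). Mean 1 models a one-to-one
interaction; growing σ_ζ weakens it and shrinks LI monotonically.
Non-interacting indices draw y independently from a truncated normal
(default spread σₓ), so `interacting_fraction = 0` reproduces the
independent-marginals limit (LI ≈ 0).

What the generators deliberately do *not* emulate: spatial correlation
between neighbouring measurements (all pairs are i.i.d.), detection and
segmentation noise, non-linear channel transfer functions, and
heterogeneous per-cell parameters within one dataset. Tests passing on this
synthetic data therefore validate the estimator's contract — decomposition
identities, limiting cases, monotonicity in the generative parameters,
sample-size and binning robustness — not its behaviour under spatially
structured noise.

## Statistical comparison of conditions

`permutation_test` contrasts an LI (or GI) between two conditions: the
full-data statistics fix the ordering; each of `n_iter` (default 100)
iterations subsamples ⌊fraction·N⌋ observations (default 50%) without
replacement from each condition independently, recomputes the statistic,
and counts strict reversals of the full-data ordering. Ties count as
non-contradicting (conservative). The p-value is the contradiction fraction
floored at 1/n_iter — a fraction of zero is reported as the bound attained
(0.01 at 100 iterations), never as 0. Samples pooled from several files are
subsampled as one pool. The test is conservative by construction: under
exchangeable conditions the contradiction fraction concentrates near 0.5,
so the floor is essentially never reached by chance.

## Numerical and design choices

- Frequencies (fractions), not counts, are the canonical histogram content,
  making EMD values N-independent.
- The uniform reference is analytic; sampling it would add noise to GI.
- Cross-histogram operations hard-fail on K or domain mismatch; the `run`
  and `compare` commands resolve `--k auto` on the pooled alignment values
  of *all* inputs so one command always uses one shared K.
- Orientation inputs are wrapped into [−90, 90] by mod-180 arithmetic;
  values already in range pass through bitwise.
- The permutation-test direction on exactly tied full-data statistics
  defaults to "a below b" (deterministic, conservative).
- Problem sizes used by the test suite and the acceptance script: N = 10⁴
  pairs for the benchmark scenarios (10–20 seeds), N = 5000 for the σ sweep
  and the two-condition discrimination experiment (40 simulations per
  condition), N = 10⁵ only for the perfect-alignment limit. The full suite
  runs in well under a minute.

## Known limitations

- GI and LI are not fully orthogonal: at fixed interaction strength α, LI
  drifts downward as GI grows (narrower marginals leave less room for the
  interaction to move the observed histogram). Comparisons across
  conditions should therefore read (GI, LI) jointly; the two-dimensional
  descriptor separates interaction strengths that LI alone cannot.
- LI is a relative, lower-bound measure — a two-fold change in the true
  coupling need not double LI.
- The percentile normalization is linear; strongly non-linear channel
  responses are out of scope.
- The estimator assumes one global bias and one interaction strength per
  dataset; mixtures within a dataset are averaged, not resolved.
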