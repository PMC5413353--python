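# debias

Decoupling **global bias** from **local interactions** in paired
cell-biological variables.

Co-localization of two proteins, or co-orientation of two filament networks,
is routinely read as evidence of interaction. But a common external effector
— cell polarity aligning both cytoskeletons, cell state biasing both
intensity distributions — produces the same observed coupling without any
point-wise interaction. This package decomposes the observed coupling into a
**global index (GI)**, the share explained by the marginal distributions
alone, and a **local index (LI)**, the residual attributable to genuine
pairwise interaction. It is aimed at quantitative cell biologists analysing
matched measurements: filament orientations, velocity vs. principal-stress
directions, FRET channel pairs, or spot intensities from two channels.

## The statistic

Per matched pair (xᵢ, yᵢ) an *alignment value* is computed — the axial angle
θᵢ = |xᵢ−yᵢ| (folded to [0°, 90°]) in orientation mode, or the difference of
percentile-normalized intensities xᵢ − yᵢ ∈ [−1, 1] in co-localization mode.
With K-bin histograms and the 1-D Earth Mover's Distance
EMD(A,B) = Σᵢ |Σ_{j≤i}(aⱼ − bⱼ)|,

```
GI = EMD(uniform, resampled)        resampled: marginals kept, pairing destroyed
LI = EMD(uniform, observed) − GI    observed:  pairing intact
```

where *uniform* is the flat histogram expected with neither bias nor
interaction. GI ≥ 0; LI < 0 signals anti-alignment. GI and LI are comparable
only at equal K. A subsampling permutation test (`debias compare`) assesses
GI/LI contrasts between conditions, and both synthetic-data generators used
in validation ship as first-class library code (`debias.simulate`).

## Worked example

Simulate coupled orientations with moderate global bias (σ = 25°) and a
moderate proportional interaction (α = 0.3), then decompose:

```
$ debias simulate orientation --n 800 --seed 42 --sigma-x 25 --alpha 0.3 \
      --out examples/coorientation_example.csv
$ debias run --mode orientation --input examples/coorientation_example.csv \
      --k 15 --seed 7
coorientation_example	GI=3.3288	LI=0.9112	K=15	N=800
```

GI = 3.33 says the narrow marginals alone would already produce most of the
observed co-alignment (the maximum possible value at K = 15 is
(K−1)/2 = 7); LI = 0.91 is the surplus coupling beyond what independent
resampling of those same marginals explains — the local interaction the
α = 0.3 setting injected. With `--alpha 0` the same pipeline reports
LI ≈ 0.

Comparing two conditions (here a file against itself, so no real contrast):

```
$ debias compare --a examples/coorientation_example.csv \
      --b examples/coorientation_example.csv --mode orientation --k 15 --seed 3
LI_A=1.0025	LI_B=1.1050	p_value=0.55	direction=a_less
```

The subsampled orderings flip about half the time — exactly the
exchangeable-null behaviour — so the difference is not significant. Library
use mirrors the CLI:

```python
from debias import OrientationSimConfig, simulate_coorientation, compute_debias

sample = simulate_coorientation(
    OrientationSimConfig(sigma_x=25, sigma_y=25,
                         interaction=("proportional", 0.3), n=800, seed=42))
result = compute_debias(sample, k=15, seed=7)
print(result.gi, result.li)
```

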