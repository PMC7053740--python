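# Methods

## Problem and model

Bi-level thresholding assumes a gray-level histogram with two modes (object
and background) separated by a valley. Classical selectors (Otsu, Kapur)
use brightness alone and degrade when noise or texture blurs the valley.
This package implements a two-dimensional variant: each pixel is described
by the pair (gray level *i*, normalized local relative entropy *j*), and
the threshold is chosen on the resulting L × L joint histogram.

The local relative entropy (LRE) of a pixel over an n × n window is

    J(x, y) = Σ_w I_w · | log( I_w / Ī(x, y) ) |

where the sum runs over the window values I_w and Ī is the window mean.
J is zero on perfectly flat neighborhoods, small inside homogeneous
regions, and large at edges and on noise pixels. J is min–max scaled to
integers in [0, L−1]; because a change of log base multiplies the raw map
by a constant, the normalized map is log-base invariant (asserted by a
test), and natural log is used internally.

A threshold vector (s, t) splits the joint histogram into four quadrants.
The low-LRE strip j < t holds the object/background mass, divided at the
gray cut into C0 (i < s) and C1 (i ≥ s); the high-LRE quadrants j ≥ t hold
edge/noise mass. Class probabilities P0, P1 and mean vectors μ0, μ1 are
moments of the strip cells. The selection criterion is a coordinate-
weighted relative entropy between the image and its two-class summary:

    D(s, t) = Σ_{i<s, j<t} [ i p_ij log(i/μ0i) + j p_ij log(j/μ0j) ]
            + Σ_{i≥s, j<t} [ i p_ij log(i/μ1i) + j p_ij log(j/μ1j) ]

with the conventions 0·log 0 := 0 (terms with i = 0 or j = 0, or with a
zero mean coordinate, vanish) and (s, t) admissible only when both classes
are nonempty. `relative_entropy_criterion` computes exactly this quantity.

## Why the selector charges the excluded quadrants

Each class block of D is a Jensen dispersion and hence nonnegative
(E[x log x] ≥ E[x] log E[x] under the class distribution). Consequently D
shrinks monotonically as the strip is emptied, and minimizing D jointly
over (s, t) as written is **degenerate**: the optimum always collapses to
the smallest admissible sliver of strip mass — a handful of minimum-LRE
pixels — and the selected s carries no information about the gray-level
valley. On a noisy two-mode phantom this produces essentially random
segmentations (measured end-to-end ME ≈ 0.43 at noise σ = 10).

`select_threshold_min_re` therefore treats the high-LRE region (all i,
j ≥ t) as what the quadrant semantics say it is — a third, edge/noise
class — and charges it its own dispersion term of the same functional
form, with its own mean vector. Total histogram mass is then conserved
across candidate vectors, no mass can be "hidden" from the objective, and
the joint search becomes well-posed: t* settles where the LRE tail
separates from the low-LRE bulk and s* at the gray-level valley of the
bulk. Measured on 128 × 128 phantoms with modes 60/180: σ = 0 gives
median ME = 0 (s* = 61, t* = 1); σ = 10 gives median ME = 0 with s* in
the valley (≈ 111–129) and interior t*; σ = 20 gives median ME ≈ 0.008.
`charge_excluded=False` restores the literal strip-only objective for
study; the two-delta identity (D = 0 with each class at a single cell,
lexicographically smallest minimizer) holds under both objectives because
the excluded region is empty at the minimizer.

Labeling uses the gray cut alone: foreground iff I(x, y) < s*. The LRE
cut only shapes the criterion during selection; an `invert` flag flips
polarity, and evaluation can minimize ME over both polarities, since a
thresholder cannot know which side is the "object".

## Comparison selectors

* `otsu_1d` / `kapur_1d`: the classical 1-D criteria on the gray-level
  histogram; classes i < s and i ≥ s, renormalized for Kapur.
* `otsu_gllre` / `kapur_gllre`: the same criteria restricted to the C0/C1
  strip regions of the joint histogram (between-class scatter around the
  renormalized strip mean; sum of renormalized class Shannon entropies).
  These are reconstructions: the comparison methods are conventionally
  named in the 2-D thresholding literature but their quadrant conventions
  are not standardized, and the regions here were chosen for consistency
  with the C0/C1 semantics above.

All 2-D searches are exhaustive over (s, t) ∈ [1, L−1]² using 2-D prefix
sums of p, i·p, j·p, i·p·log i, j·p·log j (plus column suffix sums for the
excluded-region term), so each candidate is O(1) and a full L = 256 search
is a few milliseconds. Every selector is verified against an O(L⁴)
(or O(L²)) brute-force twin on random L = 16 histograms.

## Numerical choices

* **Ties.** Distinct (s, t) with, e.g., an unoccupied gray level between
  the cuts give mathematically identical criterion values that differ by
  ~1e−16 between summation orders. Values within 1e−12 (relative) of the
  optimum are treated as exact ties and the lexicographically smallest
  (s, t) is returned, in both the fast selectors and the brute-force
  oracles; genuine criterion gaps on integer histograms are many orders of
  magnitude larger.
* **Normalization rounding.** The LRE map is scaled by
  (J − Jmin)/(Jmax − Jmin)·(L−1) and rounded half-up; a constant raw map
  (e.g. a constant image) normalizes to all zeros.
* **Borders.** Windows leaving the image are filled by edge replication
  (default) or mirror reflection; the LRE map keeps the full M × N support
  so histogram mass is exactly M·N pixels.
* **Zero pixels.** Terms with I = 0 use the entropy convention
  0·|log 0| := 0; an all-zero window has mean 0 and LRE 0.
* **Degenerate inputs.** A constant image admits no threshold: selectors
  raise `NoThresholdError` (CLI exit code 2) rather than returning an
  arbitrary cut.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `window` (n) | 3 | pixels | smallest odd window; larger n smooths the LRE map |
| `border` | replicate | — | edge extension; `mirror` optional |
| `levels` (L) | 256 | gray levels | 16-bit input is rescaled to 8-bit by v·255/65535 |
| `charge_excluded` | True | — | see above; False = literal strip objective |
| `invert` | False | — | foreground polarity of output masks |

## Synthetic phantoms

`generate_phantom` renders two-class images (disks, rectangles, or
smoothed-field blobs) with background mode 60 and foreground mode 180 by
default — a 120-level gap emulating the deep-valley regime — covering
roughly 20% foreground area, plus additive Gaussian noise (rounded,
clipped to [0, L−1]) of configurable σ. The rasterized geometry is the
exact ground truth. These phantoms do not emulate real microscopy physics
(no PSF, shot noise, illumination gradients, or partial-volume edges), so
a green end-to-end test establishes correctness of the pipeline and noise
robustness in the additive-Gaussian bimodal regime only, not performance
on real images.

## Evaluation

Misclassification error: ME = 1 − (|B_o ∩ B_T| + |F_o ∩ F_T|)/(M·N), the
fraction of pixels whose label disagrees with ground truth; 0 is perfect,
1 completely wrong. `best_polarity_me` reports min over the two mask
polarities and which orientation won (ties prefer unflipped).

## Known limitations

* Bi-level only; no multi-level or locally adaptive thresholding.
* The Otsu-GLLRE / Kapur-GLLRE region conventions are reconstructions
  (see above).
* The excluded-region charge in the default selector objective is this
  package's resolution of a degeneracy in the strip-only criterion; both
  objectives are exposed.
* Evaluation offers ME only; region metrics (IoU, Dice) are out of scope.
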