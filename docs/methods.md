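# Methods

This note documents the models and procedures implemented in `addftir`, the
assumptions behind them, the parameters that matter, and the design choices
made where the underlying workflow left them open.

## Spectral data model

A spectrum is a pair (ν̃, A) of a strictly monotonic wavenumber grid (cm⁻¹,
stored descending by FTIR convention; ascending input is normalized on
read) and finite absorbance values, plus an infobox (sample name,
abbreviation, supplier, source id, form, color, acquisition method
ATR/transmission). Grids are considered identical when they agree within
10⁻⁶ cm⁻¹; otherwise spectra are made compatible by linear interpolation,
which is exact for affine intensity profiles and refuses to extrapolate.
Cropping uses closed intervals: a request for 3600–1250 cm⁻¹ on a
4 cm⁻¹ grid registered at 4000 retains 3600 down to 1252 because no
datapoint falls at 1250.

## Database preprocessing chain

Reference spectra pass, in fixed order: rubberband baseline correction →
straight-line replacement of an uninformative window → crop to the imaging
range → negative clipping → percent normalization. Each step is linear or
positively homogeneous before the final closure, so the chain is invariant
to positive scaling of the input — deliberate, because ATR contact pressure
and particle thickness scale absorbance arbitrarily.

**Rubberband baseline.** The commercial "concave rubberband" routine is
unpublished; the implementation here is an iterated lower-convex-hull band:
anchor points (default 64, endpoints always included) are placed evenly
along the grid; each of the (default 10) iterations computes the lower
convex hull of the residual at the anchors, accumulates the interpolated
hull into the running baseline, and clamps the baseline to lie at or below
the data at the anchors. With anchors at every datapoint and one iteration
this reduces exactly to lower-convex-hull subtraction, which is the oracle
the tests compare against. With the 64-anchor default the band is piecewise
linear between anchors, so a smooth concave-up baseline is removed only to
O(h²) chord error (~10⁻⁴ of amplitude at 64 anchors); the dense-anchor
configuration removes it to machine precision.

**Window replacement.** Data inside a closed wavenumber window is replaced
by the straight segment joining the nearest datapoints just outside each
edge — idempotent by construction. Defaults: 2475–1970 cm⁻¹ for ATR spectra
(diamond-crystal artifact) and 2420–2200 cm⁻¹ for transmission spectra
(atmospheric CO₂). Windows touching the grid boundary are rejected, since
one side would have no anchor.

**Normalization.** "Percent" normalization is closure to a total of 100
(not max = 100): Hellinger distances operate on relative abundances, so the
compositional closure is the matching convention. Negative values are
clipped to zero first; an all-zero spectrum is an error, not a silent zero
vector.

**Derivative.** First derivatives use Savitzky–Golay convolution (window 9,
polynomial order 2 — the de-facto standard in FTIR work), differentiating
with respect to wavenumber on the uniform grid; edge points come from
one-sided polynomial fits. The derivative channel is invariant to additive
offsets and, after vector normalization, to positive scaling.

**SNR exclusion.** SNR = (max − median of the signal window) / SD of the
linearly detrended noise window; defaults: signal = the full retained
range, noise = 2100–1900 cm⁻¹ (a window left featureless after artifact
replacement), threshold 10. A zero-variance noise window reports +∞.
Exclusion applies to database construction only — imaging pixels are never
discarded, only left unassigned.

## Cluster analysis

Distances between percent-normalized spectra are Hellinger distances
D(p,q) = √Σ(√pᵢ/ΣP − √qᵢ/ΣQ)², kept on the [0, √2] scale (no 1/√2 factor).
Agglomeration uses `scipy.cluster.hierarchy.linkage`; group-average (UPGMA)
is the default, matching common practice in the multivariate-ecology
software this workflow grew out of, with single and complete linkage
available. Correctness is checked against a naive O(n³) agglomeration
oracle (lexicographic tie-break) via cophenetic matrices; ties are
measure-zero for the random matrices tested, so the library's internal
tie-breaking is not load-bearing.

**SIMPROF.** For one candidate group (n ≥ 3 members), the observed ordered
resemblance profile d₍₁₎ ≤ … ≤ d₍ₘ₎ is compared with its mean profile under
999 within-variable permutations; the departure π = Σₖ|d₍ₖ₎ − mean₍ₖ₎| is
referred to 999 further permutations, p = (1 + #{π\* ≥ π}) / (1 + 999).
Variables are permuted across samples (the samples-exchangeable variant).
Groups of ≤ 2 members carry no testable profile and are declared
homogeneous. Under an exchangeable null the p-value is exactly uniform by
construction, and the Monte-Carlo calibration test confirms a type-I rate
within [0.03, 0.07] at α = 0.05 over 500 groups (8 samples × 30 variables —
sized so 500 × 1998 permutations stay inexpensive; the statistic is
batched over permutations with einsum). The dendrogram partition descends
from the root, stopping at homogeneous nodes. Following the workflow's own
finding that a pure permutation rule over-fragments spectral libraries,
SIMPROF output is advisory: cluster tables are authored through curation
operations.

**Curation ledger.** Merge (union under the lowest cluster number, names
concatenated), split (rename if one target name, else fresh numbers after
the current maximum in sorted-name order), add material (new cluster or
existing number; the cluster analysis is re-run over the extended entry
set), remove, and renumber are each recorded as one ledger line; replaying
the ledger on the initial library reproduces the final table exactly. This
makes a published cluster table a pure function of (initial clustering,
ledger). The final published 32-cluster design itself is carried as data
(`addftir.add_design`), not recomputed — it encodes expert judgment.

## Pixel identification

Each pixel is searched twice: the raw channel runs the database chain
(minus SNR exclusion) on the pixel spectrum — imaging pixels are
transmission measurements, so the CO₂ window is line-replaced — and
correlates against library entries cropped to the search range; the
derivative channel correlates the vector-normalized Savitzky–Golay
derivative against derivative-transformed entries. Hit quality is Pearson
correlation floored at 0. The best entry wins; exact ties break toward the
lowest cluster number, then the lexicographically smallest entry id.

A pixel is assigned only when both channels return the same cluster number
and both qualities reach their thresholds. The commercial search's
algorithm and thresholds are unpublished, so the defaults here (Pearson,
0.6/0.6) are an explicit, configurable choice — they are *not* calibrated
to reproduce any published particle count. The agreement rule makes
assignment monotone in the thresholds: raising either threshold can only
unassign pixels. Pixels that defeat preprocessing (all-zero, zero variance)
are unassigned with the reason retained, never dropped. A pixel-region mask
supports blanking known substrate areas (e.g. a filter's polypropylene
support ring).

## Particle analysis

Assigned pixels are split into per-cluster binary masks. Each mask is
closed morphologically (square element, default radius 1 — the smallest
kernel that fills one-pixel dropouts) *before* labeling; whether to close
the global mask or per-cluster masks was an open choice, and per-cluster
closing was chosen so pixels gained by closing adopt an unambiguous
cluster. Closing is computed on a padded canvas, so it is extensive and
idempotent. Components are 8-connected by default (4-connected splits
diagonal particle edges spuriously).

Particle size is a maximum-Feret-type extent: (largest pairwise distance
between pixel centers) × pitch + pitch. The +pitch term makes a single
pixel report exactly one pixel pitch (11 µm at the default 4 × 4-binned
imaging geometry), consistent with the smallest size class of the size
distribution. For components above 400 pixels the extent is computed on the
convex hull. Size histograms bin [edge, next edge) with default edges at
the pitch and then 20…500 µm in 10-µm steps, open-ended above; composition
summaries report per-cluster percentages over all particles and optionally
within a configurable "plastic" subset.

## Validation scoring

The five-level quality score maps difference counts to {1, 0.75, 0.5,
0.25, 0.01}: no difference → 1; one/two minor → 0.75/0.5; exactly three
minor, or exactly one major with no minor → 0.25; everything worse — more
than three minor, more than one major, or any mix of minor and major →
0.01. The printed scheme's overlap at "three minor" is resolved in favor of
0.25 for exactly three and 0.01 beyond; mixed minor+major falls to the
floor. Detecting what counts as a minor or major band difference remains a
human judgment: the operation takes counts, it does not compare band lists.

## Synthetic data

Pseudo-polymer spectra are sums of Gaussian bands (Lorentzian/Voigt shapes
add realism but nothing to testability); band centers avoid the
2150–2500 cm⁻¹ replacement window so no synthetic polymer loses a
diagnostic band to the straight-line step. Library generation redraws
candidates until all pairwise Hellinger distances clear a floor (default
0.5), guaranteeing separability. Scenes place rectangular or disk particles
(thickness multiplies absorbance linearly — a Beer–Lambert idealization —
with an optional absorbance cap emulating detector saturation of thick
particles), an optional weak broad background band around 3400 cm⁻¹
emulating biogenic silica residue, per-pixel linear baseline drift, and
i.i.d. Gaussian noise. All generators are pure functions of (spec, seed).

What passing tests show — and what they do not: the synthetic cubes have
uncorrelated noise, linear baselines, and library spectra identical to the
particles' true spectra. Real imaging data adds scattering distortions,
water-vapor lines, mixed pixels at particle edges, and library/sample
instrument mismatch; recovery rates on synthetic scenes are therefore an
upper bound, not a field performance claim. Default benchmark sizes
(64 × 64 pixels, ≤ 12 particles, 10 noise seeds; 500 SIMPROF null groups)
were chosen as the smallest configurations that exercise every code path
with stable statistics.

## Known limitations

* The extended ATR correction applied to black reference materials is a
  proprietary optical model; such spectra must be imported pre-corrected.
* Atmospheric water-vapor compensation and Mie scattering correction are
  out of scope.
* The JCAMP-DX writer emits AFFN only (readers also accept SQZ/DIF/DUP).
* Reading proprietary binary instrument files is not included; convert to
  JCAMP-DX or the documented cube format first.
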