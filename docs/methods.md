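# Methods

## Problem and signal model

Protein-coding DNA exhibits the *period-3 property*: because base usage
differs across the three codon positions, the spectrum of a numerically
mapped coding sequence carries excess power at 1/3 cycles/base, while
non-coding sequence does not. `period3` locates coding regions by scoring
that frequency along a sequence with two estimators: a classical averaged
periodogram (the SDFT baseline) and a minimum-norm noise-subspace
pseudo-spectrum estimator, which is the core of the package.

### Numeric mapping

A DNA string over `{a, c, g, t}` is mapped to a single complex series.
The default *proposed quaternary code* assigns

    a → −1,  c → −j,  g → +1,  t → +j

(the K-Quaternary Code-III reflected about the imaginary axis).  The code
is a bijection, so the signal is information-preserving; `inverse_map`
recovers the sequence exactly.  The Voss four-indicator representation and
the K-Quaternary codes I/III are also provided.  Ambiguous `n` bases map
to 0 with a warning, preserving coordinates without biasing any base
channel.

Within a coding window the mapped signal decomposes into a deterministic
periodic mean plus noise.  Writing m₀, m₁, m₂ for the mean mapped value at
each codon position, the periodic part has exactly three Fourier
components: DC and one line at each of ±1/3 cycles/base.  This motivates
the exponentials-in-noise model

    x[n] = Σᵢ Aᵢ e^{j n wᵢ} + w[n]

with a small number p of complex exponentials in white noise of variance
σ².

### Minimum-norm estimation

The M-lag autocorrelation matrix of the model is R = E P Eᴴ + σ² I.  Its
eigendecomposition splits ℂᴹ into the *signal subspace* (eigenvectors of
the p largest eigenvalues) and the orthogonal *noise subspace* V_n.  Every
noise-subspace vector is orthogonal to the steering vectors
e(w) = [1, e^{jw}, …, e^{j(M−1)w}]ᵀ at the true frequencies, so

    P_LN(w) = 1 / |e(w)ᴴ a|²

peaks at them.  Among noise-subspace vectors with unit first element, the
estimator uses the one of minimal Euclidean norm,

    a = P_n u₁ / (u₁ᴴ P_n u₁),    P_n = V_n V_nᴴ,

which places the p signal zeros of A(z) = Σ a_k z^{−k} on the unit circle
and pushes all spurious zeros inside it, suppressing false peaks.  The
implementation computes a = V_n ḡ / ‖g‖² with g the first row of V_n, sets
a[0] = 1 exactly, and raises a diagnostic error when u₁ is orthogonal to
the noise subspace.  Tests verify, against exact rank-p autocorrelations:
unit first element, noise-subspace membership, minimal norm versus an
independent LAPACK constrained solve, Hermitian idempotence of P_n, nulls
at the true frequencies (≤ 1e−6) and spurious-root containment
(|z| < 1 + 1e−6).

### Positional application

The estimator is applied per sliding window: map → autocorrelation
(biased-lag Toeplitz estimate, positive semidefinite by construction) →
eigendecomposition → least-norm vector → pseudo-spectrum value at exactly
f = 1/3 via the steering-vector inner product (no FFT grid error).  Track
values are reported in dB at 1-based window-center positions; windows
where a step fails (e.g. a gap-free eigenvalue spectrum under automatic
order selection) are masked as NaN, never fabricated.  Values are capped
at 1e12 before the dB conversion, since a window can land arbitrarily
close to an exact null in floating point.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| window | `choose_window_length(N)`: multiple of 3 in (N/25, N/3), anchored at N/23 | resolution–variance compromise; ≈ 351 for an 8 kb gene span.  For exon-scale detection choose the window near the expected exon length (the fixtures use 120 bp, 60 bp for the 28-bp stress case) |
| hop | 3 bases | track resolution; codon-aligned steps |
| lag M | window/3, clamped to [12, 60] | M must exceed p by a margin while leaving ≥ 3 samples per lag for averaging |
| order p | fixed 3 | DC + the two period-3 lines of the coding model.  Per-window eigenvalue-ratio selection (`order="auto"`, argmax of λ_q/λ_{q+1}) is available and is the right tool for whole-sequence scree studies, but on pure-background windows it nulls arbitrary frequencies and creates false spikes, so it is not the prediction default |
| taper | Bartlett (triangular), 50 % overlap | the standard averaged-periodogram operating point; per-segment window-power normalization makes the rectangular case reduce exactly to the plain periodogram |
| SDFT threshold | 1.75 (mean-relative) | the stricter of the two conventional dimensionless operating points; the track is normalized to unit mean first because the absolute PSD scale is arbitrary |

## Peak calling

Periodogram tracks are thresholded at a mean-relative level.  Least-norm
tracks are called threshold-free by three criteria applied to contiguous
above-noise runs (runs separated by less than window/4 are merged):

1. **MAD prominence** — sample exceeds the track median by more than
   6 median absolute deviations;
2. **absolute null depth** — sample ≥ 10 dB.  The minimum-norm vector has
   unit first element, so its off-null response is O(1) ≡ 0 dB; a genuine
   period-3 null is orders of magnitude deeper.  The MAD criterion alone
   is insufficient because the background track is extremely flat
   (MAD ≈ 0.3 dB) yet heavy-tailed;
3. **persistent support** — the merged region must span at least
   window/3 bases.  A real exon shows its null in *every* window covering
   it, so its support is at least comparable to the exon and window
   lengths; chance background nulls are tied to a particular stretch of
   sample noise and decay as the window slides.  Measured over 20
   background-only 2.4 kb simulations, background clusters never exceeded
   ~69 bases of support, while true-exon clusters span 60–560 bases.

Each called region carries one representative peak (its maximum).  A
prediction matches an annotated exon iff the peak position lies within
the exon interval (an optional `slack` widens intervals).  Exon-level
scores follow the standard definitions Sn = Tp/(Tp+Fn), Sp = Tp/(Tp+Fp),
Mr = Me/Ae, Wr = We/Pe; zero-denominator rates are reported as undefined,
never as 0.

Residual false-call behaviour: at the default settings the least-norm
caller emits roughly one spurious region per ~10 kb of pure background.
The threshold-free story holds at the scale of single-gene spans, not
unboundedly.

## Quality factor

Track spikiness is summarized by the quality factor.  The default
convention is variance over squared mean (population variance, zero for a
constant spectrum); the reciprocal convention is also implemented because
both appear in the literature this statistic comes from.  `percent_rise`
reports the relative gain of the least-norm quality factor over the SDFT
baseline.

## Synthetic data

The generator emulates the mechanism behind the period-3 property and
nothing else.  Background bases are i.i.d. uniform; exon positions are
drawn from `(1−β)·uniform + β·codon_profile[(i − start) mod 3]`, with the
codon phase anchored at each exon start (detection at f = 1/3 is
frame-agnostic, so inter-exon frame continuity is irrelevant).  The
default profile skews position 1 toward g/a and position 3 toward g/c,
concentrated enough that the mapped period-3 coefficient is ≈ 0.30 at
β = 1 — a strong-codon-bias idealization.  The canonical fixtures are:

* `single_exon` — 1200 bp, one 300 bp exon (451–750), β = 0.9, seed 42;
* `three_exon` — 2400 bp, exons of 71/622/195 bp reproducing the layout
  proportions of a well-studied *C. elegans* three-exon gene, β = 0.9,
  seed 43;
* `short_exon` — 900 bp with a single 28 bp exon, β = 1 with a point-mass
  (g, t, c) profile (the base triplet whose mapped values carry the
  largest possible period-3 component).  A 28 bp exon under partial bias
  is below the physical detection limit of a windowed estimator; the
  deterministic profile isolates the exon-length effect;
* `negative_control` — 1200 bp of pure background.

What passing tests on these fixtures do **not** show: performance on real
genes.  Real coding sequence has weaker and heterogeneous codon bias, GC
structure, splice motifs and length distributions the generator does not
model; the synthetic results bound the method's behaviour under its own
model assumptions only.

`simulate_exponentials` realizes the exponentials-in-noise model directly
(uniform random phases, circular complex Gaussian noise) and drives the
frequency-recovery experiment: two lines at 10 dB SNR, N = 1024,
autocorrelation lag 32, order 2, 512-point grid — both frequencies are
recovered within one grid bin in ≥ 95 % of 100 seeded repetitions.

## Numerical choices

* biased-lag autocorrelation (Toeplitz, PSD) is the default estimator; a
  snapshot outer-product estimator is available for comparison;
* eigendecomposition via Hermitian `eigh`; inputs are symmetrized when
  within 1e−10 relative of Hermitian, rejected otherwise; descending
  eigenvalue order; ties broken by sort index;
* eigenvalue ratios guard against division by zero with a 1e−300 floor;
  an all-equal spectrum raises "no eigenvalue gap";
* pseudo-spectrum cap 1e12; dB floor via `log10(max(v, 1e−300))`;
* population (1/L) variance in the quality factor;
* all randomness flows through explicitly seeded `numpy` generators; no
  global RNG state is touched.

## Known limitations

* The per-window adaptation is a reconstruction: the original published
  workflow reports positional period-3 peaks without stating its window,
  hop, or per-gene lag, so only peak counts and exon containment are
  promised, not peak shapes.
* Printed segment counts for the averaged periodogram in the source
  material are not reproducible from any single overlap convention; the
  package reports K derived from (N, M, overlap).
* Automatic order selection is reliable on whole-sequence spectra with a
  clear signal/noise gap, not on short background windows.
* Reverse-strand genes are out of scope (no reverse complementing), as is
  nucleotide-level scoring.
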