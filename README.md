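# period3

Locating protein-coding (period-3) regions in DNA with a minimum-norm
noise-subspace pseudo-spectrum estimator.

Coding DNA carries a spectral signature at **1/3 cycles/base**: the three
codon positions use bases non-uniformly, so a numerically mapped coding
sequence has excess power at that frequency, while introns and intergenic
background do not.  `period3` turns this into an exon predictor for
people analysing gene structure with signal-processing tools:

* **mapping** — single-sequence complex quaternary codes (default:
  a → −1, c → −j, g → +1, t → +j, a bijection on the four bases) and the
  Voss binary indicators;
* **least-norm estimator** (the core) — per sliding window, the M-lag
  autocorrelation matrix R = E P Eᴴ + σ²I is eigendecomposed into signal
  and noise subspaces; the noise-subspace vector **a** with unit first
  element and minimal Euclidean norm, a = P_n u₁ / (u₁ᴴ P_n u₁) with
  P_n = V_n V_nᴴ, defines the pseudo-spectrum P(w) = 1/|e(w)ᴴ a|², which
  peaks sharply at true signal frequencies while its spurious polynomial
  roots are pushed inside the unit circle.  The value at f = 1/3 per
  window, in dB, forms the coding-region track;
* **SDFT baseline** — Bartlett-windowed, 50 %-overlap averaged
  periodogram and its sliding period-3 track;
* **model-order selection** — largest eigenvalue-ratio gap λ_p/λ_{p+1}
  (scree elbow);
* **evaluation** — exon-level sensitivity Sn = Tp/(Tp+Fn), specificity
  Sp = Tp/(Tp+Fp), miss rate Mr = Me/Ae, wrong rate Wr = We/Pe, and a
  spectrum-spikiness quality factor (variance over squared mean);
* **synthetic data** — a seeded generator of codon-position-biased exons
  in uniform background, so the whole pipeline is testable without
  downloads.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Generate the canonical synthetic fixtures and compare both methods on the
three-exon gene (2400 bp; exons of 71, 622 and 195 bp at 600–670,
913–1534, 1579–1773):

```sh
period3 simulate --suite -o fixtures
period3 compare fixtures/three_exon.fasta \
    --truth fixtures/three_exon.bed --window 120 -o cmp
```

which prints (abridged):

```json
{
  "least_norm": {
    "metrics": {"Sn": 1.0, "Sp": 1.0, "Mr": 0.0, "Wr": 0.0, "Tp": 3, "Fp": 0},
    "n_regions": 3,
    "quality_factor": 47.56
  },
  "sdft": {
    "metrics": {"Sn": 1.0, "Sp": 0.75, "Mr": 0.0, "Wr": 0.25, "Tp": 3, "Fp": 1},
    "n_regions": 4,
    "quality_factor": 1.198
  },
  "percent_rise_qf": 3869.4
}
```

The least-norm track calls exactly the three annotated exons and nothing
else (Sn = Sp = 1, no threshold required), while the thresholded
periodogram baseline adds a false region (Sp = 0.75).  The quality factor
— variance of the track over its squared mean, large for spiky
low-background spectra — rises by ~3.9 × 10³ percent from baseline to
least-norm, the same order of improvement reported for real *C. elegans*
genes.

The same run is available from Python:

```python
from period3 import generate_gene, predict_regions, confusion_counts, prediction_measures
from period3.synthetic import FIXTURE_SPECS

seq, exons = generate_gene(FIXTURE_SPECS["three_exon"])
track, regions, settings = predict_regions(seq, window=120)
print([p for p, _ in regions.peaks])        # [661, 1321, 1642]
print(prediction_measures(confusion_counts(regions, exons)).Sn)  # 1.0
```

For real sequences: `period3 predict genome.fasta --window 351 -o track.tsv
--bed calls.bed [--truth exons.bed]` — window length should sit in
(N/25, N/3) and near the expected exon scale; `choose_window_length`
picks a default.

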