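# topoeeg

Persistent-homology analysis of multichannel EEG functional networks, built
for a two-condition visual paradigm: ordered Gestalt images (GST) versus
random sequence diagrams (RSD). The package asks whether the *topology* of
the evoked brain network — not any single channel's response — separates
the two kinds of percepts, and provides a seeded synthetic-EEG generator so
the whole pipeline is testable without access to recordings.

It is aimed at EEG/cognitive-neuroscience researchers who want
topological-data-analysis features (Betti curves, Euler characteristic
curves, persistent entropy) from band-limited epoch data, with a
scikit-learn-style API that composes with sklearn pipelines and model
selection.

## The method

Per trial and frequency band (δ, θ, α, β, or 1–45 Hz broadband), two
channel-pair matrices are built from the band-limited epoch:

* **Phase locking** `C_pq = |1/N Σ_n exp(j(φ^p(n) − φ^q(n)))|`, with
  instantaneous phases φ from the analytic (Hilbert) signal — `C_pq = 1`
  means perfect locking;
* **Standardized distance** `d(r,t) = Σ_k ((r|_k − t|_k)/s_k)²`, with `s_k`
  the cross-channel standard deviation at sample `k`.

Each matrix is converted to dissimilarity weights in [0, 1] (`1 − C`, or
min–max-normalized `d`) and swept by a Vietoris–Rips filtration: a simplex
on a channel subset enters at scale ε equal to its largest pairwise weight.
From the filtration the package computes, by GF(2) boundary-matrix
reduction written for this purpose (and cross-checked in the tests against
a brute-force rank oracle):

* persistence barcodes and Betti curves β₀(ε), β₁(ε), β₂(ε) — components,
  loops, voids;
* the Euler characteristic χ(ε) = Σ_k (−1)ᵏ n_k(ε), the Euler entropy
  S = ln|χ|, and the **phase-transition point** ε\*, the scale of the
  negative peak of S (where χ collapses through zero);
* **persistent entropy** `H = −Σ p_i log p_i` with `p_i = ℓ_i/Σℓ_j` over
  bar lengths, plus the rescalings `Ĥ = H/log ℓ_max` and
  `Ĥ_alt = H/log n_bars`.

Conditions are then compared per subject: ordering of the median ε\*
between GST and RSD trials, and a leave-one-trial-out threshold rule on the
per-trial entropy feature giving a distinguishing rate per band and matrix
kind. See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and known limitations (including a documented structural finding
about the direction of the C-matrix entropy difference on synthetic data).

## Worked example

```python
from topoeeg import SessionConfig, band_sweep

cfg = SessionConfig(seed=7)            # 19 channels, 30 RSD + 10 GST trials
res = band_sweep(cfg, bands=("theta", "alpha"), kinds=("C", "D"),
                 subject_id="S07")
print(res.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints

```
subject  band matrix_kind  distinguishing_rate  balanced_rate pe_direction  p_value transition_order  median_eps_GST  median_eps_RSD  median_H_GST  median_H_RSD
    S07 alpha           C                0.750          0.500      GST<RSD    0.000        GST_first           0.288           0.506         2.850         3.220
    S07 alpha           D                0.750          0.500      GST<RSD    0.003        RSD_first           0.262           0.236         2.634         2.803
    S07 theta           C                0.750          0.500      GST<RSD    0.229        GST_first           0.460           0.500         3.160         3.182
    S07 theta           D                0.750          0.500      GST<RSD    0.325        GST_first           0.192           0.193         2.471         2.575
```

Reading the alpha/C row: the GST network hits its topological phase
transition at roughly half the scale of the RSD network (median ε\* 0.288
vs 0.506) — the stimulus-locked channel cluster forms an early clique —
and the per-trial persistent entropies of the two conditions differ with
Mann–Whitney p < 0.001, GST below RSD. The distinguishing rate is the
leave-one-out accuracy of a fixed-direction threshold on `Ĥ_alt`; per-trial
features (H, Ĥ, Ĥ_alt, bar counts, ε\*) are in `res.features`.

The same pipeline runs from the shell, stage by stage or end to end:

```sh
topoeeg simulate --seed 7 --out session.tsv         # or session.edf
topoeeg run-all --seed 7 --bands alpha --kinds C,D --out run/
```

`run-all` writes `features.tsv`, `summary.tsv` and a `manifest.json` with
the config hash and library versions; runs with the same seed are
byte-identical.

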