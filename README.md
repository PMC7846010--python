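# nanolayers

Nanoscale image analysis for layered membrane protein distributions —
built around the question of how two bacterial toxins (Cry11Aa and
Cyt1Aa, the synergistic pair used against *Aedes aegypti* larvae)
organize on and inside mosquito midgut cells: which protein sits above
which at the apical membrane, how far apart the two layers are, and
whether the internalized protein clusters.

The package implements the three analysis stages such a study needs,
plus the statistics around them, and a synthetic-data module that makes
every stage testable against known ground truth:

* **SRRF reconstruction** (`nanolayers.srrf`) — per-frame radiality maps
  (gradient-convergence scoring on a magnified sub-pixel grid; defaults:
  ring radius 0.5, magnification 10, 8 axes in ring) reduced by the
  second-order temporal cumulant TRAC2 over a 100-frame stack.
* **Intensity-weighted Ripley statistics** (`nanolayers.ripley`) — for a
  grayscale ROI with pixel weights w,
  `K(r) = A Σ_{i≠j} w_i w_j e_i(r) 1(d_ij ≤ r) / (Σw)²`
  with Besag edge weights `e_i(r)`; a within-mask intensity-permutation
  null yields the normalized `K̃(r)` (zero mean, unit variance under
  CSR) and 1st/99th-quantile envelopes; per-radius classification into
  clustered / dispersed / random and the `argmax(K̃)` summary with
  Kruskal–Wallis + Dunn group comparisons.
* **Carpet alignment** (`nanolayers.carpet`) — membrane ROIs become
  intensity carpets (line profiles every ∂r = 25 nm); columns are
  aligned by the paired correlation function
  `pCF(∂y) = ⟨F(y,0)F(y+∂y,∂r)⟩ / (⟨F(y,0)⟩⟨F(y,∂r)⟩) − 1`
  via its sub-bin-refined argmax, and the signed inter-layer distance is
  read per column from the paired cross-correlation (pCCF), negative
  toward the cytoplasm. Summaries (mean ± SEM) are at the
  cellular-replicate level; modes are detected by KDE.
* **Scalar quantifications** (`nanolayers.quant`) — ROI fluorescence
  comparisons, dye degree of labeling (A/ε over molar protein), and the
  Tabashnik synergism factor: additive-expectation mixture LC50
  `[ρ/LC50_a + (1−ρ)/LC50_b]⁻¹` divided by the observed mixture LC50.

`nanolayers.synthgen` simulates blinking-emitter stacks (Gaussian PSF,
Poisson + read noise, optional Markov blinking and bleaching), deformed
two-layer membranes with a known signed normal offset, and CSR / Thomas
/ Matérn-II point fields — all seeded and carrying their ground truth in
metadata. See `docs/methods.md` for models, parameters and limitations.

## Worked example

The demo simulates a wild-type-like condition (test layer 26 nm below
the reference layer, toward the cytoplasm) and a mutant-like condition
(inverted offset), recovers both distance distributions through the
carpet pipeline, and contrasts a clustered against a random intensity
field through `K̃`:

```
nanolayers demo --seed 5 --out demo_out
```

prints (abridged):

```json
{
  "wild_type_like": {"mean_nm": -26.897, "sem_nm": 0.218, "n_replicates": 8},
  "mutant_like":    {"mean_nm":  27.038, "sem_nm": 0.453, "n_replicates": 8},
  "sign_inverted": true,
  "k_thomas": {"argmax_radius_nm": 225.0, "argmax_value": 117.1,
               "fraction_clustered_radii": 1.0},
  "k_csr":    {"argmax_radius_nm": 425.0, "argmax_value": 2.09,
               "fraction_clustered_radii": 0.0}
}
```

Read: the injected ±26 nm inter-layer offset is recovered with the
correct sign on both conditions (SEM over 8 simulated cells); the
Thomas-clustered field shows massive, significant clustering peaking
near its 100 nm cluster scale (K̃ far above the 99th-quantile envelope
at every radius), while the CSR field stays inside its envelopes. Per-ROI
CSVs (`distances_*.csv`, `k_curves.csv`), a JSON report and a
reproducibility manifest are written to `demo_out/`.

The same stages are available individually (`simulate`, `srrf`,
`ripley`, `carpet`, `quant sf|kw|dol`), e.g.:

```
nanolayers quant sf --lc50-a 329.3 --lc50-b 679.23 --ratio 0.5 --observed 51.53
{"theoretical_lc50": 443.55, "synergism_factor": 8.6}
```

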