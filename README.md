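# tilquant

Whole-slide quantification of tumor-infiltrating lymphocytes (TILs) and a
percentile-based immune score for colon cancer cohorts.

Pathologists increasingly score the adaptive immune infiltrate of
colorectal tumors — the density of CD3+ and CD8+ T cells in the tumor
center (TC) and at the invasive margin (IM) — because it carries prognostic
information independent of TNM stage. `tilquant` implements a transparent,
fully automated version of that workflow for brightfield H-DAB
immunohistochemistry:

1. **Stain separation.** An RGB slide image is converted to optical density
   (OD = −log₁₀((I+1)/255)) and unmixed into hematoxylin and DAB channels
   by least-squares projection onto the Ruifrok–Johansson stain vectors.
2. **Positive area → density.** DAB-positive pixels (OD ≥ 0.15, inclusive)
   are filtered by connected-component size (10–1000 µm² keeps cell-scale
   objects, removes speckle and smears), intersected with the TC or IM
   region polygon, and converted to a cell count via the mean lymphocyte
   area of 60 µm²; density = count / region area (cells/mm²).
3. **Immune score.** Over a cohort, each marker-region (CD3_TC, CD3_IM,
   CD8_TC, CD8_IM) gets its empirical 75th percentile; a patient is "high"
   for a marker iff density ≥ p75. The number of high markers (0–4, the
   I0–I4 strata) maps to the immune score: {0,1} → Low, {2} → Intermediate,
   {3,4} → High.
4. **Associations.** Chi-square tests of score group vs stage and MSI
   status; Mann–Whitney U tests of each marker density between MSS and MSI
   tumors (two-tailed, α = 0.05, unadjusted).

Because no raw slides or per-patient tables are deposited for real cohorts,
the package ships a first-class synthetic generator (`tilquant.synthio`):
H-DAB slides rendered through the forward Beer–Lambert model with exact
ground truth, and log-normal cohort tables reproducing the right-skewed,
IM > TC, MSI-elevated structure of real colon-cancer TIL densities.

## Worked example

```bash
tilquant run --n 119 --seed 1 --out demo/
```

simulates a 119-patient cohort, scores it against its own percentiles, and
writes every artifact (densities, thresholds, per-patient scores,
cross-tab, association report) to `demo/`. The threshold report
(cells/mm², rounded for presentation):

```
      CD3_TC  CD3_IM  CD8_TC  CD8_IM
25th     187     598      89     251
50th     349     949     251     427
75th     622    1572     476     806
```

Group sizes for this draw: Low 88 (73.9%), Intermediate 24 (20.2%), High 7
(5.9%) — about a quarter of patients are high per marker by construction
(exactly 30 of 119 for tie-free data), but few are high for 3–4 markers
simultaneously unless the four densities are strongly correlated within
patients. The association report flags the simulated MSI effect where the
draw has power:

```
        comparison   statistic  p_value  significant
 CD3_IM_MSS_vs_MSI     1242.00 0.046205         True
 CD8_TC_MSS_vs_MSI     1173.00 0.017343         True
 CD8_IM_MSS_vs_MSI     1426.00 0.334742        False
```

The image pipeline works the same way from the shell:

```bash
tilquant simulate slide --seed 2 --out slide/
tilquant quantify --image slide/slide.tif --annotation slide/annotation.geojson \
    --marker CD3 --out densities.csv
```

printing

```
CD3 TC: 450.0 cells/mm^2 (72.0 cells in 0.160 mm^2)
CD3 IM: 897.9 cells/mm^2 (143.7 cells in 0.160 mm^2)
```

against ground-truth densities of 456.2 (TC) and 893.8 (IM) cells/mm² in
`slide/ground_truth.json` — within ~1.5%, the expected boundary-clipping
bias at these small demonstration regions.

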