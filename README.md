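# molarq

Measurement-based assessment of mandibular third molar eruption on dental
panoramic radiographs (DPRs), for forensic age estimation research.

Third molar eruption is one of the few dental features still changing
between ages 15 and 25, which makes it a standard marker in forensic age
assessment of living individuals. Most radiographic methods describe
eruption with ordinal morphological stages; `molarq` implements a
*metric* alternative: an **eruption quotient** computed from annotated
landmarks, together with the statistics needed to evaluate it as an age
marker (rank correlation with age, intra- and inter-rater reliability)
and a seeded synthetic-cohort simulator so the entire analysis can be
validated end to end without access to radiographs.

## The measurement

On a zoomed molar region of a DPR, a *simplified occlusal plane* is drawn
from the radiologically highest mesial cusp point of the first molar to the
highest distal cusp point of the second molar. Two perpendiculars are
dropped from this line to the mesial cementoenamel junction (CEJ) of the
second molar (length *A*) and of the third molar (length *B*), and the
quotient

&nbsp;&nbsp;&nbsp;&nbsp;*Q* = *A* / *B* = d(M2 CEJ) / d(M3 CEJ)

is used in place of any absolute distance. A DPR is a geometrically
non-isometric projection whose magnification varies across the image, so
absolute lengths are not comparable between radiographs — but a quotient of
two nearby, near-parallel lengths is invariant to uniform magnification.
As the third molar erupts, its CEJ approaches the occlusal plane, *B* falls
toward *A*, and *Q* rises toward ≈ 1, so *Q* increases with age.

Records with a disto-angulated third molar (any degree) or with mesial
angulation exceeding 30° are excluded, as are records on which the plane or
the CEJ points cannot be placed.

The statistics follow the design of the underlying study: Spearman's ρ
between *Q* and exact age per tooth (FDI 38/48) and sex, with 95% CIs from
the Fisher *z* transform using the Bonett–Wright standard error
√((1 + ρ²/2)/(n − 3)); and Krippendorff's α (interval metric,
missing-tolerant) for agreement between two sessions of one rater and
between two raters, with cluster-bootstrap 95% CIs.

## Worked example

```python
from molarq import SimulatorParams, simulate_cohort, EruptionStudy, StudyConfig

records, truth = simulate_cohort(SimulatorParams(), seed=1)  # 2538 records
results = EruptionStudy(records, StudyConfig(seed=1, n_boot=500)).fit()
print(results.summary())
```

```
Third molar eruption quotient study
============================================================
records: 2538  included: 2287  measurement failures: 0
exclusions: {'DISTAL_ANGULATION': 251}
quotient direction: m2_over_m3  rounded lengths: True
alpha metric: interval  n_boot: 500  seed: 1
correlation basis: rater R1, session 2

Spearman rho (quotient vs age) by tooth and sex
Tooth      Sex  Estimate   95% LCL   95% UCL      n
   38     male     0.757     0.675     0.821    175
   48     male     0.736     0.651     0.803    183
   38   female     0.754     0.676     0.815    195
   48   female     0.757     0.681     0.817    200

Intra-rater Krippendorff alpha by tooth and sex
Tooth      Sex  Estimate   95% LCL   95% UCL      n
   38     male     0.991     0.988     0.994    167
   48     male     0.991     0.987     0.994    176
   38   female     0.993     0.991     0.995    192
   48   female     0.992     0.990     0.994    192

Inter-rater Krippendorff alpha by tooth and sex
Tooth      Sex  Estimate   95% LCL   95% UCL      n
   38     male     0.993     0.990     0.995    170
   48     male     0.991     0.988     0.994    180
   38   female     0.990     0.986     0.994    192
   48   female     0.992     0.989     0.994    196
```

The simulated cohort contains 423 subjects (220 female, 203 male) aged
15–25, each contributing both lower third molars read three times (rater 1
twice, rater 2 once) — 2538 annotation records. Disto-angulated teeth are
excluded (251 records here). The quotient correlates strongly with age in
every tooth × sex cell, and both repeatability and reproducibility of the
measurement are α ≈ 0.99: the measurement error injected by 1.5 px landmark
jitter is small against the between-subject spread of *Q*.

`results.save("outdir/")` writes one TSV per table (3-decimal formatting,
`NE` for non-estimable cells) plus `report.json` with full-precision values
and the complete configuration; reports are byte-deterministic given the
same inputs and seed.

The same pipeline is available from the shell:

```bash
molarq simulate --seed 1 --out sim
molarq measure sim_annotations.csv --out measurements.csv
molarq study full sim_annotations.csv --seed 1 --out report/
```

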