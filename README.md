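# radsens

RNA-seq based radiosensitivity profiling for paired tumour/normal cohorts.

Radiotherapy prescriptions are conventionally one-size-fits-all, yet the
radiosensitivity of both a tumour and the normal tissue around it is largely
transcriptionally determined. `radsens` turns a gene-level RNA-seq count
matrix into per-sample radiobiological profiles and cohort-level dosing
analyses, for researchers exploring genomically personalised fractionation.

## The model

1. **Normalization.** Raw counts are converted to counts per million and
   adjusted with TMM (trimmed mean of M-values) scaling factors so
   expression is comparable across samples despite depth and composition
   differences, then log2-transformed with a prior count of 1:
   `value = log2(count / (lib_size · factor) · 10⁶ + 1)`.

2. **Radiosensitivity index (RSI).** A fixed ten-gene linear signature in
   units of SF2 (surviving fraction at 2 Gy):

   ```
   RSI = −0.0098009·AR + 0.0128283·cJun + 0.0254552·STAT1 − 0.0017589·PKC
         − 0.0038171·RelA + 0.1070213·cABL − 0.0002509·SUMO1
         − 0.0092431·CDK1 − 0.0204469·HDAC1 − 0.0441683·IRF1
   ```

   evaluated on the normalized expression values. Lower RSI = more
   radiosensitive. Tumours with RSI > 0.4 are flagged as hypofractionation
   candidates.

3. **GARD dosimetry.** Under the linear-quadratic survival model with
   β = 0.05 Gy⁻² and the 2 Gy calibration fraction, the patient-specific
   α = −0.5·ln(RSI) − 0.1 (Gy⁻¹), and the genomic-adjusted radiation dose
   of an n × d Gy regimen is GARD = n·d·(α + β·d). Inverting at a GARD
   threshold gives the minimum total dose per patient:
   D = GARD_target / (α + β·d).

4. **Cohort analysis.** Tumour vs normal group summaries (mean ± sd),
   Welch unequal-variance t-tests, a GARD-high threshold (tumour median by
   default), the ECDF of per-patient minimum doses, dose-coverage fractions
   and an optional LOESS smooth.

A synthetic-data module generates negative-binomial cohorts with planted
panel expression and known ground truth, so the whole pipeline is testable
without any sequencing data.

## Worked example

```sh
python examples/01_rsi_to_dose.py
```

prints

```
tumour: RSI=0.43  alpha=0.3220 Gy^-1  GARD(50 Gy/25fx)=21.10  dose for GARD>=21: 49.8 Gy (25 fx)
normal: RSI=0.52  alpha=0.2270 Gy^-1  GARD(50 Gy/25fx)=16.35  dose for GARD>=21: 64.2 Gy (33 fx)
```

The tumour (RSI 0.43) clears the GARD-high threshold of 21 at the standard
50 Gy/25fx course, while the surrounding normal tissue (RSI 0.52) would need
64 Gy to experience the same biological effect — a favourable therapeutic
index. The other examples cover normalization + scoring
(`02_normalize_and_score.py`), a full synthetic cohort analysis
(`03_synthetic_cohort.py`) and the 14-patient dose-coverage curve
(`04_dose_coverage.py`).

The same workflow is scriptable from a shell:

```sh
radsens generate --design prostate --seed 2 --out-dir data/
radsens run data/counts.tsv data/samples.csv --out-dir results/ -n 36 -d 2
```

which writes `profiles.tsv` (per-sample RSI/α/GARD), `report.json`,
`dose_ecdf.tsv` and a run manifest.

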