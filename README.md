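# catacrotic

Analysis of the **catacrotic (falling) phase of the photoplethysmogram
(PPG)** as a monitor of the nociception–antinociception balance under
graded opioid analgesia.

During general anesthesia a noxious stimulus (for example laryngeal-mask
insertion) raises heart rate and deforms the pulse waveform; an adequate
analgesic level suppresses that response. This package implements the full
signal chain needed to quantify the effect from a single finger-PPG
channel, plus a synthetic-study generator so every stage is testable
without patient recordings:

1. **Wavelet denoising** — db4 discrete wavelet transform, 3 levels,
   SURE or minimax thresholds with soft/hard shrinkage; the rule×mode
   combination is ranked by SNR/RMSE against a clean reference when one
   is available. The cardiac band (≤ 6.25 Hz at fs = 100 Hz) is kept
   untouched in the deepest approximation.
2. **Fiducial detection** — systolic-peak candidates from the sign change
   of the first difference, verified against a sliding 0.6 s window;
   troughs as the minimum between adjacent peaks.
3. **Per-cycle normalization** — piecewise-linear baseline removal
   between troughs (both endpoints map to 0) and division by the systolic
   peak amplitude (peak = 1).
4. **Beat features** — per beat: pulse beat interval `PBI`, diastolic
   interval `DI`, diastolic slope `DS = 1/DI` (chord slope on a
   normalized cycle), steepest catacrotic slope `DSmin` (absolute value),
   `DTI` (time from the DSmin point to the trough), and the area
   difference ratio `ADR = (S_Δ − S_curve)/S_Δ`, where `S_Δ = DI·peak/2`
   is the triangle under the peak–trough chord and `S_curve` the area
   under the descending limb.
5. **Windowed summarization** — each parameter is normalized per subject,
   `par_norm = (par − mean_pre)/RMS_pre`, with both moments taken over the
   −70…−10 s pre-stimulus window; pre-/post-values are window averages
   (−70…−10 s and +10…+70 s, the ±10 s band is discarded).
6. **Statistics** — Wilcoxon signed-rank (pre vs post), Mann-Whitney
   (between concentrations), Kruskal-Wallis, Spearman matrix, a two-group
   sample-size computation by noncentral-*t* power iteration, and the
   **prediction probability P_K**: over subject pairs with different
   ordinal predictor levels, with C/D/T concordant/discordant/tied pairs,

   `pk_raw = (C + T/2) / (C + D + T) = (Somers' d_yx + 1)/2`,

   reported as `max(pk_raw, 1 − pk_raw)` with a direction flag and a
   delete-one jackknife standard error.

The denoiser, detector and P_K estimator also expose scikit-learn style
estimator classes (`WaveletDenoiser`, `FiducialDetector`,
`PredictionProbability`) with `fit`/`transform` and fitted attributes.

## Worked example

Simulate the three-group study (15 subjects at 0, 1 and 3 ng/ml), run the
whole pipeline and the statistical battery:

```sh
catacrotic run-all --n-per-group 15 --groups 0,1,3 --seed 0 --out report.json
```

which prints `analyzed 45 subjects (0 excluded)` and writes a JSON report.
With seed 0 the prediction probabilities of the post-stimulus values are

```
P_K(PBI)   = 0.821 (SE 0.050)
P_K(DI)    = 0.827 (SE 0.048)
P_K(DS)    = 0.827 (SE 0.048)
P_K(DSmin) = 0.831 (SE 0.045)
P_K(DTI)   = 0.830 (SE 0.047)
P_K(ADR)   = 0.538 (SE 0.076)
```

i.e. the interval- and slope-related parameters order the analgesic
concentration well above chance (P_K = 0.5 is chance level), while the
area ratio ADR carries almost no concentration information. The
within-group Wilcoxon tests show the stimulus response of PBI/DI at 0 and
1 ng/ml (p ≈ 10⁻⁴) but not at 3 ng/ml — the drug has abolished the
response. The same run reports the design computation: detecting a 0.1
change-rate difference with SD 0.08 at α = 0.05 and power 0.8 needs
**12 subjects per group**.

The equivalent library calls:

```python
import catacrotic as cc
from catacrotic.pipeline import run_study

study = cc.simulate_study(n_per_group=15, groups=(0, 1, 3), seed=0)
report = run_study([record for record, _ in study])
print(report["analysis"]["prediction_probability"]["DI"])
```

Individual stages are available as `catacrotic simulate | denoise |
detect | features | analyze` on CSV/JSON files (`time_s,amplitude` plus a
metadata sidecar).

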