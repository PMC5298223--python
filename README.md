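# chewfield

**Does chewing stimulate your brain?** The masticatory muscles (temporalis,
pterygoids) are the strongest electrical sources near the head, and cortical
electric fields of ~0.2 V/m are reported to modulate ongoing neural
activity and cognition. `chewfield` quantifies how chewing-muscle EMG
propagates through the head to the cerebral cortex and predicts, per
chewing event, whether the resulting cortical field crosses that
neuromodulation threshold — the "endogenous brain stimulation" hypothesis
for the puzzling cognitive effects of gum chewing.

It is written for computational neurophysiologists and bioelectromagnetic
modelers. Because the clinical recordings behind this question
(simultaneous scalp EEG + subdural ECoG during natural chewing in
implanted epilepsy patients) are not publicly available, the package pairs
the complete analysis pipeline with a parametric head phantom and a
synthetic recording generator, so every stage runs — and is tested — end
to end from code alone.

## What's inside

| module | contents |
|---|---|
| `chewfield.phantom` | concentric-shell head phantom with muscle compartments, CSF-filled craniotomy defects (burr holes, saw lines), a skull-base foramen channel and a face-sealed insulating electrode-grid patch; head-model variants HM1 (defects+grid), HM2 (grid), HM3 (healthy); electrode layouts; seeded chewing-recording generator; condition scaling table |
| `chewfield.signals` | common-average / single re-referencing, trial excerption, sliding-FFT relative spectra (250 ms / 24.41 ms windows), exact two-tailed sign test with Benjamini–Yekutieli FDR (q = 0.001), gamma-band topography, and the p90−p10 chewing-burst amplitude statistic with all parameter variants |
| `chewfield.fem` | hexahedral FEM forward solver (one trilinear element per voxel, Jacobi-CG to 1e−9), St. Venant dipole loads with exact moment constraints, source models SM1/SM2/SM3, multilayer concentric-sphere series oracle, RDM/lnMAG error metrics, and the three-head-model shielding suite |
| `chewfield.gridfit` | six-step electrode-grid reconstruction: shrinkwrap hull, corner-bounded patch, isomap (geodesic MDS) flattening, rigid 10 mm lattice with 3-nearest-neighbor back-projection, and the face-seal current-leak check |
| `chewfield.calibrate` | the four-step dosimetry: calibrate per-trial dipole strengths against intracranial amplitudes (implanted head), propagate through the healthy head, scale by chewing condition, report 0.2 V/m exceedance fractions; plus the end-to-end parameter-recovery experiment |
| `chewfield.study` | the published summary statistics (per-patient amplitude medians, trial counts, condition amplitudes) that anchor calibration and bookkeeping |

The core physics: quasi-static volume conduction `∇·(σ∇V) = ∇·Jᵖ` on a
labeled voxel grid with the standard conductivities (skull 0.0063 S/m,
CSF 1.54 S/m, …, silicone grid ≈ 0 S/m); a current dipole **p** enters as
St. Venant monopole loads with `Σq = 0` and `Σ q·(r−r₀) = p` exact; the
cortical field is `E = −∇V` over gray matter; and per-trial dipole
strength is `q_i = A_i / (2g)` with `A_i` the measured intracranial burst
amplitude and `g` the simulated unit-moment contact amplitude (the factor
2 spans the polarity reversal of a burst).

## Worked example

```python
import numpy as np
from chewfield import study
from chewfield.calibrate import parameter_recovery
from chewfield.fem import make_source_model, run_head_model_suite
from chewfield.phantom import PhantomSpec
from chewfield.signals import summarize_amplitudes

# 1. scalp-to-intracranial attenuation from the published per-patient medians
s = summarize_amplitudes(
    list(study.EEG_MEDIAN_AMPLITUDES_UV.values()),
    list(study.ECOG_MEDIAN_AMPLITUDES_UV.values()))
print(round(s["scalp_mean_uv"], 1), round(s["intracranial_mean_uv"], 1),
      np.round(s["attenuation_ratios"], 1))

# 2. shielding: forward-solve all three head models for the belly dipole
spec = PhantomSpec()
suite = run_head_model_suite(spec, make_source_model(spec, "SM1"))
p = {hm: suite["variants"][hm]["peak_subgrid_power_v2"]
     for hm in ("HM1", "HM2", "HM3")}
print(f"defects {100*(p['HM1']-p['HM2'])/p['HM1']:+.1f}%  "
      f"grid removal net {100*(p['HM3']-p['HM1'])/p['HM1']:+.1f}%")

# 3. end-to-end: recover designed dipole strengths and 0.2 V/m exceedance
res = parameter_recovery(spec, n_trials=500, snr=10.0, seed=123)
print(f"median strength error {100*res['median_rel_error']:.1f}%  "
      f"exceedance designed {res['exceedance_true_pct']:.1f}% "
      f"recovered {res['exceedance_est_pct']:.1f}%")
```

prints (a couple of minutes; four FEM solves at ~0.4 M elements):

```
30.4 5.7 [5.  4.6 5.3 9.  3.9]
defects +1.9%  grid removal net +26.5%
median strength error 0.8%  exceedance designed 29.0% recovered 29.2%
```

Line 1: scalp chewing bursts average 30.4 µV across patients, intracranial
5.7 µV — attenuation factors 5.0/4.6/5.3/9.0/3.9 from scalp to cortex.
Line 2: closing the craniotomy defects barely changes the EMG power
reaching the subdural contacts (1.9 %), while removing the insulating
silicone grid raises it by ~27 % — the implanted grid *shields* the very
cortex it records, so healthy heads receive more chewing EMG than the
patient measurements suggest. Line 3: the calibration chain recovers known
per-trial dipole strengths to ~1 % and the fraction of chewing events
whose healthy-head peak cortical field exceeds 0.2 V/m to within sampling
error.

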