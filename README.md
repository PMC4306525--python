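# dcmerf

Dynamic causal modelling of evoked MEG responses, built to test a
predictive-coding account of perceptual evidence accumulation: does
reaction-time variation in a motion-discrimination task reflect the
**intrinsic gain of pyramidal cells** (the physiological proxy for the
estimated precision of ascending sensory evidence) or the **strength of
extrinsic forward connections** between visual cortex (VC), the middle
temporal area (MT) and posterior parietal cortex (PPC)? The package is
aimed at computational neuroscientists who want the full inference chain —
neural-mass simulation, variational inversion, family-level Bayesian model
selection, model averaging, and sensitivity analysis — as tested,
composable Python, exercised end to end on synthetic data with known
ground truth (no proprietary recordings required).

## The model

Each cortical source is a three-population column (spiny stellate cells,
pyramidal cells, inhibitory interneurons) with intrinsic coupling gains
γ₁–γ₄, coupled by second-order synaptic kernels

    v̇ = i,   i̇ = (H/τ)·m − (2/τ)·i − v/τ²

and a centred sigmoid activation S(v). Sources are linked by excitatory
forward and (inhibitory and excitatory) backward connections; a sustained
cumulative-Gaussian input drives the lowest source. The three reaction-time
bins (slow/middle/fast, design codes x = 0, 1, 2) scale a hypothesis site
multiplicatively by exp(β·x): the stellate→pyramidal gain γ₂ of a region
(the *gain* hypothesis — γ₂ controls how strongly pyramidal cells respond
to a given ascending input, i.e. precision), or a forward edge (the
*connection* hypothesis). Pyramidal output passes through a lead field; the
mode-reduced sensor data are fitted by variational Laplace, whose free
energy F (accuracy − complexity) approximates the log model evidence.
Ten condition-modulation models in three families (gain: 6, connection: 3,
null: 1) are compared by random-effects family inference with exceedance
probabilities, and parameters of the winning family are combined by
Bayesian model averaging under Occam's window (posterior odds ≥ 0.05).

## Worked example

Generate a 12-subject synthetic group whose only condition effect is a
true β = 0.3 on PPC γ₂ at mode-space SNR 4, fit all ten modulation models
per subject, and run the family analysis:

```python
import numpy as np
from dataclasses import replace
from dcmerf.synth import (SyntheticGroundTruth, fixture_small,
                          generate_erf_dataset, modulation_model_space)
from dcmerf.forward import mode_reduce
from dcmerf.pipeline import run_family_analysis, reconstruct_group_responses

model, stim, grid, lf = fixture_small(beta=0.3, site=("gamma2", "PPC"))
truth = SyntheticGroundTruth(model=model, stim=stim, n_sensors=16,
                             n_subjects=12, snr=4.0, n_modes=4, master_seed=101)
ds = generate_erf_dataset(truth)
data = [mode_reduce(s, ds.modes, 0.0, 250.0) for s in ds.subjects]

models, families = modulation_model_space(replace(model, modulation=[]))
res = run_family_analysis(models, families, data, stim, lf, ds.modes, grid,
                          mc_samples=100_000, seed=7)

for name, xp in zip(res.family.family_names, res.family.exceedance):
    print(f"{name:12s} exceedance {xp:.3f}")
g = res.group_stats
for r, scale, p in zip(g.regions, g.scaling, g.p_corrected):
    print(f"{r:4s} scaling {scale:.3f}  p (one-tailed, corrected) {p:.4f}")

resp = reconstruct_group_responses(res)
win = (grid >= 100) & (grid <= 250)
slopes = [np.polyfit(grid[win], resp["PPC"][win, c], 1)[0] for c in range(3)]
print("PPC ramp slopes (slow, mid, fast):",
      " ".join(f"{s:.4f}" for s in slopes))
```

Output (about 15 s on one CPU):

    gain         exceedance 1.000
    connection   exceedance 0.000
    null         exceedance 0.000
    VC   scaling 1.000  p (one-tailed, corrected) 1.0000
    MT   scaling 1.000  p (one-tailed, corrected) 0.7046
    PPC  scaling 1.327  p (one-tailed, corrected) 0.0007
    PPC ramp slopes (slow, mid, fast): 0.0033 0.0052 0.0077

Reading: the gain family decisively out-scores the connection and null
families (exceedance ≈ 1); only PPC shows a significant reaction-time
modulation, whose Bayesian-model-average estimate exp(β̂) ≈ 1.33 per bin
step recovers the generating ×1.35; and the reconstructed, normalised PPC
pyramidal activity ramps strictly faster for faster-RT conditions — the
signature linking response speed to parietal gain.

## Layout

    src/dcmerf/nmm.py         neural-mass sources, network, RK4 integrator
    src/dcmerf/forward.py     lead fields, spatial modes, ERF containers
    src/dcmerf/inversion.py   variational Laplace (free energy, fit, sweeps)
    src/dcmerf/comparison.py  FFX/RFX model selection, families, BMA
    src/dcmerf/pipeline.py    RT binning, statistics, study orchestration
    src/dcmerf/synth.py       behaviour + evoked-field generators, fixtures
    src/dcmerf/config.py      YAML/JSON model specs, posterior serialisation
    docs/methods.md           modelling assumptions and numerical choices
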