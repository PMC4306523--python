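# rivaldcm

Effective-connectivity analysis of bistable perception on ROI-level BOLD
time series, built as a fully synthetic, ground-truth-driven pipeline.

During bistable perception (here: a structure-from-motion sphere whose
rotation direction flips spontaneously), right-hemisphere parietal regions
and motion-sensitive visual cortex form a three-level hierarchy
r-V5 → r-pSPL → r-aSPL. This package asks, on data it generates itself, the
question such experiments ask of real fMRI: which connections change their
coupling during a perceptual switch, and do those coupling changes predict
how long a percept lasts?

The pipeline:

1. **Model space** — 64 bilinear dynamic causal models (DCMs) over the three
   regions, differing in which of the four inter-regional connections are
   modulated during switches (2⁴) and whether pSPL/aSPL receive direct
   switch input (2²), partitioned into four families (no-modulation 4,
   bottom-up 12, top-down 12, bidirectional 36).
2. **Forward model** — neural dynamics `dx/dt = (A + Σⱼ uⱼBʲ)x + Cu` with a
   balloon–Windkessel hemodynamic observation model; BOLD in percent signal
   change at TR = 2.1 s.
3. **Synthetic cohort** — subjects with gamma-distributed percept dominance
   durations (4.50 ± 0.99 s), a 2.23% mixed-percept fraction, button-press
   reaction times of 0.90 ± 0.43 s, runs of 10 trials (31.5 s stimulation /
   11 s fixation, half rivalry, half replaying an earlier rivalry sequence),
   and a built-in linear link from each subject's modulatory-coupling
   difference ΔB = B(rivalry) − B(replay) to their mean dominance duration.
4. **First-level GLM** — four regressors (fixation, stimulation,
   rivalry-switch, replay-switch) convolved with the canonical double-gamma
   HRF; switch onsets are button presses shifted earlier by the mean
   reaction time estimated from replay trials; contrast rivalry-switch >
   replay-switch.
5. **DCM inversion** — penalized Gauss–Newton (Levenberg–Marquardt) with
   Gaussian shrinkage priors and a Laplace (free-energy style) approximate
   log model evidence per subject × model.
6. **Model selection** — random-effects Bayesian model selection: Dirichlet
   posterior over model frequencies, Monte-Carlo exceedance probabilities,
   family-level inference with equal prior mass per family, and the
   two-stage winning-model rule (best family first, then its best member).
7. **Individual differences** — multiple regression of mean dominance
   duration on the winning model's four ΔB values, with single-pass Cook's
   distance (> 1) outlier exclusion, reporting R², adjusted R², F and
   standardized β.

## Worked example

```python
import numpy as np
from rivaldcm import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(
    cohort=CohortConfig(n_subjects=10, n_runs=1, trials_per_run=4,
                        rivalry_per_run=2, dt=0.3),
    out_dir="demo_run", seed=11, bms_n_samples=100_000)
manifest = run_pipeline(cfg)
print({k: v["status"] for k, v in manifest["stages"].items()})
```

prints

```
{'simulate': 'ok', 'glm': 'ok', 'invert': 'ok', 'bms': 'ok', 'regress': 'ok'}
```

and `demo_run/bms.json` then holds the selection result; for this config it
reads

```
winning_family: bidirectional      # family exceedance 0.998
winning_model:  7                  # modulation on 3 of 4 connections
```

The cohort was simulated from a bidirectional structure, and the family —
the level at which the inference is meant to be read — is recovered
decisively. The individual winning member is less stable at this reduced
problem size (one 4-trial run per subject): here it carries three of the
four generating modulations. `demo_run/regression.json` reports how well
the estimated ΔB values predict each subject's mean dominance duration —
for this run `r_squared: 0.63`, `adj_r_squared: 0.41`, one subject excluded
by Cook's distance. The same stages are available from the shell via
`rivaldcm init-config / simulate / glm / invert / bms / regress / run-all`.

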