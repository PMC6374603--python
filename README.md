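# mindtrack

Neural decoding of deceased-related attention and representation during
mindwandering fMRI tasks.

Avoidant grievers try to keep thoughts of a lost loved one out of
consciousness.  One mechanistic account holds that they continuously
monitor their own mindwandering: an attentional-control process scans for
arising mental representations of the deceased and suppresses them before
they become conscious thoughts of loss.  `mindtrack` implements the full
analysis pipeline for testing that account with fMRI:

1. **Learn spatial patterns** for two mental processes from labelled task
   data — deceased-related selective attention (**d-SA**, from
   reaction-time slowing on a grief Stroop task) and deceased-related
   mental representation (**d-MR**, from a picture/story/think
   person-processing task) — as voxel weighting matrices *W* trained by
   cross-validated MVPA within univariately selected feature masks.
2. **Track pattern expression** TR by TR during neutral
   sustained-attention (SART) tasks by projecting cleaned, standardized
   BOLD onto each *W*:  expression(t) = Σ_v w_v · bold_v(t).
3. **Model thoughts of loss**: a mixed-effects logistic regression of
   per-block thought-probe reports on the full factorial of block-wise
   d-MR expression, d-SA expression and avoidant grief style (IES-A),
   with a subject random intercept:

   logit P(thought) = β₀ + β₁·mr + β₂·sa + β₃·av + β₄·mr·sa + β₅·mr·av
   + β₆·sa·av + **β₇·mr·sa·av**

   The three-way term β₇ is the avoidance-moderated suppression
   hypothesis: at high avoidance, concurrent d-SA weakens the link
   between d-MR activation and a reported thought of loss (β₇ < 0,
   odds ratio per s.d. < 1).

Because no imaging data are distributed with the design, the package
ships a first-class synthetic-data module (`mindtrack.boldsim`) that
generates task designs, 4D BOLD with embedded ground-truth patterns,
response times, ratings, probe responses and clinical covariates from a
known generative model — so every stage of the pipeline is verifiable
end to end.  See `docs/methods.md` for the model details and declared
design choices.

## Worked example

Simulate a small high-SNR cohort and run the whole pipeline — feature
selection, per-subject pattern training, decoding of the probed SART, and
the factorial mixed model:

```python
from mindtrack import boldsim, pipeline

cohort = boldsim.simulate_cohort(boldsim.CohortParams(
    n_subjects=10, shape=(16, 16, 10), snr=2.0, seed=20260927))
result = pipeline.run_pipeline(cohort, n_perm=150, seed=0)

print(f"d-SA mask: {result.dsa_mask.n_voxels} voxels, "
      f"d-MR mask: {result.dmr_mask.n_voxels} voxels")
e = result.three_way["mr:sa:av"]
print(f"three-way B = {e.b:.3f} (se {e.se:.3f}), "
      f"OR = {e.or_value:.3f}, p = {e.p:.4f}")
```

Output:

```
d-SA mask: 170 voxels, d-MR mask: 198 voxels
three-way B = -0.706 (se 0.415), OR = 0.494, p = 0.0892
```

The masks recover the two embedded pattern supports; the decoded
block-wise expressions correlate ~0.8 with the generative latent states;
and the fitted three-way coefficient is negative, as simulated —
attenuated toward zero relative to the generative value because decoded
expressions are noisy proxies of the latent states (and, at 10 subjects,
estimated with a wide standard error).  Fitting the same model on
noise-free generative block states at 200 subjects recovers the simulated
coefficient (−2.37, OR 0.09) essentially exactly; `scripts/acceptance.py`
performs that computation.

The same machinery is available from the shell:

```bash
mindtrack simulate --seed 1 --subjects 27 --out scratch/cohort
mindtrack run --seed 1 --subjects 10 --out scratch/results
mindtrack analyze --blocks blocks.tsv --clinical clinical.tsv --split
```

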