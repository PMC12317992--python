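# activecortex

Network-ODE system identification for fMRI and Active-Cortex-Model rest/task
signal separation, with a synthetic ground-truth generator so that every
stage of the analysis is validated by parameter recovery.

## The problem

Task fMRI measures stimulus-driven activity on top of a large, structured,
ongoing background — the resting-state dynamics. Separating the two is hard
because the stimulus response is itself carried by the same network
processes. This package implements a regression-based approach:

1. **Identify a network ODE** from ROI timeseries. Each directed edge is a
   Taylor polynomial, so the derivative of region *a* is

   `dX_a/dt = λ·X_a + Σ_b Σ_{n=1..p} Ξ[a,b,n]·X_b^n`

   The coefficients Ξ are found by ridge regression of an estimated
   derivative on a polynomial library (no interaction terms), with
   sequential thresholding (STLSQ) for sparsity. The first-order diagonal is
   **not** estimated: it is fixed to a decay constant λ derived from the
   falling limb of the canonical hemodynamic response (λ ≈ −0.22 per 0.72 s
   sample), which is what lets the regression attribute the remaining
   derivative to network edges.

2. **Evaluate the model** on three criteria: held-out derivative
   prediction, similarity of the first-order coefficients to structural
   (tractography-like) connectivity, and a plausible impulse response
   (simulated HRF). A Pareto sweep over (λ, sparsity threshold) exposes the
   trade-off.

3. **Separate task signal.** With a rest model Ξ_rest and a task model
   Ξ_task, the candidate stimulus-independent background derivative is
   `(c1·Ξ_rest + c2·Ξ_task)·Θ(X)`; it is subtracted from the measured
   window derivative and re-integrated from the onset value. Named
   frameworks: rest baseline (1, 0), task baseline (0, 1), and the Active
   Cortex Model, ACM (1, −1) — remove the rest processes that are *not*
   part of the task network.

4. **Link brain to behavior**: spatiotemporal correlation of trial windows
   with reaction time, Elastic-Net RT prediction, per-trial task
   classification, per-individual task FC construction, UMAP embedding,
   SVM classification and cluster-distance analysis.

Because the real recordings this method targets are access-restricted, the
package ships a generative stand-in (`activecortex.synthetic`): stable
two-hemisphere tanh-coupled networks with positive intrahemispheric and
contralateral edges, negative other interhemispheric edges, a task
sub-network that is engaged (elevated) during task runs while off-task
processes lose structure, triangular trial inputs whose amplitude also
modulates the task-edge gain, and reaction times affinely tied to trial
amplitude. Ground truth is known, so recovery is checkable.

## Worked example

The numbered scripts under `analysis/` run the full study and write their
tables to `results/`:

```
$ python analysis/01_hrf_decay_constant.py
canonical HRF falling-limb decay rate: lambda = -0.2219 per sample (TR = 0.72 s)

$ python analysis/02_identify_network_ode.py --seed 0
recovery: order-1 correlation with truth 0.992, 100% of negative interhemispheric
edges recovered with negative sign, held-out derivative median r 0.355
derivative FC mean |off-diagonal|: measured 0.016, network 0.091, residual 0.011
pareto sweep: best dynamics at lambda=-0.22 (adjusted R^2 0.125); 10/20 rows meet
the operating rule

$ python analysis/03_separate_task_signal.py --seed 0
unseparated: max |corr(RT)| 0.623, Elastic Net R^2 0.415
acm            delta max corr +0.0372, delta R^2 +0.0079
rest_baseline  delta max corr -0.0422, delta R^2 +0.0047
task_baseline  delta max corr -0.1407, delta R^2 -0.0178
c1/c2 sweep maxima on the c1=-c2 diagonal: 100% of replicates

$ python analysis/04_fc_embedding.py --seed 0
embedded-space SVM accuracy: unseparated 0.65 -> ACM 0.90
between/within cluster distance ratio: unseparated 1.07 -> ACM 2.04
```

Reading these numbers: the decay constraint fitted from the canonical HRF
(−0.222) matches the value used throughout; a 20,000-sample rest run
recovers the true first-order network almost perfectly (r = 0.992) with the
negative interhemispheric sign structure intact; the adjusted R² of the fit
peaks at the true decay rate; only the ACM framework *increases* the
maximum spatiotemporal correlation between separated windows and reaction
time (+0.037), while subtracting the full rest or task model decreases it;
the (c1, c2) sweep maxima fall on the c1 = −c2 diagonal (scaled versions of
the ACM); and after ACM separation, per-individual task FCs of two
overlapping tasks become markedly more separable (SVM 0.65 → 0.90, cluster
distance ratio 1.07 → 2.04).

A seeded end-to-end experiment (simulate → fit → separate → behavior, with
a content-hash manifest) is also available through the CLI:

```
activecortex run --config src/activecortex/configs/acm-demo.yaml
```

## Layout

```
src/activecortex/   io, synthetic, sysid, evaluation, separation,
                    behavior, fc_embed, studies, pipeline (CLI)
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     model, assumptions, parameter choices, limitations
```
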