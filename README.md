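# ictonet

Peri-ictal functional-network inference and **brain network ictogenicity
(BNI)** modelling for intracranial EEG, with in-silico resection and
surgical-outcome statistics.

`ictonet` is aimed at researchers studying epilepsy surgery through the lens
of network dynamics. Starting from multichannel peri-ictal recordings (a few
minutes of pre-ictal activity, a seizure, a few minutes of post-ictal
activity), it:

1. **infers functional connectivity (FC)** per 8 s segment using
   surrogate-corrected zero-lag Pearson correlation (or the nonlinear h²
   index), with IAAFT surrogates providing the null and a Holm-corrected
   one-sided Mann–Whitney U test providing the significance mask;
2. **quantifies each FC network's propensity to seize** by placing a noisy
   theta neuron on every node and measuring the fraction of time nodes spend
   in the spiking ("seizure") state, integrated over a coupling interval;
3. **models surgical resection** by deleting the resected nodes from the
   network and measuring the relative drop in ictogenicity (ΔBNI) from a
   reference state calibrated to BNI_pre = 0.5;
4. **runs the cohort statistics** that link *elevated ictal BNI* to
   surgical-outcome prediction: Kruskal–Wallis epoch comparison, per-subject
   one-tailed elevation tests, a permutation chi-square against outcome, and
   ROC/AUC of ΔBNI with exhaustive half-group-split comparison.

A ground-truthed synthetic cohort generator (switched vector autoregression
with a designated ictogenic core) makes the entire pipeline testable without
clinical data.

## The model

Each FC node is a theta neuron with phase θ_j:

```
dθ_j/dt = (1 − cos θ_j) + (1 + cos θ_j) · I_j(t)
I_j(t)  = I0_j + ξ_j(t) + (K/N) Σ_{i≠j} a_ij [1 − cos(θ_i − θ_i^s)]
```

where `a_ij` are the surrogate-corrected FC weights, K is a global coupling,
ξ is Gaussian noise and θ_i^s = −arccos((1+I0)/(1−I0)) is the rest state.
For I0 < 0 the node is excitable; spiking emerges via a SNIC bifurcation at
I0 = 0. **BNI\*(K)** is the average fraction of time nodes spend in the
seizure state (a spike within a trailing window); **BNI = ∫ BNI\*(K) dK**
over a fixed interval [K1, K2] removes the dependence on a single K. A
virtual resection of node set n_s reports

```
ΔBNI^ns = (BNI_pre − BNI_post^ns) / BNI_pre,   BNI_pre calibrated to 0.5.
```

## Worked example

```python
import ictonet as ic
from ictonet.pipeline import RunConfig, run_subject

# a small synthetic responder subject: its ictogenic core couples 2.5x
# more strongly during the seizure, and the resection mask covers the core
spec = ic.SyntheticSpec(n_subjects=2, n_channels=10, n_core=4,
                        pre_s=45.0, post_s=45.0, ictal_range_s=(36.0, 45.0),
                        seed=11)
subject = ic.generate_cohort(spec)[0]

config = RunConfig(profile="test", seed=1, n_k=9)
result = run_subject(config, subject.recordings,
                     subject.ground_truth.resection_mask,
                     subject_id="sub00", engel_class="I")
print("elevated per epoch:", result.record.elevated_flags,
      "p-values:", [round(p, 4) for p in result.epoch_pvalues])
print("K interval:", tuple(round(k, 1) for k in result.k_interval))
print("K_ref:", result.k_ref, "BNI_pre:", round(result.calibration_achieved, 3))
print("DeltaBNI:", round(result.record.delta_bni, 3))
```

Output from this exact run:

```
elevated per epoch: (True, True) p-values: [0.0003, 0.0003]
K interval: (0.0, 252.0)
K_ref: 17.0 BNI_pre: 0.507
DeltaBNI: 0.991
```

Ictal BNI is significantly elevated over pre-ictal BNI in both peri-ictal
epochs (p ≈ 3·10⁻⁴ each), so this subject's FC is judged to represent its
ictogenic network; removing the resected nodes then suppresses essentially
all model seizure activity (ΔBNI ≈ 0.99), the model's prediction of a good
surgical outcome. A subject whose mask misses the core yields ΔBNI near or
below zero.

The same analysis is scriptable from the shell: `ictonet synth`,
`ictonet preprocess`, `ictonet fc`, `ictonet bni`, `ictonet resect`,
`ictonet stats` and `ictonet run` (see `ictonet --help`).

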