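# Methods

This note documents the models, parameter choices and numerical decisions
behind `ictonet`, in the spirit of the methods documentation of simulation
and statistics packages.

## Preprocessing

Recordings are down-sampled to 512 Hz (polyphase resampling with built-in
anti-aliasing), re-referenced against the **per-sample cross-channel
median**, band-pass filtered 0.5–120 Hz (4th-order Butterworth) and
notch-filtered 48–52 Hz (2nd-order Butterworth band-stop). Both filters are
applied forward–backward (`sosfiltfilt`), so they are zero-phase — important
because the FC measure downstream is zero-lag correlation, which phase
distortion would bias.

Two interpretations of the median reference were possible (median over
channels vs over time); we use the cross-channel per-sample median, which
removes common-mode activity at every instant, and expose an optional
channel-exclusion list in place of manual artifact marking (automatic
artifact rejection is out of scope).

Each peri-ictal epoch (pre-ictal, ictal, post-ictal) is cut independently
into 8 s segments whose starts are 9 s apart (1 s gaps); windows that would
cross an epoch boundary are dropped, so every segment carries one epoch
label. Each segment is further cut into ten 2 s subsegments whose starts are
uniformly spaced over [0, 6] s — the unique uniform layout minimizing the
maximum pairwise overlap — with fractional starts rounded to the sample
grid for bit-reproducibility.

## Functional connectivity

For every segment we draw 10 **IAAFT surrogates** per channel
(independently per channel, which destroys all cross-channel coupling while
preserving each channel's amplitude distribution exactly and its power
spectrum approximately). The subsegment grid applied to the original data
and to each surrogate yields 10 original and 100 surrogate association
values per channel pair. Associations are |Pearson| at zero lag by default;
the nonlinear h² index (variance explained by a piecewise-linear curve
through per-bin means over 10 equal-count bins, symmetrized by the maximum
over both regression directions, zero lag) is available as a robustness
alternative.

A one-sided Mann–Whitney U test per pair (original associations
stochastically **larger** than surrogate associations) with Bonferroni–Holm
correction over all N(N−1)/2 pairs gives the significance mask s. One-sided
testing is deliberate: only an excess of association over the null is
evidence of coupling, and two-sided rejections with ρ0 < ρsurr would
produce negative weights. The corrected weights are

    C_ij = max(0, (ρ0 − ρsurr) / (1 − ρsurr)) · s_ij      (Pearson)
    H_ij = h²_ij · s_ij                                    (h²)

with ρ0 and ρsurr the per-pair **medians** of the 10 and 100 ensemble
values (a robust summary consistent with the rank-based test; whether the
original protocol used means or medians is not determinable, and the choice
is inconsequential for rank statistics downstream). Negative corrected
values are clipped to zero — the weights feed a dynamical model in which
coupling is nonnegative. The U test uses the exact null distribution when
n + m ≤ 25 and there are no ties, and the tie-corrected normal
approximation otherwise.

**IAAFT stopping.** Iteration stops per surrogate when the rank ordering is
unchanged between iterations, when the amplitude-spectrum discrepancy stops
improving (relative improvement < 1%), or after 100 iterations. The second
criterion matters in practice: for broadband signals the rank ordering
keeps shuffling indefinitely while the spectrum error plateaus (measured
~0.25% relative L2, far below the 5% validity bound) by iteration ~15–20.

## Theta-network ictogenicity

Node dynamics and the input current are integrated with Euler–Maruyama
(noise enters with √dt scaling, multiplied by the (1 + cos θ) sensitivity
factor, matching the ODE's input pathway). Defaults: homogeneous
excitability I0 = −1.2 (each node rests a finite distance below the SNIC
bifurcation), noise_sd = 0.6 (rare noise-driven escapes when uncoupled:
baseline BNI* ≈ 4·10⁻⁴), dt = 0.01. These values are exposed in
`ThetaParams`; comparisons between networks are only meaningful at fixed
model parameters, which the pipeline enforces by construction. The step
count defaults to the full protocol length 4×10⁶; the `test` profile uses
2×10⁵ steps for desk-scale runs.

A spike is an upward crossing of θ = π (phases wrapped to (−π, π]). A node
is *in the seizure state* at time t iff it spiked within the trailing
window w = 3π/√0.5 ≈ 13.3 time units — three spiking periods at moderate
drive, so sustained spiking maps to contiguous seizure-state time while an
isolated escape contributes only one window. The first 10% of steps are
discarded as burn-in. BNI*(K) is the node-averaged seizure-state fraction.
For speed, the simulation kernel (numba) evaluates cos/sin via an
8192-entry linearly interpolated table (error ~3·10⁻⁸, far below the Euler
discretization error; the measured drift of the noise-free spiking period
against the closed form π/√I0 is ~10⁻⁴ at dt = 0.01).

**Coupling grid and [K1, K2].** BNI*(K) is evaluated on a grid of 0 plus a
geometric ladder (default 21 points to K_max = 512; the test profile uses
11), which resolves the sigmoidal transition at whatever weight scale the
FC matrices have. K1 = 0; K2 is 1.2× the largest per-curve saturation
coupling (smallest grid K with BNI* ≥ 0.95) across all of a subject's
segments, then held fixed for that subject. Curves that never reach 0.95
have ceilings below it (isolated nodes stay quiescent at any K) and
contribute the grid maximum instead; only if *no* curve saturates is the
scan declared too narrow. Fixing [K1, K2] per subject (rather than
globally) is the default; BNI is integrated by the trapezoid rule, with the
saturated tail extended at its final value where K2 exceeds the grid.

Per-epoch BNI timecourses are normalized by the maximum over the whole
peri-ictal epoch, and the ictal run is linearly interpolated onto 10
equally spaced normalized-time points so seizures of different durations
align. Note a consequence of resampling: if the epoch maximum falls between
interpolation points, the normalized maximum can sit marginally below 1.

**Calibration and virtual resection.** The reference coupling K_ref is
found by bisection until BNI*(K_ref) averages to the target 0.5 within
tolerance (each evaluation averages ≥3 fresh noise realizations). Because
the transition is steep (~0.01 per unit K on the reference network), the
bracket is additionally narrowed to 0.5% of its initial width before a
solution is accepted; otherwise an early lucky evaluation can return a K
whose true BNI* sits a noise-width from 0.5. Resection deletes the rows and
columns of the resected node set; the 1/N prefactor uses the reduced node
count (N is the size of the simulated network). ΔBNI is computed on the FC
averaged over segments in the first half of the ictal period — the portion
of the seizure whose connectivity best reflects the ictogenic tissue —
using the same theta model and K_ref.

## Cohort statistics

Group comparison pools the normalized per-segment BNI values of all
subjects and epochs into pre-ictal/ictal/post-ictal groups (Kruskal–Wallis
with tie correction). A subject is flagged *elevated-ictal* iff the
one-tailed U test (ictal > pre-ictal) is significant at α = 0.05 in **both**
peri-ictal epochs independently; the pre-ictal group is the epoch's
pre-ictal segment values and the ictal group is the 10 normalized ictal
values. The elevated × outcome association (outcome dichotomized Engel I–II
good vs III–IV poor, matching the ROC labels; a 2×4 variant over Engel
classes would also be possible but fragments the margins at cohort sizes of
16) is tested by permutation: the plain Pearson chi-square of the 2×2 table
against 10,000 random reassignments of the elevated labels, with the
add-one correction p = (1 + #{null ≥ obs})/(n_perm + 1) so p is never 0.
Note the permutation p is *super-uniform* under the null — the 2×2 statistic
is discrete, so E[p] > 0.5 — which the tests check explicitly.

AUC is computed as the Mann–Whitney probability P(score_good > score_poor)
+ ½P(tie). "All possible half-group splits" is read as: every subset of
size ⌊n/2⌋ whose label composition retains both classes contributes one
AUC; the two groups' AUC distributions are compared with a two-sided U
test. This is the only reading under which exhaustive splitting yields a
distribution of well-defined AUC values.

## Synthetic cohorts

The generator emulates the *structure* of a peri-ictal iEEG cohort, not its
biophysics. Each subject is a switched first-order vector autoregression
x(t+1) = A_e x(t) + ε with symmetric epoch-dependent coupling operator A_e:
autoregressive diagonal 0.5, couplings 0.15 on a random background graph
(edge density 0.2), a fully interconnected 5-node ictogenic core, and —
for "responder" subjects (default half the cohort) — core–core couplings
multiplied by β = 2.5 during the ictal epoch. One rescaling factor **shared
across a subject's epochs** keeps every operator's spectral radius below
0.95: per-epoch rescaling would shrink the boosted ictal operator more than
the pre-ictal one and silently invert the planted effect, whereas the
shared factor preserves the β ratio and places responders' ictal operator
at the stability cap, where the dominant core mode produces the sharp rise
in intra-core correlation (measured: mean core |ρ| ≈ 0.09 pre-ictal vs
≈ 0.59 ictal at the defaults). The VAR is simulated exactly by modal AR(1)
filtering (the operator is symmetric), with state carried continuously
across epoch switches and a 1 s burn-in.

Defaults mirror the cohort conditions the pipeline targets: 16 subjects,
two peri-ictal epochs each, 20 channels at 512 Hz, 180 s pre- and
post-ictal epochs, ictal duration uniform on [60, 120] s (so the 10-point
ictal resampling is exercised with varying segment counts). Resection masks
either cover the core exactly (good outcome, Engel I–II) or are drawn from
non-core channels (poor outcome, Engel III–IV).

What the generator does **not** emulate: 1/f spectra, interictal spikes,
artifacts, volume conduction, electrode geometry, nonstationarity within
epochs. Passing tests therefore demonstrate that the pipeline recovers
planted epoch-dependent coupling structure and core identity under
realistic statistical conditions — not that it is robust to every artifact
of clinical iEEG.

## Test problem sizes

The end-to-end recovery tests run the full pipeline at reduced problem
sizes chosen to keep the suite at desk scale while leaving every threshold,
effect size and α untouched: two cohorts of 8 subjects (4 responders), 10
channels, 27 s pre/post epochs, 27–36 s seizures, the 2×10⁵-step test
profile and a 7-point coupling grid; outcome-prediction surfaces use the
same runs plus 20 paired core-vs-peripheral resection replicates on direct
12-node networks. The group-level Kruskal–Wallis, responder-vs-flagged
Fisher, and ΔBNI AUC = 1 criteria must hold in every seeded cohort. The
acceptance script's calibration target uses a 20-node network with the test
profile, an internal bisection tolerance of 0.03 (tighter than the 0.05
verification band, leaving margin for fresh-noise re-evaluation) and 5
noise realizations per bisection evaluation.

## Known limitations

- The h² path is substantially slower than Pearson and is exercised at
  unit-test scale only.
- [K1, K2] selection depends on the scanned grid's ceiling; pathological FC
  scales outside [~10⁻³, 512] of coupling would need a wider `k_max`.
- ΔBNI for subjects with empty first-half-ictal FC cannot be calibrated
  (the network is silent at every K); the pipeline records it as missing
  and warns rather than failing the subject.
- Engel scoring, MRI-based identification of resected electrodes, and
  lagged/directed connectivity measures are out of scope; resection masks
  and outcome labels are inputs.
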