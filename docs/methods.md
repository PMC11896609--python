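# Methods

## Overview

`alsim` models the *Drosophila* antennal lobe (AL) as a network of
single-compartment leaky integrate-and-fire (LIF) neurons whose synaptic
weights come from a connectome-style synapse-count matrix, and asks how
developmental stochasticity in circuit composition shapes individuality in
projection-neuron (PN) odor codes.  Around the simulator sit the analyses
that give the question meaning: a canonical-computation battery that
validates the tuned model, generators of idiosyncratic circuits
(population bootstrapping and synapse-density resampling), population PCA
with a glomerular-organization index, preference-model application and
decoding, and a simulation-based estimator of the latent calcium–behavior
correlation that corrects observed model R² for measurement repeatability.

## Voltage model

Below threshold, each neuron obeys

    C_i dV_i/dt = (V_{i,0} − V_i)/R_i + I_odor,i(t) + Σ_j a_i W_ji I_j(t)

with per-class electrophysiology (resting potential, threshold, AP
min/max/duration, capacitance, resistance) taken from published
measurements; ORNs share the PN capacitance.  Units are mV/ms/pF/GΩ/pA, so
R·C is in ms (PN membrane time constant 0.3 GΩ × 73 pF = 21.9 ms).
Integration is forward Euler at dt = 0.1 ms.  On threshold crossing a
templated action potential is written into the voltage trace — piecewise
linear from threshold to AP max over the first half of the AP duration,
then down to AP min — during which integration is suspended; the template
therefore acts as an absolute refractory period, and integration resumes
from AP min.  The spiking neuron's output current jumps by one unit and
decays exponentially with τ_syn = 2 ms; downstream neurons receive it
scaled by the effective weight, starting the step after the spike.  The AP
and PSC waveform shapes and τ_syn are package defaults (config-exposed),
not measured quantities; only the template endpoints are constrained by the
electrophysiology table.  The one-unit PSC amplitude trades off exactly
against the sensitivity multipliers below, which is why it is fixed.

Weights: `effective_weights[j, i] = polarity(j) · W_ji · a_class(i)`, where
W_ji is the synapse count and the postsynaptic class multipliers are the
hand-tuned working point a_ORN, a_eLN, a_iLN, a_PN = 0.1, 0.04, 0.02, 0.4.
Inhibitory rows (GABAergic PNs, iLNs) are negative; the sparsity pattern of
the effective matrix equals that of the counts.

## ORN drive

An ORN of glomerulus g under odor o fires as an inhomogeneous Poisson
process at FR = FR_max · D[g,o] · (f_a + (1−f_a)·exp(−t/t_a)) with
FR_max = 400 Hz, f_a = 0.75, t_a = 110 ms, so the evoked rate adapts from
400·D to 300·D Hz.  Off odor — and for glomeruli with D = 0 — ORNs fire
homogeneously at 10 Hz.  The evoked process *replaces* the spontaneous one
during odor presentation for responsive glomeruli (the two are not summed;
this avoids double counting while preserving the 10 Hz odor-free rate).
Spikes are sampled by per-step Bernoulli thinning (p = rate·dt) and forced
in the simulator by a 10⁶ pA one-step kick current, which reliably
triggers the AP template regardless of synaptic input.  A kick landing
inside an ongoing template is swallowed; at 10 Hz and a 2 ms template this
thins the emitted spontaneous rate to 10/(1 + 10·0.002) ≈ 9.8 Hz, which is
what the odor-free calibration checks measure against.

Missing response-matrix entries are completed by alternating-least-squares
low-rank infill from random starts, averaging the infilled matrix over
repeats (default 1000) and clamping to [0, 1]; observed entries are never
altered.  The per-repeat rank keeps components explaining 75% of variance
and iterations stop at a 1e-6 relative change (200 max).  Rank rule and
tolerance are package choices; the averaging-over-repeats design follows
the observation that the mean infill tracks ground truth better than a
single run.

## Circuit construction rules

Non-olfactory glomeruli (VP1d, VP1l, VP1m, VP2, VP3, VP4, VP5) are dropped
on load.  ORNs are excitatory.  LN polarity: the eLN count is
round-half-up of n_LN/(1 + 5.4) (197 LNs → 31 eLNs); because eLNs
innervate broadly, they are drawn uniformly at random from the top half of
LNs ranked by innervated-glomerulus count (≥ 1 synapse in either direction
with any glomerulus-labeled neuron; ties broken by id; ceiling(n/2)
candidates for odd pools).  PN polarity: annotated PNs keep their
transmitter; unannotated mPNs (resp. uPNs) are drawn excitatory with
probability equal to the cholinergic fraction among annotated mPNs (resp.
uPNs), once per roster, and serialized with it so reloading never
re-randomizes.

## Idiosyncrasy generators

*Bootstrapping*: ORNs (and uPNs) are resampled with replacement within
each glomerulus pool, preserving pool sizes; all LNs form a single pool.
A sampled neuron keeps its original synapse rows/columns, so duplicates
are distinct instances with identical connectivity and no new neuron pair
is ever connected.  Multiglomerular PNs are left fixed during PN
bootstrapping (they have no single glomerulus pool).

*Synapse-density resampling*: per glomerulus, a target PN-input total is
drawn from the log-normal power law log S_g = log(a·V_g^d) + ε,
ε ~ N(0, σ²), and every synapse onto that glomerulus's PNs (any
presynaptic class) is multiplied by one scalar to hit the target; weights
become real-valued (no re-rounding — the operation is a scalar rescale).
The reference fit for the hemibrain relationship is (a, d, σ) =
(8.98, 0.73, 0.38); fitting is OLS of log S on log V with the biased
(divisor-n) MLE of σ, which the fitter reproduces exactly.  When a
population experiment resamples the synthetic fixture, the model is first
refit from the fixture's own (volume, PN-input) pairs so the resampled
totals are statistically matched to their source.  Combined modes apply
bootstrap first, then density rescaling.

## Validation battery and sensitivity

The tuned model must reproduce four canonical AL computations on its odor
panel: (1) class firing rates in literature ranges (config defaults: ORN
baseline 5–20 Hz, mean odor-evoked PN 10–200 Hz — the electrophysiology
table constrains membrane parameters, not target rates, so these are
config values), (2) PN odor-evoked rates more uniform than ORN rates,
operationalized as a lower Gini coefficient, (3) larger mean pairwise
Euclidean distance between unit-normalized per-odor population vectors for
PNs than ORNs, and (4) a sublinear transfer, measured as the OLS slope of
log(PN+1) on log(ORN+1) over glomerulus-odor pairs.  The uniformity and
separation statistics are package operationalizations of comparative
claims; their direction, not magnitude, is the reproducible content.
Robustness is scored by Cohen's d — (mean manipulated − mean baseline)
PN response over pooled SD — for single multipliers scaled 1/4× to 4× and
for joint manipulations with independent log-normal factors (σ_log = ln 2,
so ±1 SD spans 0.5×–2×), all runs sharing the baseline's seed policy.

## Population analysis

Trial tables are mean-imputed per feature and averaged within individual;
PCA is by SVD of the mean-centered matrix with a deterministic sign
convention (largest-|loading| feature positive).  The glomerular
organization index of PC k with loadings l_(g,o) is the between-glomerulus
share of loading energy, GOI_k = Σ_g n_g·(mean_o l_(g,o))² / Σ l², i.e. 1
when loadings are constant within glomeruli and ≈ 1/n_odors for unstructured
loadings; the reported index averages the top K = 5 PCs weighted by
variance fraction.  Linear preference models are applied as
β₀ + β₁·score; the shipped PN-PC2 OCT-vs-MCH model is
(β₀, β₁) = (−0.058, −0.081).  Simulated ALs are labeled OCT- vs
MCH-preferring by median split of predicted preference (balanced and
intercept-invariant; the thresholding rule is a package choice), with the
PC predictor defined by a fixed loading vector — by default the fixture's
specialist-glomerulus contrast (+G03 −G04 across odors), standing in for
an empirically fitted component.  Decoding uses scikit-learn linear
logistic regression under twofold cross-validation (train on one stratified
half, test on the other, then reverse; fold sizes differ by ≤ 1), compared
against a shuffled-label null.  Within/across-individual distances average
the left–left, right–right and left–right mean pairwise distances of
response projections per individual.

## Latent-correlation inference

Observed calcium–behavior model R² is attenuated by measurement noise.
The forward model draws latent X_c ~ N(0,1)^N, sets
X_b = r·X_c + √(1−r²)·Z, and generates noisy readouts by the same mixing
with r_c = (R²_c,c)^¼ and r_b = (R²_b,b)^¼ (so two readouts of the same
latent correlate at the measured test–retest R²); the simulated observed
statistic is corr(X_c′, X_b′)², whose mean correlation obeys the
attenuation identity r·r_c·r_b.  Calcium repeatability R²_c,c is the
summed variance fraction of leading PCs whose eigenvalue exceeds the
rank-matched mean eigenvalue of within-individual-shuffled data,
bootstrapped over individuals; behavior repeatability is the squared
test–retest correlation, also bootstrapped.  Inversion simulates the
forward model on an r_latent grid (step 0.01, default 10,000 simulations
per point, bootstrap draws of (r_c, r_b) paired to simulations by index
cycling), bins the simulated observed R², and for each observed draw
accumulates the normalized likelihood over grid points (equal prior weight
per point).  Quantiles of the r_latent posterior are squared to give
R²_latent (quantile matching P(r_latent ≤ q) = P(R²_latent ≤ q²)); the
median and 5th–95th quantiles are reported.  The estimator is validated by
parameter recovery on synthetic paired datasets, not by reproducing any
empirical value.

## The synthetic fixture

All experiments run on generated data; nothing is downloaded.  The
reference circuit has 8 glomeruli × (5 ORNs + 2 uPNs), 4 mPNs and 20 LNs
(3 eLNs at the 1:5.4 ratio), with ORN→uPN edges confined to glomerulus
blocks, LNs innervating 4–8 glomeruli (receiving ORN/uPN input there and
inhibiting or exciting the local uPNs), and per-glomerulus PN-input totals
drawn from the (8.98, 0.73, 0.38) volume–synapse law at log-uniform
volumes.  The 4-odor response matrix has a generalist/specialist
structure: two glomeruli respond strongly (D ≈ 0.75–1.0) to every odor,
one moderately tuned specialist (D ≈ 0.3–0.5) marks each odor, and the
rest are silent.  The wiring scales (volume range 7·10⁴–1.5·10⁵ µm³, ORN
share 0.95 of PN input, ORN→LN ≈ 600 synapses/edge) were calibrated once,
jointly with this odor-code structure, so that the canonical battery holds
at the standard sensitivities — the analog of hand-tuning the full-scale
model — and then frozen.  The operating point places PNs in a
high-convergence regime where weak input already drives firing and strong
input runs into the refractory ceiling, which is what produces the
uniformity, separation and sublinearity of criteria (2)–(4).  Volumes at
the top of (and slightly above) the biological range are the price of
getting hemibrain-like per-PN convergence out of only five ORNs per
glomerulus.

Paired calcium/behavior datasets embed a per-individual observed calcium
state (mixed from the latent at r_c) along a fixed random unit loading
over glomerulus-odor features, plus isotropic trial noise whose SD is
calibrated by bisection against the PCA-repeatability estimator itself;
behavior is measured twice at r_b.  What the generator does *not* emulate:
odor-dependent noise correlations, hemispheric asymmetry, missing-trial
structure beyond uniform missingness, or any nonlinearity in the
calcium-behavior link — so passing tests show estimator correctness under
the model's own assumptions, not robustness to their violation.

## Problem sizes and numerical choices

Default experiment sizes keep the full pipeline comfortably interactive:
populations of 100 idiosyncratic ALs per variation mode (each a 2.8 s
simulated panel at dt = 0.1 ms over ~120 neurons), 20 replicate paired
datasets at N = 69 individuals, 2000 inversion simulations per grid point
in the recovery study (the 10,000 default is used when precision matters
more than turnaround).  GOI uncertainty is the SD over 50 bootstrap
resamples of individuals.  Degenerate inputs fail loudly: all-zero rate
vectors, fully missing rows/columns, unassigned polarities, zero-length
windows, rate·dt ≥ 1, and non-finite voltages all raise with the offending
neuron/feature named.  Ties in LN ranking break by id; PCA signs follow
the largest-loading convention; the half-open [start, end) window counts
spikes.

## Known limitations

The simulator omits conductance-based synapses, morphology, plasticity and
neuromodulation.  LN firing is more heterogeneous than in real recordings
(no homeostasis), and some PN off-odor rates are high — both mirror known
deviations of this model class.  The fixture is a caricature tuned to
reproduce comparative, not absolute, statistics; absolute rates and
loadings should not be compared to physiology.  The latent-correlation
module reproduces a procedure and its calibration, and cannot be checked
against empirical posterior values without the original recordings'
bootstrap distributions.
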