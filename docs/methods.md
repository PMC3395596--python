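# Methods

## The model

`alnet` simulates the locust antennal lobe (AL) as a conductance-based
spiking network of three cell classes: 300 projection neurons (PNs), 100
inhibitory local interneurons (LNs) and 50 excitatory local interneurons
(eLNs). PNs and eLNs share one single-compartment Hodgkin–Huxley-type
membrane (transient Na, delayed-rectifier K, transient A-type K, leak);
under DC stimulation they fire overshooting Na spikes at a fixed rate
(inter-spike-interval CV < 0.001). LNs have no fast Na current; they carry
a low-threshold Ca current, a Ca-dependent K current fed by a first-order
intracellular Ca pool, a delayed-rectifier K current and leak, and fire
low-amplitude Ca spikes (peaks below 0 mV) with pronounced spike-frequency
adaptation.

Channel kinetics are not uniquely fixed by the model family, so the
kinetic forms are assembled from the standard lineage:
Traub–Miles Na/K rates (threshold offset V_T = −55 mV) and Huguenard-type
A-current kinetics for the excitatory cells; for the LN, a
Morris–Lecar-style regenerative pair (fast Ca activation at −35 mV with
slow, weak inactivation; a squared sigmoidal K recovery gate at −25 mV,
τ ≈ 6 ms) plus the Ca pool (τ = 1000 ms) driving the adaptation current
through a Hill-type gate (half-activation at [Ca] = 2, τ_q = 50 ms). Every
constant lives in `src/alnet/params/cells.json` and is validated on load;
swapping a parameterization requires no code change.

**Units and cell size.** Voltages in mV, time in ms, conductances in µS,
currents in nA, capacitance in µF. The cell surface is chosen small
(C ≈ 9.5 nF·10⁻³, leak 0.0014 µS, rheobase ≈ 0.023 nA) so that per-cell
synaptic conductance totals in the 0.0002–0.001 µS range — the range the
study sweeps — are dynamically significant. Scaling all membrane
conductances, the capacitance and the input currents by a common factor
leaves single-cell voltage trajectories exactly unchanged, so this choice
only fixes the meaning of the absolute synaptic conductance scale.

**Integration.** Fixed-step integration at dt = 0.04 ms: Rush–Larsen
(exponential) updates for gating variables and an exponential-Euler update
for the voltage in conductance form. The accuracy contract is
step-halving convergence: halving dt from 0.04 to 0.02 ms moves the spike
times of a 1 s tonic PN trace by less than 1 ms. In the network kernel the
gate steady states and relaxation factors are tabulated on a 0.05 mV
voltage grid (built from the same rate functions as the single-cell path)
and linearly interpolated.

## Synapses and wiring

Fast synapses (nicotinic ACh and GABA_A) follow a first-order activation
scheme: a gating variable s relaxes toward α/(α+β) while the presynaptic
voltage exceeds −20 mV and decays with rate β otherwise; the conductance is
g_max·s. ACh: α = 2/ms, β = 0.05/ms, E = 0 mV; GABA_A: α = 1/ms,
β = 0.16/ms, E = −75 mV. Slow GABA_B inhibition uses a two-stage scheme —
transmitter-bound receptor r (K1 = 0.09, K2 = 0.0012 ms⁻¹) activates a
G-protein pool s (K3 = 0.18, K4 = 0.034 ms⁻¹) — with a saturating Hill-4
conductance g_max·s⁴/(s⁴+100). Following one presynaptic burst the GABA_B
conductance peaks hundreds of milliseconds later and decays with a
half-time above 100 ms, so it integrates LN activity over the timescale of
an odor presentation.

Wiring is Bernoulli per ordered pair: PN→LN 0.5, PN→eLN 0.5, eLN→PN 0.1,
eLN→LN 0.5, LN→PN 0.5, LN→LN 0.5, LN→eLN 0.5; no self-connections, no
eLN→eLN pathway. Per-synapse maxima are the pathway's per-cell total
divided by the target's in-degree, so per-cell drive is invariant to
population size and connection probability. The two swept totals are
`g_exc` (eLN-mediated lateral excitation per cell) and `g_slow` (GABA_B
per PN; GABA_B uses the LN→PN adjacency). The fixed totals
`g_ach` = 0.0075 µS and `g_fast` = 0.002 µS are calibration constants,
fixed once against the target network phenomenology —
roughly 12–17 % of PNs respond without lateral excitation, g_exc = 0.001 µS
with g_slow = 0 recruits > 90 % of the network, and raising g_slow curtails
that recruitment — and then frozen.

## Stimuli

An odor is a Gaussian intensity profile over the ring coordinate
x ∈ [−1, 1) (σ = 0.15, truncated to 0 below 0.1 of peak, wrapping
circularly), delivered as a current pulse: exponential rise τ = 100 ms
from onset at 500 ms, exponential decay τ = 200 ms after 1500 ms, in a
3000 ms trial. Odor identity is the profile center measured in units of
one PN index step on the 300-PN ring (maximum possible shift: 150 units);
the default panel holds 21 odors at 5-unit steps. Similar odors are
shifted by 5 units, dissimilar by 40.

The σ and the peak current are free calibration constants of the model.
σ = 0.15 puts ≈ 90–100 PNs above the truncation floor. The peak current
(0.035 nA ≈ 1.5 × rheobase) was calibrated so that, with no lateral
pathways, the most strongly driven PNs fire ~40 spikes/s during the
plateau while most responsive PNs fire 10–30 — large enough that 50 ms
PSTH bins carry usable counts for the correlation analyses, small enough
that only ~1/6 of the ring responds directly.

LNs receive the same profile scaled to 0.7; eLNs receive a *narrow*
version of the PN profile (σ scaled by the eLN/PN population ratio,
50/300). This width scaling matters mechanistically: with a narrow eLN
profile a 5-unit odor shift displaces the eLN activation pattern by a
large fraction of its width, so lateral excitation recruits measurably
different PN subsets for similar odors — the amplification of small input
differences that drives decorrelation. Input noise is an
Ornstein–Uhlenbeck process per neuron (correlation time 20 ms) with
standard deviation 10 % of the stimulus peak — the upper end of the
model's 5–10 % design band; at lower noise the unbalanced high-excitation
regime remains classifiable and the reliability cost of excitation is not
expressed.

## Analysis conventions

* PSTH: 50 ms bins, 25 ms hop, origin at t = 0 — 120 bins per 3000 ms
  trial; a spike is counted in every bin whose window covers it (≤ 2).
  Time averages use the bins whose windows intersect the stated interval,
  so "stimulus" averages cover bins 19–59.
* Correlation: uncentered cosine between population count vectors; two
  all-zero vectors correlate at 1 (shared silence), a zero against a
  nonzero vector at 0. Before stimulus onset the network is silent, so
  correlation series begin near 1 and fall as responses individuate
  (pre-odor population vectors are zero-dominated, so they correlate
  highly).
* C_trials: per-bin cosine averaged over the 45 unordered trial pairs of
  one odor, then over stimulus bins. C_odors: the same estimator applied
  across odors (all cross-odor single-trial pairs). Using one estimator
  for both makes M = C_trials + (1 − C_odors) comparable across cells;
  computing C_odors from trial-averaged PSTHs instead would suppress noise
  asymmetrically and bias M.
* Response complexity: per PN and trial, the 21-odor × 20-bin response
  array (non-overlapping 50 ms bins over the stimulus) is mean-centered
  across time and the number of principal components reaching 80 % of the
  variance is counted; zero-variance (static) responses are assigned 0.
  300 PNs × 10 trials give 3000 values per grid cell.
* Classification: distance d_ij = 1 − c_ij between single-trial
  responses; agglomerative clustering (single linkage by default; average
  and complete are selectable) cut at two clusters; errors counted under
  both cluster↔odor assignments and the minimum kept, so the error
  proportion is at most 0.5 (chance).

## Synthetic data and what passing tests show

All inputs are synthetic by design — the study itself uses no external
data. The stimulus module additionally provides inhomogeneous-Poisson
surrogate rasters (rate ∝ profile × envelope) used to exercise the
analysis and classification stages without simulation. Surrogates capture
rate-coded spatial tuning and Poisson count noise but none of the network
dynamics (no temporal patterning, no correlations between neurons), so
tests that pass on surrogates validate the measurement pipeline, not the
biology. The biological claims are tested against the simulator itself.

## Problem sizes

The acceptance experiments and the `analysis/` drivers run a reduced
network of 150 PNs / 50 LNs / 25 eLNs with per-cell conductance totals
unchanged (the in-degree normalization makes per-cell drive
size-invariant), 2000 ms trials for recruitment and the trade-off
experiment (500 pre + 1000 stimulus + 500 post), and the full 3000 ms
protocol for decorrelation. The reliability/separability experiment uses a
3 × 3 conductance grid {0, 0.0004, 0.001} × {0, 0.0002, 0.0004} µS, one
similar-odor pair (5-unit shift) and 10 trials per odor, repeated over
three master seeds; the classification ordering is stochastic at this
scale and is required in at least two of the three seeds. Full-size runs
(300/100/50, 6 × 6 grid, 21 odors × 10 trials) use the same code paths via
`run_experiment` and take hours, not minutes.

## Numerical and degenerate-input choices

* Gating variables are clamped to [0, 1]; calcium to ≥ 0. Non-finite
  voltages abort a trial with the offending cell and time.
* Cells with in-degree 0 on a pathway receive no conductance from it
  (rather than redistributing the total).
* The E/I ratio g_exc/g_slow is defined as 5 when g_slow = 0; the 36
  default grid cells are totally ordered by (ratio, g_exc, g_slow).
* Zero-variance complexity is 0; all-silent responses are flagged as
  degenerate in the distance matrix rather than dropped.
* Linkage ties are broken by scipy's deterministic index order, making the
  two-cluster cut reproducible and permutation-invariant.

## Known limitations

* The fast-oscillation/synchronization phenomenology of the AL is not a
  target of this package; the explosive high-excitation regime here is
  tonic rather than oscillatory, so its trial-to-trial unreliability is
  carried mostly by input noise amplification.
* LN adaptation uses a single slow Ca pool (τ = 1 s); adaptation
  accumulates through the whole stimulus rather than settling early.
* Receptor-neuron transduction dynamics, synaptic plasticity,
  multi-compartment morphology and odor mixtures are out of scope.
* Channel kinetics, the fixed pathway totals, σ, the peak current and
  the noise bandwidth are calibrated choices documented above; alternative values can be supplied through the
  parameter file and configuration objects without code changes.
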