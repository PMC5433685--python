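# Methods

## Channel gating model

Channels are simulated as continuous-time Markov chains with a generator
matrix Q (off-diagonal transition rates in 1/s, rows summing to zero)
and a designated set of conducting states. Trajectories are exact-jump
(Gillespie) simulations: the initial state is drawn from the stationary
distribution of Q, holding times are exponential in the state's exit
rate, and the final dwell is truncated at the record end and flagged
(rather than dropped) so dwell durations always sum to the requested
duration — the bookkeeping that open-probability estimates rely on.

The default scheme is the minimal three-state chain that reproduces
bursting:

    C_interburst  <-(1/s, 2/s)->  O  <-(10/s, 100/s)->  C_flicker

giving ~1 s interburst closures, bursts of a few ~80 ms openings, and
~10 ms flickery closures. No specific kinetic scheme is claimed for real
CFTR; this is a modelling choice that generates the right phenomenology
for validating the downstream analyses, and all rates are configurable.
Two-state C<->O schemes are provided for calibration work where the
stationary open probability k_open/(k_open+k_close) must be known in
closed form.

Rendering: the unitary current is i = γ·(V_hold − V_rev), so a 20 pS
channel clamped at −50 mV (with V_rev set to 0) deflects −1 pA —
openings are downward, as in inside-out patch recordings with a large
inside-high Cl⁻ gradient. The reversal potential is a configuration
value; a helper documents the Nernst value (+71.8 mV for 147/10 mM Cl⁻
at 37 °C) but nothing computes with it implicitly. Noise is white
Gaussian added per sample; the optional zero-phase Gaussian low-pass
(σ = 0.1325/f_c) is applied after the noise, mimicking a recording
filter acting on the summed signal. Filter coloration of the noise is
therefore the only deviation from whiteness the idealizer must
tolerate; capacitance and leak artifacts are out of scope.

Multi-channel patches draw independent per-channel substreams from one
seed (`numpy` `SeedSequence.spawn`), so channels are statistically
independent and every run is reproducible. A deliberately `coupled`
mode drives two conductance levels from a single trajectory to provide
a positive control for the cooperativity analysis.

## Idealization

Event detection uses the half-amplitude criterion: a sample belongs to
level k when its deflection from baseline is beyond (k − ½) unitary
amplitudes; with explicit per-level currents (needed when a
small-conductance and a full-conductance channel share a patch, whose
levels are not multiples of one another) the thresholds sit midway
between adjacent level currents. Baseline defaults to the mode of the
all-points histogram, which is robust for channels that are mostly
closed. Runs of equal level become events; durations are integer
samples over the sampling rate.

Brief-event exclusion imposes a dead time: events shorter than the
threshold are merged into the preceding retained event (leading ones
fold forward), and same-level neighbours coalesce. This conserves total
record duration exactly. Recovery tests compare detection against
ground truth *at matched resolution* — the same dead time imposed on
the true dwell sequence — because a filter with rise time t_r
genuinely cannot see closures shorter than t_r, and pretending
otherwise would test the filter, not the detector. Typical exclusion
thresholds are 1 ms for full-conductance openings and 4 ms for
small-conductance openings analysed at 50 Hz bandwidth.

## Dwell-time and burst analysis

Dwell histograms use logarithmic axes with 10 bins per decade, edges at
10^(k/10) ms, left-closed right-open. Exponential mixtures are fitted
by maximum likelihood conditioned on dwells exceeding the imposed dead
time (left truncation): the one-component censored MLE is closed-form
by memorylessness (τ̂ = mean(t) − c); the two-component fit maximizes
the truncated mixture likelihood by Nelder–Mead from three starts with
the log-sum-exp trick, and reports a log-likelihood ratio against the
one-component fit as a model-selection aid. Degenerate inputs (all
dwells equal, fewer than 10 dwells) are rejected with diagnostics.

The critical closed time t_c separating flickery (intraburst) from
interburst closures is the equal-density crossing of the two fitted
closed-time components, available in closed form:

    t_c = ln(a_f τ_s / (a_s τ_f)) / (1/τ_f − 1/τ_s)

The crossing criterion is the standard choice among the several in use;
it is recorded in the output metadata of every run. Unit tests verify
the closed form against an independent numeric root-finder.

Bursts are delimited by closures longer than t_c; a burst spans from
its first opening to the end of its last opening, so the terminal
closure is excluded and T_MBD ≥ T_b holds by construction. Burst
analysis requires a genuinely single-channel record and rejects
multi-level event lists. The summary reports P_o (total open time over
total time), T_MBD, P_o(burst) (aggregate open time over aggregate
burst duration), T_b = T_MBD·P_o(burst), and T_IBI obtained by
inverting P_o = T_b/(T_MBD + T_IBI); the mean directly measured closure
above t_c is reported alongside as a cross-check, and the identity
holds exactly on every summary produced.

## Amplitude and conductance

All-points histograms (default 10-s analysis windows of 50 Hz-filtered
data, both configurable) are fitted with sums of Gaussians by nonlinear
least squares on the binned counts — matching how such histograms are
actually fitted in practice — with peak-based initialization and a
goodness-of-fit correlation R reported; non-convergence yields a
flagged result, never a silent failure. Component areas give level
occupancies; the component nearest zero deflection is the baseline, and
i per level is the component mean minus the baseline mean. Level
assignment tolerates a component-mean error of a quarter of the largest
expected deflection by default, enough to separate a half-conductance
level from a full one. Conductance is the absolute OLS slope of the
i–V relation (pA/mV × 1000 = pS), invariant to any constant offset of
the voltage axis.

## Two-channel binomial analysis

For N identical independent channels P(k) is binomial (supported for
N ≤ 5); for two channels with unequal open probabilities the three
level occupancies follow the product formulas, which sum to one
identically. The cooperativity ratio printed form is interpreted as

    CR = [P(1)² / (P(0)·P(2))] ÷ [2N/(N−1)]

the only reading for which N = 2 identical independent channels give
exactly CR = 1 (P(1)²/(P(0)P(2)) = 4 and the divisor is 4); the
interpretation is unit-tested against that benchmark. CR > 1 for any
p₁ ≠ p₂ under independence (an AM–GM-type strict inequality, verified
on a grid), and positively coupled channels drive CR below 1 because
the single-open level empties. Classification uses a configurable
tolerance band (default ±0.1) around 1. Observed occupancies may come
from idealized event time fractions or from Gaussian-fit component
areas; both paths are provided because amplitude-histogram areas are
what a mixed sc/wtl patch yields most directly.

## Ribosome profiling

The footprint generator samples A-site codons with probability
proportional to per-codon dwell weights, draws read lengths from a
distribution over 27–29 nt (configurable within 20–40 nt), and places
each 5′ end at (A-site codon middle − offset(length)). An elevated
weight at codon 2 (8× gene mean by default) emulates the initiation
peak of harringtonine-treated cells; without such a peak a start-codon
metagene has no calibration signal, and the calibrator correctly
refuses (modal bin < 2× median background).

Calibration recovers offsets per read length from the modal 5′ position
near start codons: the initiating ribosome's P site covers the start
codon, so its A-site middle is at cds_start + 4, and
offset = 4 − (modal 5′ position relative to the start). Only 5′-end
calibration is implemented, reflecting the greater variability of
footprint 3′ ends.

Occupancy: each read increments the codon containing nucleotide
(5′ + offset); reads with uncalibrated lengths, unknown transcripts, or
A sites outside the CDS are tallied, never silently dropped. Per gene,
counts at included positions are divided by the gene's mean over
included positions, making the mean ratio exactly 1 per gene (asserted
in tests); ratios are averaged across genes per codon. Included
positions are sense codons past the first 51 nt (17 codons) of the CDS
— the region depleted by run-off elongation during harvesting. The
per-gene mean is computed over included positions only; this choice is
what preserves the occupancy-1 identity. ATG positions count toward
the gene mean but the ATG row is flagged excluded in the output table,
since initiation chemistry inflates apparent Met dwell; the exclusion
applies to all ATG codons because the table is indexed by codon, not
position. Genes with mean coverage below 0.5 reads/codon (a default,
not an empirical constant) are skipped and counted. The slow-codon
boundary is a configurable quantile (default 0.90) of the per-codon
occupancy distribution, logged with its definition; a Spearman rank
correlation of occupancy against genome codon usage is attached to the
report.

## Assay quantifications

Melt curves are fitted with the Boltzmann sigmoid in its descending
form f(T) = bottom + (top − bottom)/(1 + exp((T − T_a)/slope)), slope
> 0, so the soluble fraction falls with temperature and T_a is the
temperature at which half the protein remains soluble. Top and bottom
plateaus are fitted rather than pinned at 1 and 0 because fractions
are expressed relative to the 37 °C point and real plateaus drift.
At least five temperatures are required; R² < 0.5 flags the fit as
non-sigmoidal instead of failing. Normalization to the 37 °C value is
per replicate.

ddCt: duplicate wells averaged, ΔCt per sample against the reference
gene, ΔΔCt against the reference sample, fold = 2^(−ΔΔCt). qPCR
efficiency = (10^(1/|slope|) − 1)·100 rounded to integer percent
(slope 1/log₁₀2 ≈ 3.32 is exactly 100%). Western-blot totals (B + C)
are divided by the geometric mean of the normalizers (NPT and ACTB by
default; geometric mean is the standard multi-reference convention, and
single-normalizer mode exists), scaled so the reference sample is
exactly 100%. Microarray ratios are median(Cy3)/median(Atto647) per
tRNA over replicate probes (24 in the reference design), rescaled so
spike-in standards equal 1 — making the result invariant to uniform
channel gain. Classification proportions are truncated (not rounded)
to whole percent, the convention under which 12/27 reports as 44% and
15/27 as 55%.

## Determinism and problem sizes

A single seed feeds `numpy.random.SeedSequence`, which spawns
independent substreams per channel and stage; fixed seeds give
byte-identical outputs. The benchmark script simulates 600-s
two-channel records at 1 kHz (6×10⁵ samples each) — long enough that
the CR of identical channels concentrates well inside ±0.1 of 1 —
and the test suite uses 120–400 s records, 10⁵ footprint reads over
10 genes × 300 codons, and 200-replicate Monte-Carlo studies for
estimator bias; the full suite runs in well under a minute.

## What the generators do and do not emulate

Simulated traces have ideal baselines (no drift, seal leak, or
capacitance transients) and white noise before filtering; real records
would additionally need baseline tracking. The footprint generator
draws reads independently per position (multinomial), with no
sequence-composition bias, no ligation bias, and no reading-frame
blur; real libraries show all three, so passing recovery tests
demonstrate correctness of the calculation, not robustness to every
library artifact. Melt curves and Ct tables have Gaussian noise only.
Within those limits, every analysis result in the tests is measured
against generator ground truth or closed-form oracles, never against
itself.

## Known limitations

No hidden-Markov or segmental-k-means idealization; no missed-event
correction beyond left-truncated likelihoods; no full Q-matrix fitting;
cooperativity statistics only for two-channel patches; occupancy has no
P-site/E-site multi-site model and no differential statistics between
conditions; genome mapping and adapter trimming are upstream of this
package, which consumes transcript-space alignments.
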