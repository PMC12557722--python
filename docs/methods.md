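# Methods

`alexfret` analyses (and simulates) diffusion-based single-molecule FRET
measurements with microsecond alternating-laser excitation (ALEX), of the
kind used to resolve the global conformational dynamics of the Rag GTPase
heterodimer.  This note records the models, the defaults and why they were
chosen, the numerical choices, and the limits of what the synthetic tests
demonstrate.

## Photon-stream model and the synthetic generator

A measurement is a stream of photon detection events, each carrying an
integer timestamp (clock period 12.5 ns by default) and one of three
channel labels that jointly encode detector and excitation period:
donor emission under donor excitation (DexDem), acceptor emission under
donor excitation (DexAem, the FRET-sensitized channel), and acceptor
emission under acceptor excitation (AexAem).  AexDem photons are
negligible in practice and are not modeled.

The generator (`simkit`) emulates:

- **Transits.** Molecules cross the confocal volume for milliseconds.
  Transit durations are exponential with mean `mean_transit_ms` (default
  3 ms) truncated to 0.2–10 ms, which reproduces the broad burst-size
  distributions of diffusion experiments without modeling diffusion
  paths or the excitation point-spread function.  Transit start times
  are a Poisson process (default mean spacing 50 ms); overlapping
  transits are thinned with a warning, since the analysis assumes one
  molecule at a time.
- **Alternation.** Lasers alternate on an explicit 50 µs grid, 45% duty
  per laser with the remaining 10% discarded as switching gaps —
  standard µs-ALEX practice.  Photons are generated only inside the
  active window of the responsible laser, at `burst_rate` (default
  50 kHz per laser) during a transit.
- **Species.** Dual-labeled (default 60%), donor-only (20%) and
  acceptor-only (20%) molecules.  Donor-only transits produce no
  acceptor-excitation photons (stoichiometry S ≈ 1), acceptor-only ones
  no donor-excitation signal (S ≈ 0).
- **Conformational dynamics.** Dual-labeled molecules carry a
  continuous-time Markov chain over K FRET states (Gillespie-sampled,
  initial state from the stationary distribution).  Each
  donor-excitation photon is routed to the acceptor channel with
  probability γE/(γE + 1 − E) given the state's efficiency E at its
  arrival time.
- **Corrections ground truth.** Donor leakage l routes each
  donor-emitted photon to DexAem with probability l/(1+l), making the
  standard correction F_DA − l·F_DD exact in expectation; direct
  excitation adds DexAem photons with expected count d·E[F_AA]; γ ≠ 1
  rescales the per-photon acceptor odds.  Defaults are l = d = 0, γ = 1
  so the raw proximity ratio equals E.
- **Background.** Uniform Poisson photons per channel inside the
  corresponding laser window (defaults 400/300/300 counts/s in-window,
  i.e. ~450 counts/s effective total).

The scenario presets encode the nucleotide states of the Rag system:
`apo` (E 0.19/0.73, rates 50 and 202 s⁻¹), `dual-GDP` (three near-static
states 0.19/0.35/0.60), `single-GTP` (high-FRET dominant), `dual-GTP`
(fast exchange, enhanced mid-FRET), `raptor-bound` (single static state
at 0.40).  Burst brightness, background and acquisition length are not
reported for the original measurements; the defaults above are typical
for confocal smFRET and are recorded in every scenario config.

What the generator does **not** emulate: diffusion re-entry ("burst
splitting" by the same molecule), triplet blinking and photobleaching,
state-dependent brightness, detector afterpulsing and dead time, and
interphoton correlations beyond alternation.  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every photophysical artifact of real data.

## Burst search and metrics

Background rates are estimated per 10 s window from the exponential tail
of the inter-photon delay distribution (delays above a threshold follow
a shifted exponential by memorylessness; the threshold is iterated to
3/rate).  The burst criterion is the standard sliding window: m = 10
consecutive photons spanning less than m/(F·bg) seconds (F = 6) mark a
burst; bursts below 30 photons are discarded.  Burst edges are then
trimmed: leading/trailing photons separated from the core by more than
ten times the burst's median inter-photon spacing (capped by
1/(F·bg)) are stripped.  Hot windows at the burst boundary always sweep
in a few isolated background photons whose millisecond spacings would
otherwise dilate the burst span several-fold; because in-burst spacings
are ~20 µs and background spacings ~2 ms, the threshold separates the
two cleanly (the probability that a genuine in-burst gap exceeds ten
medians is e⁻⁷ per gap).  Without trimming, the spurious state
transitions implied during those sparse edge spans inflate the fitted
interconversion rates by tens of percent.

Per burst, with counts F_DD, F_DA, F_AA: PR = F_DA/(F_DD+F_DA);
F_DA' = F_DA − l·F_DD − d·F_AA; E = F_DA'/(γF_DD + F_DA');
S = (γF_DD + F_DA')/(γF_DD + F_DA' + F_AA/β).  Dual-labeled molecules
are selected by S ∈ [0.25, 0.75].  Population summaries use histogram
modes; no Gaussian mixture fitting is attempted because only approximate
population modes are meaningful at these statistics.

## Burst-variance analysis

Each selected burst's donor-excitation photons are cut into consecutive
windows of n_sub = 5; the acceptor fraction per window is a subburst
FRET value.  For a static molecule the per-burst standard deviation of
these values is bounded by the binomial shot-noise limit
σ = √(E(1−E)/n_sub).  Significance is assessed per FRET bin by Monte
Carlo: 1,000 resamples drawing binomial subbursts matched to each
burst's window count and mean FRET, with the 99.9th percentile of the
resampled bin-mean σ as the static band.  The Monte-Carlo band (rather
than an analytic test) avoids small-n bias and matches how the analysis
is done in practice.  n_sub = 5 is the field-standard choice balancing
time resolution against shot noise; stoichiometry photons are excluded
because S is excitation- not conformation-dependent.

One caveat applies to tail bins: a static burst whose windowed mean FRET
fluctuates away from its true efficiency carries the variance of the
true efficiency, while the matched null uses the (smaller) binned one —
so sparsely populated bins far from a population mode can flag
"dynamic" even for static samples once enough bursts accumulate.  BVA
conclusions should be read at the populated bins around the population
modes, which is how the analysis is used here and in practice.

## Photon-by-photon HMM

The kinetics model is a discrete-time hidden Markov chain on the
timestamp clock: per-tick transition matrix A, per-state emission
distribution B over the three channels, initial distribution π at the
first photon of each burst.  Over an inter-photon gap of g ticks the
state propagates by A^g.  This discrete-gap formulation (rather than a
continuous-time likelihood) keeps the E-step exact: with the
eigendecomposition A = VΛV⁻¹, both A^g and the expected number of
i→j transitions inside a gap reduce to closed forms — the latter through
the divided difference (λ_k^g − λ_m^g)/(λ_k − λ_m), evaluated as
g·λ^{g−1} for (near-)coincident eigenvalues.  The forward/backward
recursions are scaled per photon and vectorized across bursts.
Baum–Welch therefore has exactly monotone log-likelihood, which the
tests assert.

Initialisation seeds emissions by k-means on per-burst (E, S) with
seed-dependent jitter, uniform exit rates of 100 s⁻¹, and uniform π.
Because k-means can miss a minority population (label collapse), fits
used for inference are best-of-restarts over a few jittered seeds.
Convergence is declared at a relative log-likelihood change below 1e-8
(1e-10 for the headline fits).

**State classification.**  A state's emission stoichiometry
S = (B_DD+B_DA)/(B_DD+B_DA+B_AA·duty ratio) labels it donor-only
(S > 0.8), acceptor-only (S < 0.2) or FRET, with
E = B_DA/(B_DD+B_DA) for FRET states; states within 0.02 of a
threshold are flagged ambiguous.  States are reported sorted by E.

**Model selection.**  The number of states is chosen by an integrated-
complete-likelihood style score: the complete-data log-likelihood along
the Viterbi path minus (d/2)·ln(N photons), d = K(K−1)+K(C−1)+(K−1).
Using the Viterbi complete-data likelihood (rather than the
posterior-entropy form of ICL) penalizes overlapping redundant states
directly; the alternative form would be a drop-in replacement.

**Rates.**  Conformational rates are the off-diagonal entries of the
principal matrix logarithm of A divided by the clock period, restricted
to the FRET states — transitions through donor-only/acceptor-only states
reflect labeling, not conformation.  If A is not embeddable the
first-order (A−I)/Δt estimate is used with a warning.  A
Viterbi-dwell-based estimate is provided as a secondary diagnostic; it
systematically under-counts short dwells and is not used for reporting.
Uncertainties, when requested, come from a burst bootstrap
(resample-with-replacement, warm-started refits, percentile intervals).

**Known bias.**  The emission model treats channels as independent per
photon, but ALEX imposes a deterministic alternation of available
channels on the 50 µs grid.  This residual correlation, together with
background photons inside bursts, inflates fitted interconversion rates
by roughly 10–15% at the default conditions (measured against
ground-truth segmented fits).  This is inherent to the pooled-channel
photon-by-photon HMM family; the recovered state efficiencies are
unaffected (bias < 0.01).

## Distance conversion

E and inter-dye distance are linked by r = R0·((1−E)/E)^{1/6}.  The
default R0 = 54.5 Å (Cy3/Cy5-class pair) reproduces the four reported
efficiency/distance pairs of the Rag system (0.13→74 Å, 0.35→61 Å,
0.6→51 Å, 0.40→58 Å) within ~1 Å simultaneously; it is configurable.
Conformation bands follow the system's structural interpretation:
closed below 54 Å, open in 54–68 Å, wide-open above, with boundary
distances assigned to the lower-distance band.

## Pipeline and reproducibility

`pipeline.run` executes simulate → background → burst search → metrics →
selection → histogram → BVA → HMM → rates → distances, writing one
artifact per stage (Photon-HDF5-style stream, TSV tables, JSON model and
report).  A single run seed derives per-stage substreams keyed by stage
name (SeedSequence over (seed, crc32(stage))), so a stage can be re-run
in isolation; the same config and seed reproduce byte-identical reports.
The report carries the config hash (stable under key reordering), seed
and package version.

## Problem sizes

The validation experiments use 5,000 transits (~3,000 dual-labeled;
~2,200 selected bursts, ~0.5 M in-burst photons) for apo-state parameter
recovery, and 800/1,200 transits for state-count selection on the apo
and dual-GDP presets — enough for the reported tolerances (state
efficiencies ±0.03, rates ±20%) with the estimators' statistical error
a few percent.
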