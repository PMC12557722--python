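# alexfret

Burst analysis for diffusion-based single-molecule FRET with microsecond
alternating-laser excitation (ALEX), including photon-by-photon hidden
Markov kinetics. Built for experiments like the smFRET characterization
of the Rag GTPase heterodimer, whose nucleotide-dependent global
conformation (wide-open / open / closed) is read out from the distance
between dye labels on the two nucleotide-binding domains.

The package covers the full analysis chain:

- **Simulation** (`alexfret.simkit`) — synthetic ALEX photon streams
  with known ground truth: millisecond transits of dual-labeled,
  donor-only and acceptor-only molecules, continuous-time Markov
  interconversion between FRET states, laser alternation, Poisson
  background. Presets encode the apo, dual-GDP, single-GTP, dual-GTP
  and Raptor-bound scenarios.
- **Burst search and metrics** (`alexfret.bursts`) — sliding-window
  burst detection against a delay-tail background estimate, per-burst
  FRET efficiency `E = F_DA′/(γF_DD + F_DA′)` and stoichiometry
  `S = (γF_DD + F_DA′)/(γF_DD + F_DA′ + F_AA/β)` with leakage /
  direct-excitation / γ corrections, and dual-label selection by S.
- **Burst-variance analysis** (`alexfret.bva`) — subburst FRET standard
  deviation versus the binomial static limit `√(E(1−E)/n)` with a
  Monte-Carlo confidence band; detects sub-millisecond dynamics.
- **Photon-by-photon HMM** (`alexfret.hmm`) — multi-channel hidden
  Markov model on inter-photon gaps (state propagates by `A^g` over a
  gap of g clock ticks), exact Baum–Welch via spectral closed forms,
  integrated-complete-likelihood state-count selection, Viterbi paths,
  and transition rates from the matrix logarithm of the fitted `A`.
- **Distances** (`alexfret.distances`) — Förster conversion
  `r = R0·((1−E)/E)^{1/6}` (default R0 = 54.5 Å) and conformation calls.
- **Pipeline + CLI** (`alexfret.pipeline`, `alexfret` command) — one
  seeded, fully reproducible run from scenario to report.

## Worked example

Simulate the apo-state scenario (two FRET states, E = 0.19 and 0.73,
interconverting at 50 and 202 s⁻¹, plus donor-only / acceptor-only
contaminants), detect and select bursts, fit a four-state HMM and
convert the recovered states to distances:

```python
from alexfret import simkit, bursts, hmm, distances

sc = simkit.get_preset("apo").replace(n_bursts=1000, seed=7)
stream = simkit.simulate_experiment(sc)

bg = bursts.estimate_background(stream)
table = bursts.search_bursts(stream, background=bg)
selected, report = bursts.select_bursts(bursts.compute_metrics(table))
print(f"{report['n_total']} bursts, {report['n_selected']} dual-labeled "
      f"({report['n_donor_only']} donor-only, {report['n_acceptor_only']} acceptor-only rejected)")

seqs = bursts.burst_photons(stream, selected)
fit = hmm.em_fit_multistart(seqs, 4, stream.clock_period_s, n_starts=2, seed=0)
print(fit.states[["state", "E_state", "S_state", "label", "occupancy"]]
      .round(3).to_string(index=False))

fret = fit.states.loc[fit.states.label == "FRET", "state"].to_numpy()
rates = hmm.transition_rates(fit.model, fret, fit.occupancy)
print(f"k(L->H) = {rates.rates[0,1]:.0f} /s   k(H->L) = {rates.rates[1,0]:.0f} /s")
print(distances.call_conformation(rates.E_state).round(2).to_string(index=False))
```

Output (numbers as printed by this run):

```
661 bursts, 434 dual-labeled (110 donor-only, 117 acceptor-only rejected)
 state  E_state  S_state         label  occupancy
     0    0.738    0.503          FRET      0.153
     1    0.196    0.503          FRET      0.811
     2    0.619    0.011 acceptor-only      0.018
     3    0.002    0.998    donor-only      0.017
k(L->H) = 46 /s   k(H->L) = 184 /s
   E  distance_A conformation
0.20       68.97    wide-open
0.74       45.88       closed
```

The fit recovers the two conformational states (E ≈ 0.20 and 0.74, true
0.19 / 0.73) next to the donor-only (S ≈ 1) and acceptor-only (S ≈ 0)
label states, the interconversion rates to within statistical error of
the ground truth, and maps the states onto a wide-open (~69 Å) and a
closed (~46 Å) conformation of the dye pair.

The same analysis from the shell:

```sh
alexfret run --scenario apo --seed 7 --outdir apo_run
alexfret compare apo_run/fret_histogram.tsv gtp_run/fret_histogram.tsv --out overlay.tsv
```

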