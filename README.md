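# gabadmf

Whole-brain dynamic mean-field (DMF) modelling of resting-state fMRI, with
PET-informed regional inhibitory gain, Balloon–Windkessel BOLD generation,
sliding-window functional connectivity dynamics (FCD), Kolmogorov–Smirnov
model fitting, and connectome-replacement perturbation experiments.

## The scientific problem

Loss of consciousness — whether transient (propofol anaesthesia) or chronic
(disorders of consciousness after severe brain injury) — reconfigures the
brain's spatiotemporal activity in strikingly similar ways despite wholly
different causes. Biophysical whole-brain models let those causes be probed
*in silico*: a network of excitatory/inhibitory neural-mass pairs, coupled
by a diffusion-MRI structural connectome, is calibrated so its simulated
haemodynamics match empirical fMRI, and is then perturbed — either by
scaling regional inhibition according to the empirical GABA-A receptor
density map (virtual anaesthesia), or by swapping the structural connectome
for a patient-derived or rewired one (virtual injury).

This package implements that machinery end-to-end for computational
neuroscientists: model, haemodynamics, fitting, null models, statistics,
and a synthetic-fixture generator so every stage runs and is testable with
no access to patient data.

## The model in brief

Each region *n* has excitatory and inhibitory populations with currents

```
I_E(n) = W_E·I0 + w₊·J_NMDA·S_E(n) + G·J_NMDA·Σ_p C_np S_E(p) − J_FIC(n)·S_I(n)
I_I(n) = W_I·I0 + J_NMDA·S_E(n) − S_I(n)
```

rates r = F(m·g·(I − I_thr)) with F(x) = x/(1 − e^(−d·x)), and gating

```
dS_E/dt = −S_E/τ_NMDA + (1 − S_E)·γ·r_E + σ·ν(t)
dS_I/dt = −S_I/τ_GABA + r_I + σ·ν(t)
```

integrated with Euler–Maruyama (numba-compiled). The global coupling `G`
scales long-range excitatory interactions over the structural connectome
`C`; per-region feedback inhibition `J_FIC` is tuned so excitatory
populations fire near 3 Hz; and regional neuromodulation enters through
the inhibitory gain `g_NM(n) = 1 + s_I·d_n`, with `d_n` the normalised
GABA-A receptor density. Simulated rates drive a Balloon–Windkessel
haemodynamic model; BOLD is sampled at the empirical TR and band-passed to
0.008–0.09 Hz. Fit to data is the KS distance between simulated and
empirical FCD value distributions (sliding window 30 TRs, step 3).
See `docs/methods.md` for every convention and numerical choice.

## Worked example

```python
import gabadmf as g

spec = g.FixtureSpec(n_regions=20, seed=7)          # synthetic 20-region brain
connectome = g.synth_connectome(spec)
rmap = g.synth_receptor_map(spec, connectome.coordinates)

scaled = g.scale_for_simulation(connectome)          # max weight -> 0.2
tuned = g.tune_fic(g.DMFParameters(G=1.2), scaled, seed=1)
print(f"FIC tuning: {tuned.rounds} round(s), "
      f"mean rate {tuned.mean_rates.mean():.2f} Hz")

trace = g.simulate(tuned.params, scaled, duration_s=190.0, seed=2)
print(f"180 s simulation: grand-mean excitatory rate {trace.rates.mean():.2f} Hz")

bold = g.bandpass(g.balloon_windkessel(trace, TR=2.0))
fcd = g.fcd_matrix(bold)
sample = g.fcd_sample(fcd)
print(f"BOLD: {bold.n_TRs} volumes at TR=2 s -> {fcd.n_windows} FC windows, "
      f"{len(sample)} FCD values (mean {sample.values.mean():.2f})")

null = g.randomise_weight_preserving(connectome, seed=5)
print(f"random null: {null.n_edges} edges (original {connectome.n_edges}), "
      f"weight sum {null.weights.sum():.3f} vs {connectome.weights.sum():.3f}")
```

prints

```
FIC tuning: 1 round(s), mean rate 3.01 Hz
180 s simulation: grand-mean excitatory rate 3.00 Hz
BOLD: 90 volumes at TR=2 s -> 21 FC windows, 210 FCD values (mean 0.71)
random null: 57 edges (original 57), weight sum 48.365 vs 48.365
```

The tuner holds the 3 Hz excitatory firing target; the simulated BOLD
yields an FCD sample whose distribution is what model fitting compares
against empirical data; and the weight-preserving null keeps edge count
and total weight exactly while rewiring the topology.

The same workflows are scriptable from the shell:

```sh
gabadmf make-fixtures --out fixtures/
gabadmf consensus --cohort-dir fixtures/cohort --labels fixtures/labels.txt --out consensus.tsv
gabadmf null --connectome consensus.tsv --kind random --seed 1 --out random.tsv
gabadmf fit-g --connectome consensus.tsv --empirical-dir scans/ --out results/
gabadmf fit-gain --connectome consensus.tsv --map fixtures/receptor_map.tsv \
    --empirical-dir scans/ -G 1.2 --out results/
gabadmf replace --connectome consensus.tsv --null lattice \
    --empirical-a scansA/ --empirical-b scansB/ -G 1.2 --out results/
```

Every CLI run writes a `manifest.json` with the resolved options, seeds and
input digests.

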