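# dirlfp — directional-LFP beta mapping for DBS contact selection

Programming a directional deep-brain-stimulation (DBS) lead is slow: the
middle two levels of the electrode are each split into three segments, so a
monopolar contact review must test six segmented contacts per hemisphere
(about 20 minutes each) before the clinician knows which direction to
stimulate. In the parkinsonian subthalamic nucleus (STN), however, beta-band
(13–35 Hz) local field potentials (LFPs) recorded from those same segments
are strongest on the contacts facing the motor territory — the contacts that
tend to work best clinically. `dirlfp` implements that observation as a
screening tool: record ~2 minutes of rest LFP per hemisphere, rank the six
segments by normalized beta, and test the top-ranked contacts first.

## The statistic and the analysis

For each segmented contact *c* with power spectral density *P_c(f)* (Welch,
1-s Hann windows, 50% overlap):

* a beta peak is searched once per hemisphere, on the contact with maximal
  raw 13–35 Hz power: a local spectral maximum at *f₀* ∈ [13, 35] Hz that
  exceeds a log–log linear 1/f fit (5–45 Hz, beta band excluded) by ≥ 3 dB;
* **normalized beta** of every contact is
  `NB_c = ∫_{f₀±3 Hz} P_c(f) df / ∫_{13}^{35} P_c(f) df`,
  with the numerator band falling back to low beta (13–20 Hz) when no peak
  exists. The ratio is unitless, lies in [0, 1], and is invariant to global
  gain, which makes the six contacts of one lead directly comparable.

Contacts are ranked by `NB_c`. Against a monopolar review that provides each
contact's clinical efficacy (% rigidity improvement per mA) and therapeutic
window (TW = side-effect threshold − effect threshold, mA), the package
computes per-hemisphere Spearman correlations, paired top-2-beta-vs-rest
comparisons, and top-*k* screening curves: the probability that the best
clinical contact lies among the first *k* contacts screened, for the
beta-guided order versus the uninformed baseline (exactly *k*/6).

Because no patient recordings ship with the package, a synthetic cohort
generator produces hemispheres in which a dorsally biased beta source drives
both the spatial LFP pattern (shared narrowband oscillation attenuated with
angular/level distance on a 1/f background) and the clinical response, with
known ground truth for every stage.

## Worked example

```bash
cd analysis
python 01_simulate_cohort.py   # 19 hemispheres, 120 s at 1 kHz, seed 2026
python 03_prediction_curves.py
```

prints

```
n = 19 hemispheres (12 with a beta peak)
best-efficacy contact found: top-1 0.63, top-2 0.68 (random 0.17 / 0.33)
widest-TW contact found:     top-1 0.42, top-2 0.63
beta-peak subset (n=12): top-2 1.00
```

Reading: screening only the single highest-beta contact already finds the
most efficient stimulation contact in 63% of hemispheres versus 17% for an
uninformed first pick; restricting to hemispheres with a clear oscillatory
peak, the two highest-beta contacts contain the best contact in every
simulated case. `02_beta_profiles.py` writes the per-contact normalized-beta
table and a time-frequency figure; `04_group_statistics.py` prints the
correlation and paired-test battery (tables land in `results/`, figures in
`results/figures/`).

The same pipeline is scriptable from the shell:

```bash
dirlfp simulate --config sim.yaml --seed 3 --out cohort/
dirlfp analyze cohort/ --out results/
dirlfp recommend cohort/lfp/H1.tsv   # prints the screening order + time saved
```

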