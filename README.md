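# pcenet

Retrospective reconstruction of drinking-water tetrachloroethylene (PCE)
exposure on water distribution networks, and case-control analysis of the
reconstructed exposures.

From the late 1960s to 1980, asbestos-cement water mains in many New
England towns were sprayed with a vinyl liner applied in a PCE slurry.
The solvent did not fully evaporate and leached into tap water for years,
contaminating some streets heavily (thousands of µg/L in low-flow,
dead-end pipes) and neighboring streets not at all. Because water samples
only exist from 1980 onward, epidemiological studies of this exposure must
*model* each subject's historical dose from the pipe network, the liner
installation years, and the subject's residential history.

`pcenet` implements that modeling chain end to end, for epidemiologists
and exposure scientists who want to reconstruct network-borne contaminant
exposures or study the method's behavior on synthetic data:

1. **Network & flow** (`pcenet.network`, `pcenet.flow`) — EPANET-style INP
   reader/writer (junctions, reservoirs, pipes, demands) plus a sidecar
   CSV of liner attributes; steady-state demand-driven flow by damped
   Newton iteration on nodal heads under the Hazen-Williams law
   `h = r·sign(Q)|Q|^1.852`, `r = 10.67 L/(C^1.852 d^4.871)`. Exact on
   branched (tree) networks, mass-balanced to tolerance on looped ones.
2. **Leaching & transport** (`pcenet.leach`) — first-order (Fickian)
   liner depletion: the mass a pipe of surface area `S = πdℓ` releases in
   the calendar year starting `a` years after installation is
   `J = S·m0·(e^(−a/R) − e^(−(a+1)/R))` with leaching time constant
   `R = 2.25` y (sensitivity grid 0.025–10 y). Released mass mixes into
   the flow field by flow-weighted averaging in topological order, giving
   each node an annual **relative delivered dose (RDD)** — a proxy whose
   ordering across subjects, not its absolute value, is meaningful.
3. **Exposure histories** (`pcenet.exposure`) — residential histories ×
   annual dose fields → per-subject RDD series; latency-windowed
   cumulative/peak/duration metrics (latencies 0–19 y); percentile
   category cuts (median/75th/90th) from exposed controls.
4. **Epidemiology** (`pcenet.epi`) — crude odds ratios with Woolf 95%
   CIs, ML logistic adjusted ORs, the 10% change-in-estimate confounder
   screen, LOESS smoothing of the outcome-vs-RDD relation with a
   data-driven high-exposure cut point, Wilcoxon signed-rank comparison
   of paired exposure vectors, and full latency × category OR tables.
5. **Validation** (`pcenet.validation`) — modeled vs measured
   concentrations: non-detect substitution (half the 0.5 µg/L detection
   limit), Spearman rank correlation, ln-ln OLS (R², slope), stratified
   by flow tertile, pipe position, installation era, and more.
6. **Synthetic data** (`pcenet.synth`) — towns (grid + dead-end branches,
   clustered vinyl-lined neighborhoods installed 1968–1980), cohorts
   (1983–1993 reference frame, 40-year residential histories, core
   covariates at realistic prevalences), logistic outcome injection with
   a configurable true OR on the top exposure category, and sampling
   campaigns with lognormal measurement error and detection-limit
   censoring — so the whole chain is testable without any external data.

## Worked example

Generate a synthetic town and cohort (920 cases / 1293 controls, true OR
1.3 on the >90th-percentile category), then run the analysis:

```sh
pcenet fixtures --out demo --seed 7
cat > demo/config.yaml <<EOF
network_inp: demo/network.inp
pipe_attrs: demo/pipe_attrs.csv
subjects_csv: demo/subjects.csv
residences_csv: demo/residences.csv
samples_csv: demo/samples.csv
out_dir: demo/results
seed: 7
EOF
pcenet analyze --config demo/config.yaml --latency 0,5
```

```
 latency stratum  category  cases  controls  ref_cases  ref_controls  cor  cor_low  cor_high  aor  aor_low  aor_high
       0     all      ever    291       396        629           897 1.05     0.87      1.26 1.06     0.88      1.28
       0     all le_median    123       201        629           897 0.87     0.68      1.12 0.88     0.69      1.13
       0     all gt_median    168       195        629           897 1.23     0.98      1.55 1.25     0.99      1.58
       0     all    gt_p75    105        99        629           897 1.51     1.13      2.03 1.53     1.14      2.05
       0     all    gt_p90     49        38        629           897 1.84     1.19      2.84 1.92     1.23      2.97
       5     all      ever    280       383        629           897 1.04     0.87      1.25 1.06     0.88      1.27
       ...
```

Each row compares one exposure category at one latency against the fixed
referent of women never exposed over the whole study period (629 cases,
897 controls here). `cor` is the crude odds ratio with its Woolf 95%
interval, `aor` the logistic-adjusted estimate controlling for the core
covariates (age, vital status, family and personal breast-cancer history,
age at first birth, occupational PCE, study of origin). The exposure
gradient is visible: null at `ever`, elevated above the 90th percentile
(AOR 1.92, 95% CI 1.23–2.97), consistent with the injected effect of 1.3
up to the sampling noise of an ~87-subject cell.

```sh
pcenet validate --config demo/config.yaml
# n=75 rho=0.83 (p=1.3e-20) R2=0.74
```

compares modeled point concentrations (µg/L, under the configured
absolute calibration) with the synthetic 1980 sampling campaign: rank
correlation 0.83 over 75 samples, R² 0.74 on the ln-ln regression.

```sh
pcenet sensitivity --config demo/config.yaml --leach-rate 0.75,2.25,10
#     R  spearman_vs_baseline
#  0.75              0.988648
#  2.25              1.000000
# 10.00              0.958384
```

varies the leaching constant: subject cumulative RDDs re-scale but keep
essentially the same rank order (Spearman ≥ 0.96 against the R = 2.25
baseline), which is why percentile-based risk categories are robust to
this poorly known parameter.

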