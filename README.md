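# spliceproof

Kinetic-proofreading analysis of 3' splice-site (3'SS) selection by the
U2AF heterodimer.

U2AF nucleates spliceosome assembly by binding the polypyrimidine tract and
terminal AG of candidate 3' splice sites. Its initial interactions are
sub-second, yet splicing outcomes are exquisitely sensitive to small
differences in binding free energy. The resolution is kinetic proofreading:
assembly passes through successive bound states, `E -> Intermediate -> A`,
with irreversible ATP-driven forward steps (`k_fwd1`, `k_fwd2`) racing
U2AF dissociation (`k_off_E`, `k_off_int`, `k_off_A`) at each checkpoint.
This package implements that model and every analysis needed to fit it to
single-molecule and sequencing-style data, plus synthetic-data generators
that emulate each measurement modality so that every fit is testable by
parameter recovery.

## The model

**Bound-state survival.** A molecule observed entering the Intermediate
state stays bound for a two-phase hypoexponential time with survival

```
S(t) = e^{-lam t} - k_fwd2/(lam - k_off_A) * (e^{-lam t} - e^{-k_off_A t}),
lam = k_fwd2 + k_off_int
```

which is what slow single-molecule tracking dwell-time distributions are
fitted to, jointly across conditions with rates shared or free per
condition (`BoundSurvivalModel`).

**Site choice.** For two competing 3' splice sites whose binding
free-energy difference is `ddG` (positive when the S3 site binds tighter;
`-ddG = RT ln(k_off_S3/k_off_S2)`; association is sequence-independent),
with the dimensionless checkpoint strengths `Kf = k_fwd1/k_off_E` and
`Ks = k_fwd2/k_off_int`, the percent spliced in of S3 is

```
PSI = (Kf+1)(Ks+1) / [ 2 Kf Ks + (Kf+Ks)(1 + r) + 1 + r^2 ],   r = e^{-ddG/RT}
```

Limits: `Kf, Ks -> 0` gives the full-proofreading logistic with doubled
exponent (`1/(1+e^{-2 ddG/RT})`, the affinity gap read twice);
`Kf, Ks >> 1` gives `PSI ~ 1/2` (no specificity — every binding event
commits); the equilibrium ("thermodynamic") expectation is the single
exponent logistic. Supporting analyses cover k-mer enrichment from
RNA Bind-n-Seq-style pools, an additive per-position energy model for
scoring sites and deriving `ddG`, two-state HMM segmentation of binding
traces, isotherm (Hill) titration fits, correlation-based dwell and
time-to-splice estimators, and dynamic-metagene splicing half-lives.

## Worked example

Simulate slow-tracking dwell data for a control and a
forward-step-inhibited condition (the inhibitor halves `k_fwd2`), then
refit them jointly with both off-rates shared:

```python
import spliceproof as sp

truth = sp.KineticScheme(k_off_int=1/9.1, k_fwd2=0.15/9.1, k_off_A=1/82)
inhibited = sp.KineticScheme(k_off_int=1/9.1, k_fwd2=0.5*0.15/9.1, k_off_A=1/82)
acq = sp.AcquisitionSettings(frame_interval=3.0, n_frames=400,
                             photobleach_rate=0.002, seed=1)
control = sp.simulate_dwell_times(truth, 5000, acq, condition="control")
drug = sp.simulate_dwell_times(
    inhibited, 5000,
    sp.AcquisitionSettings(frame_interval=3.0, n_frames=400,
                           photobleach_rate=0.002, seed=2),
    condition="inhibitor")

model = sp.BoundSurvivalModel(
    [control, drug],
    sp.SharingSpec(k_off_int="shared", k_fwd2="free", k_off_A="shared"))
res = model.fit(n_bootstrap=200, seed=0)
print(res.summary())
lo, hi = res.ci(lambda s: s["control"].k_fwd2 / s["inhibitor"].k_fwd2)
print(f"forward-rate fold reduction: "
      f"{res.rate('k_fwd2','control')/res.rate('k_fwd2','inhibitor'):.2f} "
      f"[{lo:.2f}, {hi:.2f}]")
```

prints

```
Joint bound-survival fit
  conditions: control, inhibitor
  log-likelihood = -17436.87   AIC = 34881.73   BIC = 34909.27
  free parameters: 4   events: 7223
  [control] k_off_int = 0.1128 /s (lifetime 8.86 s), k_fwd2 = 0.01773 /s, k_off_A = 0.01366 /s (lifetime 73.2 s), Ks = 0.157
  [inhibitor] k_off_int = 0.1128 /s (lifetime 8.86 s), k_fwd2 = 0.009542 /s, k_off_A = 0.01366 /s (lifetime 73.2 s), Ks = 0.0846
forward-rate fold reduction: 1.86 [1.58, 2.24]
```

The shared Intermediate lifetime comes back at 8.9 s (truth 9.1 s), the
A-complex lifetime at 73 s (truth 82 s, inside the bootstrap CI at this
sample size), the control `Ks` at 0.157 (truth 0.15), and the halving of
`k_fwd2` at 1.86-fold [1.58, 2.24]. The PSI equation is then immediately
usable: `sp.psi(1.0, sp.ProofreadingParams(Kf=10, Ks=0.15))` returns
`0.702` — a site bound tighter by one RT captures 70% of splicing events
under partial proofreading.

A command-line interface mirrors the library
(`spliceproof simulate|fit|analyze <stage> ...`); every subcommand logs its
seed and configuration hash and reads/writes plain-text formats (CSV
traces and dwell tables, BED6+ site tables, FASTA pools, JSON reports).

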