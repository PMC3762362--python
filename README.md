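# cosmoskin

Kinetic analysis of single-molecule colocalization (CoSMoS) experiments on
actin branch formation by the Arp2/3 complex, together with a stochastic
simulator that generates the spot-level event streams such experiments
produce.

## The scientific problem

WASP-family proteins activate the Arp2/3 complex to nucleate new
(*daughter*) actin filaments from the sides of existing (*mother*)
filaments. Multi-color TIRF colocalization imaging of dye-labeled Arp2/3
complex, dimeric VCA activator (diVCA), and actin resolves the pathway one
molecule at a time: a diVCA-Arp2/3 complex binds a filament side (a
*nascent branch*), and this intermediate is resolved by kinetic competition
between two first-order pathways — intact dissociation from the filament
(rate constant k_A−) and release of diVCA leaving an *activated*
filament-bound complex (rate constant k_V−\*), which may then nucleate a
daughter. The competing-clock algebra is

```
tau_V* = 1 / (k_A− + k_V−*)          mean nascent-branch lifetime
f_V−   = k_V−* / (k_A− + k_V−*)      probability of diVCA release
k_V−*  = f_V− / tau_V*               the estimator used in practice
k_B    = k_A+ · [f_AV·f_B(+diVCA) + (1 − f_AV)·f_B(−diVCA)]
```

where f_AV is the fraction of Arp2/3 complexes arriving with diVCA bound,
f_B the fraction of nascent branches yielding a daughter, k_A+ the
per-subunit filament association rate constant, and k_B the overall
second-order branch-formation rate constant. The analysis supports the
conclusion that diVCA release is the rate-limiting trigger of daughter
nucleation: k_B is proportional to k_V−\* across activator mutants.

The package is for single-molecule biophysicists who have spot-level event
tables (appearance/disappearance times and positions per channel) and want
the full downstream analysis, and for anyone who wants to test such
pipelines against simulated ground truth.

## What's inside

| module | role |
| --- | --- |
| `synthetic_cosmos` | continuous-time Markov chain simulator of filament-site and tethered-Arp2/3 experiments, plus the camera observation model (photobleaching, 0.1 s detection limit, frame snapping, localization jitter, non-specific background) |
| `event_classification` | coincident-arrival / departure-order / branch classification with detection-efficiency (1/p0) and background corrections |
| `dwell_inference` | left-truncated exponential-mixture maximum likelihood with bootstrap errors; waiting-time fits for k_A+; global photobleach power regression |
| `rate_model` | the rate algebra above with first-order error propagation; the reference measurement table |
| `correlation_resampling` | Pearson r and the Gaussian-resampled permutation tail probability |
| `binding_equilibria` | single-site occupancy, exact direct and competition anisotropy isotherm fits |
| `bulk_kinetics` | pyrene-trace barbed-end concentration and fold-stimulation |
| `pipeline` | end-to-end estimation: observed event tables → all quantities with standard errors |
| `cli_io` | TSV event-table dialect and the `cosmoskin` command-line interface |

## Worked example

Simulate a wild-type experiment at the reference scale (~877 observed
Arp2/3 binding events) and recover the kinetics:

```python
from cosmoskin import KineticParams, ObservationConfig
from cosmoskin.pipeline import run_synthetic_experiment

params = KineticParams.from_construct("wt")     # wild-type diVCA conditions
obs = ObservationConfig(seed=1, duration=600.0)  # 50 ms frames, 0.1 s t_min
est, tables = run_synthetic_experiment(params, 115, obs)
for k in ("f_av", "f_corelease", "f_v_minus", "tau_v_star", "k_v_star"):
    print(f"{k:12s} {est[k].value:8.4f} +- {est[k].se:.4f}")
```

prints

```
f_av           0.8094 +- 0.0123
f_corelease    0.9776 +- 0.0055
f_v_minus      0.0196 +- 0.0052
tau_v_star     0.8500 +- 0.3801
k_v_star       0.0231 +- 0.0120
```

i.e. ~81% of the simulated Arp2/3 complexes arrived carrying diVCA
(ground truth 83%), ~98% of nascent branches released both proteins as a
unit (truth 97.2%), and the diVCA release rate constant recovered as
0.023 ± 0.012 s⁻¹ against a programmed 0.04 s⁻¹ — the wide uncertainty
being dominated by the handful of branch events a single record of this
size contains (pooling branch observations across records tightens it; see
`docs/methods.md`).

The same operations are available from the shell:

```sh
cosmoskin simulate --mode filament --n 115 --seed 1 --out events.tsv
cosmoskin correlate --points panel.tsv --resamples 100000 --seed 1
```

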