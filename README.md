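# emtlogic

Logical modelling of the signalling network that drives tumour-cell
epithelial–mesenchymal transition (EMT), invasion and migration — the early
steps of metastasis — and the analyses that sit on top of such a model:
exact attractor enumeration under mutations, stochastic phenotype
probabilities, in-silico genetic-interaction screens, rule-robustness
censuses, and two ways of confronting the model with transcriptome data.

The package is aimed at systems biologists working with Boolean/logical
models of signalling (the GINsim/MaBoSS ecosystem) who want a scriptable,
tested Python implementation of this analysis stack.

## The model and its analyses

The bundled model has 32 Boolean nodes: two constant environment inputs
(`ECMicroenv`, `DNAdamage`), 24 signalling species (p53 family, Notch, Wnt,
TGF-β/SMAD, AKT1/AKT2, miR-34/200/203, the EMT transcription factors, the
cadherins, …) and six phenotype read-outs (`CellCycleArrest`, `Apoptosis`,
`EMT`, `Invasion`, `Migration`, `Metastasis`). Each non-input node `x`
carries a logical rule `f_x` over its regulators (`!`, `&`, `|`), and the
dynamics is asynchronous: one node flips at a time.

* **Stable states** are fixed points `x = f(x)`; the wild-type model has
  exactly nine (a homeostatic state with only E-cadherin ON, four apoptotic,
  two EMT-arrested, two metastatic). Mutations are clamps — gain of function
  (GoF) forces a node ON, loss of function (LoF) OFF.
* **Phenotype probabilities** follow the continuous-time Markov reading of
  the asynchronous dynamics (all flip rates 1/time-unit): `P(phenotype)` is
  the probability the read-out node is ON at the trajectory endpoint.
* **Epistasis** between two mutations is scored on the event of *not*
  reaching metastasis: `ε = (1 − p12) − (1 − p1)(1 − p2)`; `ε < 0` is
  synergy, `ε > 0` alleviation/masking.
* **Robustness**: every model variant differing from the wild type by one or
  two AND↔OR swaps is enumerated (8001 variants for the bundled model) and
  its stable states are censused against the wild-type attractors
  (`DIST_TO_WT` = Hamming distance to the nearest wild-type state).
* **EBP matching**: a binarized expression profile is compared bit-by-bit
  with each stable state; the integer agreement count (expression-based
  phenotype score) names the closest phenotype per timepoint.
* **Module activity**: a sample's pathway activity is its projection on the
  first principal axis of the pathway's gene-centred expression submatrix;
  group differences are Welch t-tests.

Synthetic-data generators stand in for the study's external inputs: a
TGF-β-induction time course (3 replicates at 0/8/24/72 h, 11 sigmoidally
responding genes), a two-group tumour cohort (88 vs 17 samples with planted
module-activity shifts), and random Boolean models for oracle testing.

## Worked example

```python
from emtlogic import (
    load_metastasis_model, label_stable_state,
    SimulationConfig, estimate_phenotype_probabilities,
)

model = load_metastasis_model()

states = model.enumerate_stable_states()
print(len(states))                          # 9
print(sorted(str(label_stable_state(s)) for s in states))
# ['Apoptosis+CellCycleArrest', 'Apoptosis+CellCycleArrest',
#  'Apoptosis+CellCycleArrest', 'Apoptosis+CellCycleArrest',
#  'EMT+CellCycleArrest', 'EMT+CellCycleArrest', 'HS',
#  'Metastasis', 'Metastasis']

# Notch activation with p53 loss: the fully penetrant metastatic mutant
clamps = {"NICD": 1, "p53": 0}
print(all(s["Metastasis"] for s in model.enumerate_stable_states(clamps)))
# True
cfg = SimulationConfig(n_trajectories=1000, seed=0)
probs = estimate_phenotype_probabilities(model, clamps, cfg)
print(probs["Metastasis"], probs["Apoptosis"])  # 1.0 0.0
```

The nine stable states are the model's wild-type repertoire; clamping
`NICD=1, p53=0` collapses it so that every attractor — and hence every
simulated trajectory — is metastatic, while apoptosis becomes unreachable.

The same stages are available from a shell:

```bash
emtlogic stable-states --out stable_states.tsv
emtlogic simulate --clamp NICD=1 --clamp p53=0 --trajectories 1000
emtlogic screen --out-dir screen_results      # 52 singles + 1300 doubles
emtlogic robustness --out-dir robustness_results
emtlogic synth timecourse --out tc.tsv && emtlogic ebp --expr tc.tsv
```

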