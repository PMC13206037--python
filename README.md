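# nticell

Information-theoretic analysis of collective individuation in small clonal
communities of motile cells.

When a single cell divides into a confined community of 2, 4, then 8
genetically identical siblings, does each cell's behaviour stay its own, or
is it absorbed into — and later re-emitted by — the collective?  `nticell`
quantifies this with **non-trivial information closure (NTIC)** computed on
per-cell kinetic-energy (KE) time series:

```
NTIC = I(X_{t+1}; X_t) − I(X_{t+1}; X_t | C_t)
     = I(X_{t+1}; C_t) − TE(C→X)
```

where `X_t` is the focal cell's log-KE and `C_t` the sibling mean-field
(the mean KE of all contemporaneous cells excluding the focal one).  NTIC
is the redundancy between the self-predictive channel and the collective
channel.  Per-cell permutation surrogates of `C_t` (50 permutations, 95th/
5th-percentile thresholds) classify each cell and life-history phase into:

| MI(X′;C) significant | NTIC vs bounds | category |
|---|---|---|
| yes | above upper | coupled |
| yes | within | information closure |
| yes | below lower | synergistic |
| no  | within | independent |
| no  | outside | anomalous (excluded) |

"Information closure" — coupling without loss of self-prediction — is the
signature of *situated autonomy*: the cell remains embedded in an
informative collective while its future becomes self-determined.  The
package also maps each cell onto a minimal-MI partial-information-
decomposition fingerprint (redundancy vs synergy), measures
parent–daughter inheritance fidelity with the Jensen–Shannon divergence
between middle-phase KE distributions, and checks robustness under
temporal coarse-graining.

Because recordings of this kind are not publicly archived, the package
ships a first-class synthetic community generator: binary-fission
genealogies whose per-cell KE series realize *known* informational regimes
(coupled / information-closed / independent), used throughout the
validation suite to test the whole pipeline against ground truth.  See
`docs/methods.md` for the models, estimator choices and calibration.

## Worked example

```python
from nticell import (RegimeSpec, simulate_lineage, simulate_community,
                     classify_bundle)

lineage = simulate_lineage(generations=3, frames_per_generation=9000, seed=7)
bundle = simulate_community(lineage, RegimeSpec.information_closed(), seed=7)
results = classify_bundle(bundle, phases=("middle",), generations=(3,), seed=7)
print(results[["cell_id", "mi_ctx", "ntic_stat", "category"]].round(4))
```

prints one row per eight-cell-stage cell (values in bits):

```
   cell_id  mi_ctx  ntic_stat             category
0        7  0.0363    -0.0224  information_closure
1        8  0.0314    -0.0148  information_closure
2        9  0.0209    -0.0292  information_closure
3       10  0.0257    -0.0279  information_closure
4       11  0.0254    -0.0183  information_closure
5       12  0.0320    -0.0111  information_closure
6       13  0.0325    -0.0298  information_closure
7       14  0.0424    -0.0173  information_closure
```

Every cell shares significant information with its siblings (`mi_ctx`
well above the per-cell surrogate threshold, here ≈ 0.005 bits on
average) while its NTIC statistic stays inside the surrogate band — the
information-closed signature this community was designed to carry:
coupled to the collective, yet informationally self-determined.

The same pipeline is scriptable from the shell:

```
nticell simulate --config cfg.yaml --out run/
nticell classify --config cfg.yaml --out run/
nticell inherit  --config cfg.yaml --out run/
nticell sweep    --config cfg.yaml --out run/
nticell report   --out run/
```

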