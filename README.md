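# cscc-bn

Bayesian-network clinical decision support for cutaneous squamous cell
carcinoma (cSCC): surgery versus the anti PD-1 antibody Cemiplimab.

Treatment choice in advanced skin cancer weighs tumor extent (the
AJCC/UICC 8th-edition T/N/M categories), histology (cSCC vs. basal cell
carcinoma) and molecular markers (PD-L1 expression as CPS and TPS). This
package implements that decision process as a discrete Bayesian network:
the joint distribution over all variables factorizes node-wise as

    P(X1, ..., Xn) = ∏ᵢ P(Xi | Pa(Xi))

and a treatment node's posterior given partial patient evidence e,

    P(T | E = e) = P(E = e | T) P(T) / Σₜ P(E = e | T = t) P(T = t),

is computed by exact variable elimination (verified against brute-force
enumeration). Untested markers are simply absent evidence and are
marginalized — no imputation. The option with the higher posterior is the
primary recommendation; the other is subordinate.

It is aimed at clinical-informatics researchers and tumor-board tooling
developers: the generic engine (model dialect, wildcard CPT rules, exact
inference, validation) is reusable for any small discrete network, and the
shipped reference model reproduces a published eight-node skin-cancer
network's posteriors exactly.

## What's in the box

* `cscc_bn.network` — discrete-BN data model, structural validation,
  compilation of compact wildcard CPT rules into full tables.
* `cscc_bn.inference` — exact posterior inference: enumeration oracle and
  variable elimination, required to agree to 1e-10.
* `cscc_bn.reference` — the shipped 8-node skin-cancer model
  (`models/cscc_reference.yaml`) plus the ten-constraint calibration suite.
* `cscc_bn.policy` — higher-probability-wins recommendation with the
  1–99% clamp and surgery tie-break.
* `cscc_bn.evaluate` — confusion matrices, sensitivity/specificity/
  accuracy/PPV/NPV, ROC/AUC (first principles), concordance audits.
* `cscc_bn.cohort` — reproducible synthetic cohorts matching the published
  marginal frequencies, with configurable treatment-assignment policies.
* `cscc_bn.cli` — the `cscc-bn` command-line tool.

## Worked example

A hypothetical advanced patient — cSCC, T4a, N3, M0, both PD-L1 scores
positive:

```sh
$ cscc-bn infer --evidence Histology=cSCC,T=T4a,N=N3,M=M0,TPS=positive,CPS=positive
Surgery: 60%
Cemiplimab: 95%
primary: Cemiplimab
subordinate: Surgery
```

Surgery remains possible (60%) but immunotherapy is clearly favored (95%),
so Cemiplimab is the first-line suggestion. An early tumor with no PD-L1
testing — the markers are marginalized, not guessed:

```sh
$ cscc-bn infer --evidence Histology=cSCC,T=T1,N=N0,M=M0
Surgery: 99%
Cemiplimab: 1%
primary: Surgery
subordinate: Cemiplimab
```

The same from Python:

```python
from cscc_bn import (
    CaseEvidence, build_reference_model, case_to_evidence,
    posterior_by_variable_elimination, recommend,
)

model = build_reference_model()
case = CaseEvidence("cSCC", "T3", "N2", "M0")  # PD-L1 unknown
ev = case_to_evidence(case)
s = posterior_by_variable_elimination(model, ev, "Surgery")["recommended"]
c = posterior_by_variable_elimination(model, ev, "Cemiplimab")["recommended"]
print(recommend(s, c).primary, round(s * 100), round(c * 100))
# Cemiplimab 70 80
```

Cohort workflows:

```sh
cscc-bn simulate --n 66 --seed 7 --out cohort.csv     # synthetic cohort
cscc-bn batch --cohort cohort.csv --out-prefix run    # metrics + ROC + audit
cscc-bn calibrate-check                               # 10/10 constraints pass
cscc-bn validate-model --model my_model.yaml          # structural checks
```

`batch` prints a JSON report with per-node confusion counts, sensitivity/
specificity/accuracy/PPV/NPV, the Cemiplimab AUC, the concordance count and
a discordant-record audit listing both posteriors per mismatched patient.

## Model file dialect

Models are YAML (or JSON) with `nodes`, `edges` and `cpt_rules`; a rule
fixes a subset of a child's parents (unlisted parents are wildcards) and
supplies one distribution, the most specific matching rule wins, and
equal-specificity conflicts are compile errors. See
`src/cscc_bn/models/cscc_reference.yaml` and `docs/methods.md` for the
full description of the shipped parameterization, its assumptions and its
limitations.
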