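"""The shipped reference model: head-and-neck skin-cancer treatment choice.

An eight-node network for choosing between surgical resection and the anti
PD-1 antibody Cemiplimab in cutaneous squamous cell carcinoma (cSCC) and
basal cell carcinoma (BCC).  Six observable root nodes — histology, the
AJCC/UICC 8th-edition T, N and M categories, and the two PD-L1 expression
markers CPS (Combined Positive Score) and TPS (Tumor Proportion Score) — all
feed the two treatment nodes, each binary ``recommended`` /
``not_recommended``.  The treatment nodes share no edge: each option is
scored independently and the final choice is made downstream by the
comparison rule in :mod:`cscc_bn.policy`.

Root priors come from the 66-patient cohort frequencies; the tables of the
treatment nodes are expert-style elicited values expressed as compact
wildcard rules:

* each option gets a base probability per (T, N, M) combination, built from
  per-category severity anchors combined by ``max`` (Cemiplimab: any single
  advanced category is sufficient reason for systemic therapy) or ``min``
  (surgery: the least operable category limits resectability);
* BCC overrides reduce the Cemiplimab tendency (its approval in BCC is
  second-line, after hedgehog-pathway inhibitors);
* a positive CPS adds a small Cemiplimab bonus in very advanced disease
  (T4a/T4b, N3 or M1), reflecting the better objective response rates seen
  with PD-L1 expression; at earlier stages PD-L1 status does not move the
  recommendation.  TPS is carried as an observable but does not shift the
  treatment tables (CPS subsumes it, counting immune cells as well).

CPS and TPS are modeled as *binary* latent states; an "unknown" marker is
simply absent evidence and is marginalized over the marker's prior — no
third "unknown" state exists in the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .inference import Evidence, posterior_by_variable_elimination
from .network import (
    BayesianNetworkModel,
    CPTRule,
    EdgeSpec,
    ModelError,
    NodeSpec,
    compile_cpt,
)
from .policy import CEMIPLIMAB, SURGERY, round_half_up_percent

__all__ = [
    "HISTOLOGY_STATES",
    "T_STATES",
    "N_STATES",
    "M_STATES",
    "MARKER_STATES",
    "TREATMENT_STATES",
    "CaseEvidence",
    "CalibrationConstraint",
    "CalibrationResult",
    "CALIBRATION_CONSTRAINTS",
    "build_reference_model",
    "reference_model_path",
    "case_to_evidence",
    "check_calibration",
]

HISTOLOGY_STATES = ("cSCC", "BCC")
T_STATES = ("Tx", "T0", "Tis", "T1", "T2", "T3", "T4a", "T4b")
N_STATES = ("Nx", "N0", "N1", "N2", "N3")
M_STATES = ("Mx", "M0", "M1")
MARKER_STATES = ("positive", "negative")
TREATMENT_STATES = ("recommended", "not_recommended")

UNKNOWN = "unknown"

_COHORT_N = 66

# cohort counts behind the root priors
_HISTOLOGY_COUNTS = {"cSCC": 22, "BCC": 44}
_T_COUNTS = {"Tx": 1, "T0": 3, "Tis": 4, "T1": 46, "T2": 5, "T3": 4, "T4a": 2, "T4b": 1}
_N_COUNTS = {"Nx": 48, "N0": 11, "N1": 0, "N2": 1, "N3": 6}
_M_COUNTS = {"Mx": 45, "M0": 20, "M1": 1}

# N1 was never observed in the cohort but is a legal category; a degenerate
# zero prior would make N1 evidence inconsistent, so it gets the 1% floor and
# the observed categories are rescaled to keep the prior normalized.
_N1_FLOOR = 0.01

# CPS was positive in all 7 tested patients; a 1.0/0.0 prior is clamped to
# the 1–99% band used throughout the model.  TPS: 5 positive / 2 negative.
_CPS_PRIOR = {"positive": 0.99, "negative": 0.01}
_TPS_PRIOR = {"positive": 5 / 7, "negative": 2 / 7}

# ---------------------------------------------------------------------------
# treatment tendency anchors (probability of "recommended"), cSCC

# Cemiplimab: any single sufficiently advanced category drives systemic
# therapy, so anchors combine by max.
_CEM_T = {"Tx": 0.01, "T0": 0.01, "Tis": 0.01, "T1": 0.01, "T2": 0.05, "T3": 0.60, "T4a": 0.90, "T4b": 0.95}
_CEM_N = {"Nx": 0.01, "N0": 0.01, "N1": 0.30, "N2": 0.80, "N3": 0.90}
_CEM_M = {"Mx": 0.01, "M0": 0.01, "M1": 0.95}

# Surgery: the least resectable category is limiting, so anchors combine by
# min.  Tx/T0/Tis rows are conservative surgery-favoring defaults.
_SURG_T = {"Tx": 0.95, "T0": 0.95, "Tis": 0.95, "T1": 0.99, "T2": 0.90, "T3": 0.75, "T4a": 0.65, "T4b": 0.40}
_SURG_N = {"Nx": 0.99, "N0": 0.99, "N1": 0.85, "N2": 0.70, "N3": 0.60}
_SURG_M = {"Mx": 0.99, "M0": 0.99, "M1": 0.20}

#: Cemiplimab bonus for PD-L1 CPS positivity, applied only in very advanced
#: disease (T4a/T4b, N3 or M1) and only for cSCC.
_CPS_BONUS = 0.05

#: BCC Cemiplimab tendencies are reduced relative to cSCC by this amount
#: (floored at 1%); surgery tendencies are shared between histologies.
_BCC_CEM_REDUCTION = 0.15


def _cem_base(t: str, n: str, m: str) -> float:
    return max(_CEM_T[t], _CEM_N[n], _CEM_M[m])


def _surg_base(t: str, n: str, m: str) -> float:
    return min(_SURG_T[t], _SURG_N[n], _SURG_M[m])


def _very_advanced(t: str, n: str, m: str) -> bool:
    return t in ("T4a", "T4b") or n == "N3" or m == "M1"


def _treatment_dist(p_rec: float) -> dict[str, float]:
    p = round(p_rec, 10)
    return {"recommended": p, "not_recommended": round(1.0 - p, 10)}


def _treatment_rules() -> list[CPTRule]:
    rules: list[CPTRule] = []
    for t in T_STATES:
        for n in N_STATES:
            for m in M_STATES:
                tnm = {"T": t, "N": n, "M": m}
                cem = _cem_base(t, n, m)
                surg = _surg_base(t, n, m)
                rules.append(CPTRule.make("Cemiplimab", tnm, _treatment_dist(cem)))
                rules.append(CPTRule.make("Surgery", tnm, _treatment_dist(surg)))
                cem_bcc = max(0.01, cem - _BCC_CEM_REDUCTION)
                if cem_bcc != cem:
                    rules.append(
                        CPTRule.make("Cemiplimab", {"Histology": "BCC", **tnm}, _treatment_dist(cem_bcc))
                    )
                if _very_advanced(t, n, m):
                    boosted = min(cem + _CPS_BONUS, 0.99)
                    rules.append(
                        CPTRule.make(
                            "Cemiplimab",
                            {"Histology": "cSCC", "CPS": "positive", **tnm},
                            _treatment_dist(boosted),
                        )
                    )
    return rules


def _prior_rule(node: str, counts: dict[str, int]) -> CPTRule:
    total = sum(counts.values())
    return CPTRule.make(node, {}, {s: c / total for s, c in counts.items()})


def _n_prior_rule() -> CPTRule:
    dist = {s: c / _COHORT_N * (1.0 - _N1_FLOOR) for s, c in _N_COUNTS.items()}
    dist["N1"] = _N1_FLOOR
    return CPTRule.make("N", {}, dist)


def build_reference_model() -> BayesianNetworkModel:
    """Construct the reference network programmatically.

    The shipped ``models/cscc_reference.yaml`` is the serialized form of this
    model; a round-trip test keeps the two in lockstep.
    """
    nodes = [
        NodeSpec("Histology", HISTOLOGY_STATES, group="histology"),
        NodeSpec("T", T_STATES, group="tnm"),
        NodeSpec("N", N_STATES, group="tnm"),
        NodeSpec("M", M_STATES, group="tnm"),
        NodeSpec("CPS", MARKER_STATES, group="pdl1"),
        NodeSpec("TPS", MARKER_STATES, group="pdl1"),
        NodeSpec("Surgery", TREATMENT_STATES, group="treatment"),
        NodeSpec("Cemiplimab", TREATMENT_STATES, group="treatment"),
    ]
    roots = ["Histology", "T", "N", "M", "CPS", "TPS"]
    edges = [EdgeSpec(parent=p, child=c) for c in (SURGERY, CEMIPLIMAB) for p in roots]

    rules = [
        _prior_rule("Histology", _HISTOLOGY_COUNTS),
        _prior_rule("T", _T_COUNTS),
        _n_prior_rule(),
        _prior_rule("M", _M_COUNTS),
        CPTRule.make("CPS", {}, dict(_CPS_PRIOR)),
        CPTRule.make("TPS", {}, dict(_TPS_PRIOR)),
    ]
    rules.extend(_treatment_rules())

    model = BayesianNetworkModel(nodes=nodes, edges=edges, cpt_rules=rules)
    by_name = {n.name: n for n in nodes}
    for node in nodes:
        parent_specs = [by_name[p] for p in model.parents_of(node.name)]
        node_rules = [r for r in rules if r.child == node.name]
        model.cpts[node.name] = compile_cpt(node_rules, node, parent_specs)
    return model


def reference_model_path() -> Path:
    """Filesystem path of the shipped reference model YAML."""
    return Path(resources.files("cscc_bn") / "models" / "cscc_reference.yaml")


# ---------------------------------------------------------------------------
# single-case evidence


@dataclass(frozen=True)
class CaseEvidence:
    """One patient's observable findings.

    T/N/M follow the AJCC/UICC 8th-edition category labels; ``cps`` and
    ``tps`` may be ``"unknown"``, which means the marker was not tested and
    is marginalized during inference (it is *not* a network state).

    Labels are checked by :meth:`validate` (called by
    :func:`case_to_evidence`), not at construction, so that malformed cohort
    rows can be carried through a batch and reported per record.
    """

    histology: str
    t: str
    n: str
    m: str
    cps: str = UNKNOWN
    tps: str = UNKNOWN

    _VOCAB = {
        "histology": HISTOLOGY_STATES,
        "t": T_STATES,
        "n": N_STATES,
        "m": M_STATES,
        "cps": MARKER_STATES + (UNKNOWN,),
        "tps": MARKER_STATES + (UNKNOWN,),
    }

    def validate(self) -> None:
        for fname, vocab in self._VOCAB.items():
            value = getattr(self, fname)
            if value not in vocab:
                raise ModelError(
                    f"field {fname!r}: illegal label {value!r}; expected one of {list(vocab)}"
                )


def case_to_evidence(case: CaseEvidence) -> Evidence:
    """Map a case to network evidence; unknown PD-L1 markers are omitted.

    Raises :class:`ModelError` naming the field and offending value for any
    label outside the case vocabulary.
    """
    case.validate()
    obs = {"Histology": case.histology, "T": case.t, "N": case.n, "M": case.m}
    if case.cps != UNKNOWN:
        obs["CPS"] = case.cps
    if case.tps != UNKNOWN:
        obs["TPS"] = case.tps
    return Evidence.from_map(obs)


# ---------------------------------------------------------------------------
# calibration against the published posteriors


@dataclass(frozen=True)
class CalibrationConstraint:
    """One pinned posterior: evidence, target treatment node, expected
    integer percent (within the 1–99 elicitation band)."""

    label: str
    evidence: CaseEvidence
    target_node: str
    expected_percent: int

    def __post_init__(self) -> None:
        if not 1 <= self.expected_percent <= 99:
            raise ModelError(f"expected_percent {self.expected_percent} outside [1, 99]")


@dataclass
class CalibrationResult:
    constraint: CalibrationConstraint
    computed_percent: int
    passed: bool


#: The ten published posteriors the shipped model reproduces: the advanced
#: and early worked examples plus the three audited discordant patients.
CALIBRATION_CONSTRAINTS: list[CalibrationConstraint] = [
    CalibrationConstraint(
        "advanced cSCC (T4a N3 M0, CPS+/TPS+)",
        CaseEvidence("cSCC", "T4a", "N3", "M0", "positive", "positive"),
        SURGERY,
        60,
    ),
    CalibrationConstraint(
        "advanced cSCC (T4a N3 M0, CPS+/TPS+)",
        CaseEvidence("cSCC", "T4a", "N3", "M0", "positive", "positive"),
        CEMIPLIMAB,
        95,
    ),
    CalibrationConstraint(
        "early cSCC (T1 N0 M0, PD-L1 unknown)",
        CaseEvidence("cSCC", "T1", "N0", "M0"),
        SURGERY,
        99,
    ),
    CalibrationConstraint(
        "early cSCC (T1 N0 M0, PD-L1 unknown)",
        CaseEvidence("cSCC", "T1", "N0", "M0"),
        CEMIPLIMAB,
        1,
    ),
    CalibrationConstraint(
        "patient A (T2 N0 M0, PD-L1 unknown)",
        CaseEvidence("cSCC", "T2", "N0", "M0"),
        SURGERY,
        90,
    ),
    CalibrationConstraint(
        "patient A (T2 N0 M0, PD-L1 unknown)",
        CaseEvidence("cSCC", "T2", "N0", "M0"),
        CEMIPLIMAB,
        5,
    ),
    CalibrationConstraint(
        "patient B (T2 N0 M0, CPS+/TPS-)",
        CaseEvidence("cSCC", "T2", "N0", "M0", "positive", "negative"),
        SURGERY,
        90,
    ),
    CalibrationConstraint(
        "patient B (T2 N0 M0, CPS+/TPS-)",
        CaseEvidence("cSCC", "T2", "N0", "M0", "positive", "negative"),
        CEMIPLIMAB,
        5,
    ),
    CalibrationConstraint(
        "patient C (T3 N2 M0, PD-L1 unknown)",
        CaseEvidence("cSCC", "T3", "N2", "M0"),
        SURGERY,
        70,
    ),
    CalibrationConstraint(
        "patient C (T3 N2 M0, PD-L1 unknown)",
        CaseEvidence("cSCC", "T3", "N2", "M0"),
        CEMIPLIMAB,
        80,
    ),
]


def check_calibration(
    model: BayesianNetworkModel,
    constraints: list[CalibrationConstraint] | None = None,
) -> list[CalibrationResult]:
    """Recompute each pinned posterior and compare after half-up integer
    rounding; failures are report rows, never exceptions."""
    if constraints is None:
        constraints = CALIBRATION_CONSTRAINTS
    results = []
    for c in constraints:
        post = posterior_by_variable_elimination(
            model, case_to_evidence(c.evidence), c.target_node
        )
        pct = round_half_up_percent(post["recommended"])
        results.append(CalibrationResult(c, pct, pct == c.expected_percent))
    return results
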