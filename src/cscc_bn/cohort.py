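"""Reproducible synthetic patient cohorts.

The published 66-patient validation cohort is not deposited, so every
evaluation path in this package is exercised on synthetic cohorts drawn from
the published *marginal* frequencies (histology, T, N, M, PD-L1 status).
Fields are sampled independently — the cohort table reports only marginals,
so independence is the honest default — except that PD-L1 unknown-ness is
drawn once per record and applied to CPS and TPS jointly, because real
PD-L1 testing yields both scores or neither.  An optional coupling knob
upweights nodal involvement in locally advanced tumors for users who want a
more correlated cohort; it defaults off.

Treatment flags come from a configurable policy:

``model_based``
    administered therapy := the model's own primary recommendation, then
    flipped independently per record with probability ``flip_noise`` —
    giving cohorts whose recoverable accuracy is known by construction;
``stage_based``
    Cemiplimab for locally advanced or metastatic disease (T3/T4a/T4b,
    N2/N3, or M1), surgery otherwise;
``fixed_labels``
    caller-supplied flags applied verbatim.

All randomness flows through a single PCG64 generator seeded from the spec,
so identical (spec, seed) pairs give byte-identical cohorts on any platform.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import PatientRecord, predict_cohort
from .network import BayesianNetworkModel, ModelError
from .policy import CEMIPLIMAB, SURGERY
from .reference import UNKNOWN, CaseEvidence

__all__ = [
    "CohortSpec",
    "DEFAULT_MARGINALS",
    "PDL1_UNKNOWN_RATE",
    "generate_cohort",
    "assign_treatments",
    "write_cohort_csv",
    "read_cohort_csv",
    "cohort_to_csv_text",
]

#: Published cohort marginal frequencies (fractions of 66 patients).
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "histology": {"cSCC": 22 / 66, "BCC": 44 / 66},
    "T": {
        "Tx": 1 / 66,
        "T0": 3 / 66,
        "Tis": 4 / 66,
        "T1": 46 / 66,
        "T2": 5 / 66,
        "T3": 4 / 66,
        "T4a": 2 / 66,
        "T4b": 1 / 66,
    },
    "N": {"Nx": 48 / 66, "N0": 11 / 66, "N1": 0.0, "N2": 1 / 66, "N3": 6 / 66},
    "M": {"Mx": 45 / 66, "M0": 20 / 66, "M1": 1 / 66},
    # conditional on the marker having been tested
    "CPS_known": {"positive": 1.0, "negative": 0.0},
    "TPS_known": {"positive": 5 / 7, "negative": 2 / 7},
}

#: 59 of 66 patients had no PD-L1 testing; unknown-ness hits CPS and TPS jointly.
PDL1_UNKNOWN_RATE = 59 / 66

CSV_COLUMNS = [
    "patient_id",
    "histology",
    "T",
    "N",
    "M",
    "CPS",
    "TPS",
    "surgery_given",
    "cemiplimab_given",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    ``flip_noise`` applies to the model_based policy only; ``coupling``
    switches on the optional T–N advanced-disease association.
    """

    n: int = 66
    seed: int = 0
    marginals: dict[str, dict[str, float]] = field(default_factory=lambda: DEFAULT_MARGINALS)
    pdl1_unknown_rate: float = PDL1_UNKNOWN_RATE
    treatment_policy: str = "stage_based"
    flip_noise: float = 0.0
    coupling: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ModelError(f"cohort size must be positive, got {self.n}")
        if not 0.0 <= self.flip_noise <= 0.5:
            raise ModelError(f"flip_noise {self.flip_noise} outside [0, 0.5]")
        if self.treatment_policy not in ("model_based", "stage_based", "fixed_labels"):
            raise ModelError(f"unknown treatment policy {self.treatment_policy!r}")
        for var, dist in self.marginals.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ModelError(f"marginal for {var!r} sums to {total:.8g}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ModelError(f"marginal for {var!r} has a negative frequency")


def _draw(rng: np.random.Generator, dist: dict[str, float], size: int) -> list[str]:
    labels = list(dist.keys())
    probs = np.array([dist[s] for s in labels], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=size, p=probs)
    return [labels[i] for i in idx]


def generate_cohort(
    spec: CohortSpec, model: BayesianNetworkModel | None = None
) -> list[PatientRecord]:
    """Draw ``spec.n`` records and assign treatments per the spec's policy.

    ``model`` is required for the model_based policy.  Identical spec and
    seed give bit-identical cohorts.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    m = spec.marginals
    hist = _draw(rng, m["histology"], spec.n)
    t = _draw(rng, m["T"], spec.n)
    n_cat = _draw(rng, m["N"], spec.n)
    if spec.coupling:
        # upweight nodal involvement for locally advanced primaries
        for i in range(spec.n):
            if t[i] in ("T3", "T4a", "T4b") and rng.random() < 0.35:
                n_cat[i] = "N2" if rng.random() < 0.4 else "N3"
    m_cat = _draw(rng, m["M"], spec.n)

    unknown = rng.random(spec.n) < spec.pdl1_unknown_rate
    cps_known = _draw(rng, m["CPS_known"], spec.n)
    tps_known = _draw(rng, m["TPS_known"], spec.n)
    cps = [UNKNOWN if u else v for u, v in zip(unknown, cps_known)]
    tps = [UNKNOWN if u else v for u, v in zip(unknown, tps_known)]

    records = [
        PatientRecord(
            patient_id=f"P{i + 1:04d}",
            case=CaseEvidence(hist[i], t[i], n_cat[i], m_cat[i], cps[i], tps[i]),
            surgery_given=False,
            cemiplimab_given=False,
            excluded=False,
        )
        for i in range(spec.n)
    ]
    treatment_seed = int(rng.integers(0, 2**31 - 1))
    return assign_treatments(
        records,
        spec.treatment_policy,
        model=model,
        seed=treatment_seed,
        flip_noise=spec.flip_noise,
    )


def _stage_based_cemiplimab(case: CaseEvidence) -> bool:
    return case.t in ("T3", "T4a", "T4b") or case.n in ("N2", "N3") or case.m == "M1"


def assign_treatments(
    records: list[PatientRecord],
    policy: str,
    model: BayesianNetworkModel | None = None,
    seed: int = 0,
    flip_noise: float = 0.0,
    labels: list[tuple[bool, bool]] | None = None,
) -> list[PatientRecord]:
    """Return copies of ``records`` with treatment flags set by ``policy``."""
    if policy == "fixed_labels":
        if labels is None or len(labels) != len(records):
            raise ModelError("fixed_labels policy needs one (surgery, cemiplimab) pair per record")
        return [
            replace(r, surgery_given=s, cemiplimab_given=c)
            for r, (s, c) in zip(records, labels)
        ]

    if policy == "stage_based":
        out = []
        for r in records:
            cem = _stage_based_cemiplimab(r.case)
            out.append(replace(r, surgery_given=not cem, cemiplimab_given=cem))
        return out

    if policy == "model_based":
        if model is None:
            raise ModelError("model_based policy requires a model")
        rng = np.random.Generator(np.random.PCG64(seed))
        predictions = predict_cohort(model, records)
        out = []
        for r, p in zip(records, predictions):
            if not p.ok:
                out.append(replace(r, excluded=True))
                continue
            primary = p.recommendation.primary
            if flip_noise > 0.0 and rng.random() < flip_noise:
                primary = CEMIPLIMAB if primary == SURGERY else SURGERY
            out.append(
                replace(
                    r,
                    surgery_given=primary == SURGERY,
                    cemiplimab_given=primary == CEMIPLIMAB,
                )
            )
        return out

    raise ModelError(f"unknown treatment policy {policy!r}")


# ---------------------------------------------------------------------------
# CSV round-trip


def _records_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "histology": r.case.histology,
            "T": r.case.t,
            "N": r.case.n,
            "M": r.case.m,
            "CPS": r.case.cps,
            "TPS": r.case.tps,
            "surgery_given": int(r.surgery_given),
            "cemiplimab_given": int(r.cemiplimab_given),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def cohort_to_csv_text(records: list[PatientRecord]) -> str:
    buf = io.StringIO()
    _records_frame(records).to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue()


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    Path(path).write_text(cohort_to_csv_text(records))


def read_cohort_csv(path_or_buffer) -> list[PatientRecord]:
    """Read a cohort CSV back into records (lossless round-trip)."""
    df = pd.read_csv(path_or_buffer, dtype=str).fillna("")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ModelError(f"cohort CSV is missing column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                case=CaseEvidence(
                    row["histology"], row["T"], row["N"], row["M"], row["CPS"], row["TPS"]
                ),
                surgery_given=row["surgery_given"] in ("1", "True", "true"),
                cemiplimab_given=row["cemiplimab_given"] in ("1", "True", "true"),
            )
        )
    return records
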