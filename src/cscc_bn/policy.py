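"""Turn the two treatment posteriors into a clinical recommendation.

The comparison rule is deliberately simple: the treatment with the higher
posterior probability is the primary suggestion, the other is subordinate.
Reported probabilities are clamped to the 1–99% band used when the model's
tables were elicited — the model never claims certainty in either direction.
Exact ties break toward surgery, the typical primary treatment for resectable
skin cancer; tied outputs are flagged so downstream consumers can see that
the ordering was conventional rather than computed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Recommendation", "clamp_probability", "recommend", "round_half_up_percent"]

SURGERY = "Surgery"
CEMIPLIMAB = "Cemiplimab"


def clamp_probability(p: float) -> float:
    """Clamp a probability into [0.01, 0.99] (the 1–99% reporting band)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p!r} outside [0, 1]")
    return min(max(p, 0.01), 0.99)


def round_half_up_percent(p: float) -> int:
    """Convert a probability to an integer percent, rounding halves up."""
    import math

    return int(math.floor(p * 100.0 + 0.5))


@dataclass(frozen=True)
class Recommendation:
    """A two-option treatment recommendation.

    ``surgery_percent`` / ``cemiplimab_percent`` are the clamped, half-up
    rounded posteriors; ``raw_surgery`` / ``raw_cemiplimab`` preserve the
    unclamped posteriors for traceability.  ``margin`` is the absolute
    percent difference between the two options.
    """

    surgery_percent: int
    cemiplimab_percent: int
    primary: str
    subordinate: str
    margin: int
    tie_break: bool
    raw_surgery: float
    raw_cemiplimab: float

    def as_dict(self) -> dict:
        return {
            "surgery_percent": self.surgery_percent,
            "cemiplimab_percent": self.cemiplimab_percent,
            "primary": self.primary,
            "subordinate": self.subordinate,
            "margin": self.margin,
            "tie_break": self.tie_break,
            "raw_surgery": self.raw_surgery,
            "raw_cemiplimab": self.raw_cemiplimab,
        }


def recommend(surgery_p: float, cemiplimab_p: float) -> Recommendation:
    """Compare the two treatment posteriors and pick the primary option.

    Both inputs are clamped to [0.01, 0.99] before comparison.  The option
    with the strictly higher clamped probability is primary; an exact tie
    goes to surgery (and is flagged via ``tie_break``).
    """
    s = clamp_probability(surgery_p)
    c = clamp_probability(cemiplimab_p)
    tie = s == c
    primary = SURGERY if s >= c else CEMIPLIMAB
    subordinate = CEMIPLIMAB if primary == SURGERY else SURGERY
    sp = round_half_up_percent(s)
    cp = round_half_up_percent(c)
    return Recommendation(
        surgery_percent=sp,
        cemiplimab_percent=cp,
        primary=primary,
        subordinate=subordinate,
        margin=abs(sp - cp),
        tie_break=tie,
        raw_surgery=surgery_p,
        raw_cemiplimab=cemiplimab_p,
    )
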