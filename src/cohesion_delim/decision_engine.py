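"""Cohesion-species decision rules combining geography, clustering, and niche tests.

Genetic exchangeability (GE) is rejected when an allopatric lineage pair shows
separate molecular clustering, or a parapatric pair shows separate clustering
*and* has an asserted barrier to gene flow.  Ecological interchangeability
(EI) is rejected only when the equivalency test rejects identity and every
consulted similarity direction indicates niche divergence.  The species-status
conclusion then follows a stated policy: ``conservative_both`` requires both
rejections; ``flowchart_either`` treats either rejection as sufficient.

All decision functions are pure: identical inputs always give identical
verdicts, and each verdict carries an evidence trail naming the rule that
fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

GEOGRAPHIES = ("allopatric", "parapatric", "sympatric")
POLICIES = ("conservative_both", "flowchart_either")
SIMILARITY_OUTCOMES = ("conservatism", "divergence", "not_significant")

__all__ = [
    "LineagePairAssessment",
    "CohesionDecision",
    "assess_ge",
    "assess_ei",
    "delimit",
    "build_table2",
]


@dataclass
class LineagePairAssessment:
    """All evidence for one lineage pair, as consumed by the decision rules.

    ``molecular_verdicts`` maps dataset name (e.g. ``vae_90p``) to
    ``"separate"`` or ``"overlapping"``; ``similarity_outcomes`` maps
    background method to a mapping of direction label -> outcome.
    """

    pair: tuple[str, str]
    geography: str  # allopatric | parapatric | sympatric
    barrier_present: bool = False
    barrier_name: str = ""
    morphology_verdict: str | None = None  # recorded, never decisive
    molecular_verdicts: Mapping[str, str] = field(default_factory=dict)
    niche_overlap_d: float | None = None
    equivalency_outcome: str | None = None  # not_equivalent | not_significant
    similarity_outcomes: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    n_a: int | None = None
    n_b: int | None = None
    reproductive_isolation_asserted: bool = False

    def __post_init__(self) -> None:
        if self.geography not in GEOGRAPHIES:
            raise ValueError(f"geography must be one of {GEOGRAPHIES}, got {self.geography!r}")


@dataclass
class CohesionDecision:
    pair: tuple[str, str]
    ge: str  # "rejected" | "not rejected"
    ei: str
    conclusion: str  # "separate cohesion species" | "single species"
    policy: str
    evidence: list[str]


def _aggregate_molecular(verdicts: Mapping[str, str]) -> tuple[str, str]:
    """Majority vote across molecular datasets; ties fall to 'overlapping'."""
    if not verdicts:
        raise ValueError("at least one molecular clustering verdict is required")
    n_sep = sum(v == "separate" for v in verdicts.values())
    n_ovl = len(verdicts) - n_sep
    agg = "separate" if n_sep > n_ovl else "overlapping"
    detail = f"molecular verdicts {dict(verdicts)} -> majority '{agg}'"
    return agg, detail


def assess_ge(a: LineagePairAssessment) -> tuple[str, list[str]]:
    """Genetic-exchangeability verdict plus its evidence trail.

    Rejected iff (allopatric AND separate clustering) OR (parapatric AND
    separate clustering AND barrier present).  Sympatric pairs reject only
    under separate clustering plus a user-asserted reproductive-isolation
    flag (an extension beyond the source rule, which never met sympatry).
    Morphology is recorded but non-decisive.
    """
    if not a.geography:
        raise ValueError("geographic relationship is required")
    mol, detail = _aggregate_molecular(a.molecular_verdicts)
    trail = [detail, f"geography = {a.geography}"]
    if a.morphology_verdict is not None:
        trail.append(f"morphology = {a.morphology_verdict} (recorded, non-decisive)")
    if a.geography == "allopatric" and mol == "separate":
        trail.append("rule: allopatric + separate clustering -> reject GE")
        return "rejected", trail
    if a.geography == "parapatric" and mol == "separate" and a.barrier_present:
        trail.append(
            f"rule: parapatric + separate clustering + barrier ({a.barrier_name or 'unnamed'})"
            " -> reject GE"
        )
        return "rejected", trail
    if (
        a.geography == "sympatric"
        and mol == "separate"
        and a.reproductive_isolation_asserted
    ):
        trail.append("rule: sympatric + separate clustering + asserted isolation -> reject GE")
        return "rejected", trail
    trail.append("rule: conditions for rejecting GE not met -> fail to reject")
    return "not rejected", trail


def assess_ei(
    a: LineagePairAssessment,
    background_method: str = "thresh75",
) -> tuple[str, list[str]]:
    """Ecological-interchangeability verdict for one background method.

    Rejected iff the equivalency test found the niches not equivalent AND
    every similarity direction under the chosen background method shows
    divergence; any conservatism or non-significant direction fails to
    reject.
    """
    missing = []
    if a.equivalency_outcome is None:
        missing.append("equivalency outcome")
    sims = a.similarity_outcomes.get(background_method)
    if not sims:
        missing.append(f"similarity outcomes for background {background_method!r}")
    if missing:
        raise ValueError("missing inputs: " + ", ".join(missing))
    trail = [
        f"equivalency = {a.equivalency_outcome}",
        f"similarity[{background_method}] = {dict(sims)}",
    ]
    if a.equivalency_outcome == "not_equivalent" and all(
        v == "divergence" for v in sims.values()
    ):
        trail.append("rule: non-equivalent + all-direction divergence -> reject EI")
        return "rejected", trail
    trail.append("rule: conditions for rejecting EI not met -> fail to reject")
    return "not rejected", trail


def delimit(
    ge: str,
    ei: str,
    policy: str = "conservative_both",
    pair: tuple[str, str] = ("A", "B"),
    evidence: Sequence[str] = (),
) -> CohesionDecision:
    """Combine GE and EI verdicts into a species-status conclusion."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    for name, v in (("GE", ge), ("EI", ei)):
        if v not in ("rejected", "not rejected"):
            raise ValueError(f"{name} verdict must be 'rejected' or 'not rejected', got {v!r}")
    if policy == "conservative_both":
        separate = ge == "rejected" and ei == "rejected"
        rule = "conservative_both: separate species iff GE rejected AND EI rejected"
    else:
        separate = ge == "rejected" or ei == "rejected"
        rule = "flowchart_either: separate species iff GE rejected OR EI rejected"
    conclusion = "separate cohesion species" if separate else "single species"
    trail = list(evidence) + [rule, f"GE = {ge}; EI = {ei} -> {conclusion}"]
    return CohesionDecision(
        pair=pair, ge=ge, ei=ei, conclusion=conclusion, policy=policy, evidence=trail
    )


def build_table2(
    assessments: Sequence[LineagePairAssessment],
    policy: str = "conservative_both",
    background_method: str = "thresh75",
):
    """Summary table mirroring the published assessment layout.

    One row per lineage pair with the GE evidence columns, the EI evidence
    columns, and the policy conclusion.  Returns a pandas DataFrame (empty
    with headers for an empty input).
    """
    import pandas as pd

    columns = [
        "comparison",
        "geography",
        "barrier",
        "morphology",
        "molecular_clustering",
        "ge_conclusion",
        "n_a",
        "n_b",
        "niche_overlap_d",
        "equivalency",
        "similarity",
        "ei_conclusion",
        "species_conclusion",
        "policy",
    ]
    rows = []
    for a in assessments:
        ge, ge_trail = assess_ge(a)
        ei, ei_trail = assess_ei(a, background_method)
        decision = delimit(ge, ei, policy, pair=a.pair, evidence=ge_trail + ei_trail)
        mol, _ = _aggregate_molecular(a.molecular_verdicts)
        sims = a.similarity_outcomes.get(background_method, {})
        rows.append(
            {
                "comparison": f"{a.pair[0]} to {a.pair[1]}",
                "geography": a.geography,
                "barrier": a.barrier_name if a.barrier_present else "none",
                "morphology": a.morphology_verdict or "unavailable",
                "molecular_clustering": mol,
                "ge_conclusion": f"{'Reject' if ge == 'rejected' else 'Fail to reject'} GE",
                "n_a": a.n_a,
                "n_b": a.n_b,
                "niche_overlap_d": a.niche_overlap_d,
                "equivalency": a.equivalency_outcome,
                "similarity": "; ".join(f"{k}: {v}" for k, v in sims.items()),
                "ei_conclusion": f"{'Reject' if ei == 'rejected' else 'Fail to reject'} EI",
                "species_conclusion": decision.conclusion,
                "policy": policy,
            }
        )
    return pd.DataFrame(rows, columns=columns)
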