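"""Risk / resilience classification of significant variants.

A variant enriched in the cohort relative to the reference is a candidate
risk allele; a depleted one a candidate resilience allele.  The call is
made only when at least one line of damaging evidence supports it: a
deleterious SIFT prediction, a possibly/probably damaging PolyPhen2
prediction, a CADD phred score strictly above 10, or a curated literature
association.  Variants with no supporting evidence remain
``candidate_only``.

The literature step of such determinations is inherently manual; here it is
explicit data (the ``literature_flag`` and ``allele_role`` annotation
columns) rather than hidden judgment.  ``allele_role`` records whether the
tested allele is itself the putative risk allele or a known protective
allele — for a protective allele, depletion in the cohort is reported as
loss of protection, but the call direction still follows enrichment
(enriched -> risk, depleted -> resilience).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CADD_DAMAGING_CUTOFF", "EvidenceFlags", "evidence_flags", "classify", "RiskCall", "classify_results"]

#: CADD phred scores strictly above this are treated as potentially damaging.
CADD_DAMAGING_CUTOFF = 10.0


@dataclass(frozen=True)
class EvidenceFlags:
    """Damaging-evidence booleans plus the curated literature flag."""

    sift_damaging: bool
    polyphen_damaging: bool
    cadd_damaging: bool
    literature_flag: str = "none"

    @property
    def any_evidence(self) -> bool:
        return (
            self.sift_damaging
            or self.polyphen_damaging
            or self.cadd_damaging
            or self.literature_flag != "none"
        )


def evidence_flags(
    sift: str = "NA",
    polyphen: str = "NA",
    cadd_phred: float | None = None,
    literature_flag: str = "none",
    cadd_cutoff: float = CADD_DAMAGING_CUTOFF,
) -> EvidenceFlags:
    """Derive damaging-evidence flags from annotation values.

    SIFT counts when "deleterious"; PolyPhen2 when possibly or probably
    damaging; CADD when present and strictly greater than the cutoff
    (a score of exactly 10 does not count).
    """
    cadd = cadd_phred is not None and not (isinstance(cadd_phred, float) and np.isnan(cadd_phred)) and cadd_phred > cadd_cutoff
    return EvidenceFlags(
        sift_damaging=sift == "deleterious",
        polyphen_damaging=polyphen in ("possibly_damaging", "probably_damaging"),
        cadd_damaging=bool(cadd),
        literature_flag=literature_flag,
    )


@dataclass(frozen=True)
class RiskCall:
    """Classification outcome for one variant."""

    key: str
    call: str  # risk | resilience | candidate_only
    direction: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.call in ("risk", "resilience") and not self.rationale:
            raise ValueError("risk/resilience calls require a nonempty rationale")


def classify(
    direction: str,
    tested_allele_role: str,
    flags: EvidenceFlags,
    key: str = "",
) -> RiskCall:
    """Apply the risk/resilience rule table.

    Rule table (requires at least one evidence flag):
      * enriched  + risk allele       -> risk
      * enriched  + protective allele -> risk (protective allele enriched:
        a risk-direction signal, noted in the rationale)
      * depleted  + risk allele       -> resilience
      * depleted  + protective allele -> resilience (protective allele
        reduced: loss of protection, noted in the rationale)
    Without evidence, or when frequencies are exactly equal, the variant
    stays candidate_only.
    """
    if direction not in ("enriched", "depleted", "equal"):
        raise ValueError(f"unknown direction {direction!r}")
    if tested_allele_role not in ("risk_allele", "protective_allele", "unknown"):
        raise ValueError(f"unknown tested_allele_role {tested_allele_role!r}")
    role = "risk_allele" if tested_allele_role == "unknown" else tested_allele_role
    if direction == "equal" or not flags.any_evidence:
        reason = "cohort and reference frequencies equal" if direction == "equal" else "no damaging evidence"
        return RiskCall(key, "candidate_only", direction, (reason,))

    if direction == "enriched":
        call = "risk"
        branch = (
            "tested risk allele enriched in cohort"
            if role == "risk_allele"
            else "protective allele enriched in cohort (risk-direction signal)"
        )
    else:
        call = "resilience"
        branch = (
            "tested risk allele depleted in cohort"
            if role == "risk_allele"
            else "protective allele reduced in cohort (loss of protection)"
        )
    rationale = [branch]
    if flags.sift_damaging:
        rationale.append("SIFT deleterious")
    if flags.polyphen_damaging:
        rationale.append("PolyPhen2 possibly/probably damaging")
    if flags.cadd_damaging:
        rationale.append(f"CADD > {CADD_DAMAGING_CUTOFF:g}")
    if flags.literature_flag != "none":
        rationale.append(f"literature: {flags.literature_flag}")
    return RiskCall(key, call, direction, tuple(rationale))


def classify_results(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    cadd_cutoff: float = CADD_DAMAGING_CUTOFF,
) -> pd.DataFrame:
    """Attach calls and rationales to an enrichment results frame.

    ``results`` is indexed by variant key with a ``direction`` column;
    ``annotations`` is the annotation frame from
    :func:`fasdvar.variants.read_annotations`.  Variants without an
    annotation row get default (all-NA) evidence and role, hence
    candidate_only.  Returns a copy with ``call`` and ``rationale`` columns.
    """
    calls, rationales = [], []
    for key, row in results.iterrows():
        if key in annotations.index:
            ann = annotations.loc[key]
            flags = evidence_flags(
                ann["sift"], ann["polyphen"], ann["cadd_phred"], ann["literature_flag"], cadd_cutoff
            )
            role = ann["allele_role"]
        else:
            flags = evidence_flags()
            role = "risk_allele"
        rc = classify(row["direction"], role, flags, key=key)
        calls.append(rc.call)
        rationales.append("; ".join(rc.rationale))
    out = results.copy()
    out["call"] = calls
    out["rationale"] = rationales
    return out
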