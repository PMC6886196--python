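"""Rule-based PCOM classifier implementing the Rotterdam volume arm.

Per ovary, in order of precedence: an explicit classical-PCOM phrase
("numerous peripheral follicles", "string of pearls") is sufficient for
PCOM-present at any volume; an unmentioned or unmeasured ovary is
unidentifiable; a volume above the 10 ml cutoff with a volume confounder
(dominant follicle, corpus luteum, dermoid, hemorrhagic cyst, ...) is
unidentifiable — the enlargement may not be stromal, and the Rotterdam
consensus advises a repeat scan; above the cutoff without a confounder
is present; at or below the cutoff, absent. A report is PCOM-present if
at least one ovary is; otherwise unidentifiable outranks absent, since
PCOM in an unassessed ovary cannot be excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .contextualizer import SIDES, build_ovary_documents
from .termmining import TermList, count_term_hits, default_term_lists
from .textprep import RawReport

__all__ = [
    "PCOMLabel",
    "RuleConfig",
    "OvaryCall",
    "ReportCall",
    "classify_ovary",
    "aggregate_report",
    "classify_report_rbc",
]

LABELS = ("absent", "unidentifiable", "present")


class PCOMLabel(str, enum.Enum):
    """Three-way polycystic ovary morphology determination."""

    ABSENT = "absent"
    UNIDENTIFIABLE = "unidentifiable"
    PRESENT = "present"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


@dataclass
class RuleConfig:
    """Tunables of the rule engine."""

    volume_cutoff_ml: float = 10.0
    confounder_list: TermList = field(
        default_factory=lambda: default_term_lists()["confounder"]
    )
    pcom_list: TermList = field(
        default_factory=lambda: default_term_lists()["pcom_phrase"]
    )

    def __post_init__(self) -> None:
        if self.volume_cutoff_ml <= 0:
            raise ValueError("volume_cutoff_ml must be positive")


@dataclass(frozen=True)
class OvaryCall:
    """Per-ovary decision with a machine-readable reason code."""

    side: str
    label: PCOMLabel
    volume_ml: float | None
    confounder_hit: bool
    pcom_phrase_hit: bool
    reason: str


def classify_ovary(
    volume_ml: float | None,
    confounder_hit: bool,
    pcom_phrase_hit: bool,
    mention_found: bool,
    cfg: RuleConfig,
    side: str = "left",
) -> OvaryCall:
    """Apply the per-ovary rule table; first matching rule wins."""
    if pcom_phrase_hit:
        label, reason = PCOMLabel.PRESENT, "PHRASE"
    elif not mention_found or volume_ml is None:
        label, reason = PCOMLabel.UNIDENTIFIABLE, (
            "NO_MENTION" if not mention_found else "NO_VOLUME"
        )
    elif volume_ml > cfg.volume_cutoff_ml and confounder_hit:
        label, reason = PCOMLabel.UNIDENTIFIABLE, "CONFOUNDED"
    elif volume_ml > cfg.volume_cutoff_ml:
        label, reason = PCOMLabel.PRESENT, "VOL_GT_CUTOFF_NO_CONFOUNDER"
    else:
        label, reason = PCOMLabel.ABSENT, "VOL_LE_CUTOFF"
    return OvaryCall(
        side=side,
        label=label,
        volume_ml=volume_ml,
        confounder_hit=confounder_hit,
        pcom_phrase_hit=pcom_phrase_hit,
        reason=reason,
    )


_PRECEDENCE = {
    PCOMLabel.PRESENT: 2,
    PCOMLabel.UNIDENTIFIABLE: 1,
    PCOMLabel.ABSENT: 0,
}


def aggregate_report(left: PCOMLabel, right: PCOMLabel) -> PCOMLabel:
    """Combine per-ovary labels: present > unidentifiable > absent."""
    return left if _PRECEDENCE[left] >= _PRECEDENCE[right] else right


@dataclass(frozen=True)
class ReportCall:
    """Full per-report decision of the rule-based classifier."""

    report_id: str
    left: OvaryCall
    right: OvaryCall
    overall: PCOMLabel


def classify_report_rbc(
    report: RawReport,
    cfg: RuleConfig | None = None,
    stopwords: frozenset[str] | None = None,
) -> ReportCall:
    """Classify one raw report end to end (deterministic).

    Composes cleaning, contextualization, laterality, volume extraction
    and term detection, then the rule table per ovary and the report
    aggregation. Term hits are counted over the whole per-ovary document
    (follower sentences carry the cyst descriptions).
    """
    if cfg is None:
        cfg = RuleConfig()
    docs = build_ovary_documents(report, stopwords)
    calls: dict[str, OvaryCall] = {}
    for side in SIDES:
        doc = docs[side]
        confounder = count_term_hits(doc.token_sentences, cfg.confounder_list) > 0
        phrase = count_term_hits(doc.token_sentences, cfg.pcom_list) > 0
        calls[side] = classify_ovary(
            volume_ml=doc.volume_ml,
            confounder_hit=confounder,
            pcom_phrase_hit=phrase,
            mention_found=doc.mention_found,
            cfg=cfg,
            side=side,
        )
    overall = aggregate_report(calls["left"].label, calls["right"].label)
    return ReportCall(
        report_id=report.report_id,
        left=calls["left"],
        right=calls["right"],
        overall=overall,
    )
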