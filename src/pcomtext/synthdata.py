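"""Seeded generator of synthetic pelvic-ultrasound report text.

The real EMR corpus behind this method is private, so experiments run on
synthetic reports that emulate its structure: dictated prose with uterus
and kidney distractor sentences, per-ovary measurement sentences with
1-decimal diameters in cm or integer mm, classical polycystic-morphology
phrases, volume-confounder mentions, unmeasured or unmentioned ovaries,
and dictation typos inside measurement strings.

Per-ovary truth labels are fixed by construction before any text noise:
dimensions are sampled, checked against the ellipsoid formula and the
10 ml cutoff, and recorded in a generation trace from which the truth
can be re-derived with the rule engine. The global ``p_typo`` rate then
corrupts the *text* of a measured ovary without touching its truth —
this emulates transcription noise, where the dictated measurement was
real but the written record is unusable, and is what degrades
classifier accuracy as noise increases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .rbc import PCOMLabel, RuleConfig, aggregate_report, classify_ovary
from .textprep import RawReport

__all__ = ["SynthConfig", "OvaryTrace", "SynthRecord", "generate_corpus", "noiseless_config"]

_PI6 = math.pi / 6.0


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults mirror the documented study corpus.

    ``class_mix`` follows the published full-corpus marginals (44% / 32%
    / 24%). The unidentifiable arms (confounded volume, no mention,
    2-D-only, garbled measurement) are weighted by the corresponding
    rates, renormalized. ``p_typo`` is the post-hoc dictation-noise rate
    on measured ovaries; 0.03 keeps rule-based accuracy in the
    mid-90s range the method reports on real text.
    """

    n_reports: int = 1000
    class_mix: tuple[float, float, float] = (0.44, 0.32, 0.24)  # absent/unident/present
    p_mm_units: float = 0.2
    p_missing_unit: float = 0.1
    p_2d_only: float = 0.2
    p_no_ovary_mention: float = 0.3
    p_typo: float = 0.03
    p_confounder_given_large: float = 0.3
    p_pcom_phrase_given_present: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for name in (
            "p_mm_units",
            "p_missing_unit",
            "p_2d_only",
            "p_no_ovary_mention",
            "p_typo",
            "p_confounder_given_large",
            "p_pcom_phrase_given_present",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def noiseless_config(n_reports: int = 1000, seed: int = 0) -> SynthConfig:
    """Canonical phrasing, explicit cm units, fully measured ovaries."""
    return SynthConfig(
        n_reports=n_reports,
        p_mm_units=0.0,
        p_missing_unit=0.0,
        p_2d_only=0.0,
        p_no_ovary_mention=0.4,
        p_typo=0.0,
        p_confounder_given_large=0.6,
        seed=seed,
    )


@dataclass(frozen=True)
class OvaryTrace:
    """What was dictated for one ovary, before any text corruption."""

    arm: str
    mention_found: bool
    dims_cm: tuple[float, ...] | None  # 3-D only when a volume exists
    unit: str | None  # cm | mm | None (unit omitted in text)
    confounder: bool
    phrase: bool
    typo: bool = False

    @property
    def volume_ml(self) -> float | None:
        if self.dims_cm is None or len(self.dims_cm) != 3:
            return None
        return math.prod(self.dims_cm) * _PI6

    def derive_label(self, cfg: RuleConfig | None = None) -> PCOMLabel:
        """Re-run the rule table on the trace (truth by construction)."""
        if cfg is None:
            cfg = RuleConfig()
        return classify_ovary(
            self.volume_ml, self.confounder, self.phrase, self.mention_found, cfg
        ).label


@dataclass(frozen=True)
class SynthRecord:
    """One synthetic report with its ground truth and generation trace."""

    report: RawReport
    truth_left: PCOMLabel
    truth_right: PCOMLabel
    truth_overall: PCOMLabel
    trace_left: OvaryTrace
    trace_right: OvaryTrace


_CONFOUNDERS = (
    "a dominant follicle",
    "a corpus luteum",
    "a dermoid cyst",
    "a hemorrhagic cyst",
    "a simple cyst",
    "a complex cyst",
)

_PCOM_PHRASES = (
    "numerous peripheral follicles",
    "multiple small follicles in a string of pearls orientation",
    "a polycystic ovarian appearance",
)

_LEAD_DISTRACTORS = (
    "the uterus is anteverted and normal in size, measuring {u1} x {u2} x {u3} cm.",
    "the uterus is retroverted and measures {u1} x {u2} x {u3} cm.",
    "the endometrial stripe is thin and homogeneous.",
    "the uterus appears unremarkable.",
)

_TAIL_DISTRACTORS = (
    "the kidneys are unremarkable.",
    "no free fluid is seen in the pelvis.",
    "no adnexal mass is identified.",
    "the bladder is partially distended.",
)


def _round1(x: float) -> float:
    return float(np.round(x, 1))


def _sample_dims(rng: np.random.Generator, lo: float, hi: float,
                 vol_lo: float, vol_hi: float) -> tuple[float, ...]:
    """Rejection-sample three 1-decimal diameters with volume in range."""
    while True:
        dims = tuple(_round1(v) for v in rng.uniform(lo, hi, size=3))
        vol = math.prod(dims) * _PI6
        if vol_lo <= vol <= vol_hi and all(d > 0 for d in dims):
            return dims


def _dims_text(dims: tuple[float, ...], unit: str | None, rng: np.random.Generator) -> str:
    if unit == "mm":
        parts = [f"{int(round(d * 10))}" for d in dims]
        suffix = " mm"
    else:
        parts = [f"{d:g}" for d in dims]
        suffix = " cm" if unit == "cm" else ""
    sep = " x " if rng.random() < 0.5 else "x"
    return sep.join(parts) + suffix


def _garble(text: str, rng: np.random.Generator) -> str:
    """Dictation typo inside a measurement: break the first separator."""
    i = text.find("x")
    if i < 0:
        return text
    return text[:i] + "." + text[i:]


def _choose_unit(cfg: SynthConfig, rng: np.random.Generator) -> str | None:
    u = rng.random()
    if u < cfg.p_mm_units:
        return "mm"
    if u < cfg.p_mm_units + cfg.p_missing_unit:
        return None
    return "cm"


def _sample_ovary(
    target: PCOMLabel, side: str, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[list[str], OvaryTrace]:
    """Sentences and trace for one ovary with the requested truth label."""
    if target is PCOMLabel.ABSENT:
        dims = _sample_dims(rng, 1.8, 4.0, 1.0, 9.7)
        unit = _choose_unit(cfg, rng)
        trace = OvaryTrace("absent_measured", True, dims, unit, False, False)
        sents = [f"the {side} ovary measures {_dims_text(dims, unit, rng)}."]
        if rng.random() < 0.3:
            sents.append("it has a normal sonographic appearance.")
        return sents, trace

    if target is PCOMLabel.PRESENT:
        if rng.random() < cfg.p_pcom_phrase_given_present:
            phrase = _PCOM_PHRASES[rng.integers(len(_PCOM_PHRASES))]
            if rng.random() < 0.5:
                dims = _sample_dims(rng, 1.8, 4.0, 1.0, 9.7)
                unit = _choose_unit(cfg, rng)
                trace = OvaryTrace("present_phrase", True, dims, unit, False, True)
                sents = [
                    f"the {side} ovary measures {_dims_text(dims, unit, rng)}.",
                    f"it contains {phrase}.",
                ]
            else:
                trace = OvaryTrace("present_phrase", True, None, None, False, True)
                sents = [f"the {side} ovary demonstrates {phrase}."]
            return sents, trace
        dims = _sample_dims(rng, 2.4, 5.2, 10.4, 60.0)
        unit = _choose_unit(cfg, rng)
        trace = OvaryTrace("present_volume", True, dims, unit, False, False)
        # usually plain "measures" phrasing: size must be read from the
        # numbers, not from a lexical giveaway
        template = (
            f"the {side} ovary measures {{m}}."
            if rng.random() < 0.7
            else f"the {side} ovary is enlarged, measuring {{m}}."
        )
        return [template.format(m=_dims_text(dims, unit, rng))], trace

    # target is UNIDENTIFIABLE: weighted arms
    weights = np.array(
        [
            cfg.p_confounder_given_large,
            cfg.p_no_ovary_mention,
            cfg.p_2d_only,
            max(
                1.0
                - cfg.p_confounder_given_large
                - cfg.p_no_ovary_mention
                - cfg.p_2d_only,
                0.0,
            ),
        ]
    )
    if weights.sum() == 0:
        weights = np.array([1.0, 0.0, 0.0, 0.0])
    arm = ("confounded", "no_mention", "2d_only", "garbled")[
        rng.choice(4, p=weights / weights.sum())
    ]
    if arm == "confounded":
        dims = _sample_dims(rng, 2.4, 5.2, 10.4, 60.0)
        unit = _choose_unit(cfg, rng)
        confounder = _CONFOUNDERS[rng.integers(len(_CONFOUNDERS))]
        trace = OvaryTrace("confounded", True, dims, unit, True, False)
        template = (
            f"the {side} ovary measures {{m}}."
            if rng.random() < 0.7
            else f"the {side} ovary is enlarged, measuring {{m}}."
        )
        sents = [
            template.format(m=_dims_text(dims, unit, rng)),
            f"there is {confounder} within it.",
        ]
        return sents, trace
    if arm == "no_mention":
        if rng.random() < 0.5:
            trace = OvaryTrace("no_mention", False, None, None, False, False)
            return [], trace
        trace = OvaryTrace("not_visualized", True, None, None, False, False)
        return [f"the {side} ovary is not visualized."], trace
    if arm == "2d_only":
        d2 = tuple(_round1(v) for v in rng.uniform(1.5, 4.0, size=2))
        unit = _choose_unit(cfg, rng)
        trace = OvaryTrace("2d_only", True, None, unit, False, False)
        return [f"the {side} ovary measures {_dims_text(d2, unit, rng)}."], trace
    # garbled: a measurement was dictated but the transcript is unusable
    dims = tuple(_round1(v) for v in rng.uniform(1.5, 4.0, size=3))
    unit = _choose_unit(cfg, rng)
    trace = OvaryTrace("garbled", True, None, unit, False, False, typo=True)
    text = _garble(_dims_text(dims, unit, rng), rng)
    return [f"the {side} ovary measures {text}."], trace


def _side_targets(
    overall: PCOMLabel, rng: np.random.Generator
) -> tuple[PCOMLabel, PCOMLabel]:
    A, U, P = PCOMLabel.ABSENT, PCOMLabel.UNIDENTIFIABLE, PCOMLabel.PRESENT
    if overall is A:
        return A, A
    if overall is P:
        other = (A, P, U)[rng.choice(3, p=(0.7, 0.2, 0.1))]
        pair = (P, other)
    else:
        other = (A, U)[rng.choice(2, p=(0.75, 0.25))]
        pair = (U, other)
    return pair if rng.random() < 0.5 else (pair[1], pair[0])


def _apply_typo(
    sents: list[str], trace: OvaryTrace, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[list[str], OvaryTrace]:
    """Corrupt the measurement text of a measured ovary; truth unchanged."""
    if trace.dims_cm is None or len(trace.dims_cm) != 3:
        return sents, trace
    if rng.random() >= cfg.p_typo:
        return sents, trace
    out = list(sents)
    for i, s in enumerate(out):
        if "x" in s and any(c.isdigit() for c in s):
            out[i] = _garble(s, rng)
            break
    return out, replace(trace, typo=True)


def generate_corpus(cfg: SynthConfig) -> list[SynthRecord]:
    """Generate ``cfg.n_reports`` synthetic reports with ground truth.

    A fixed seed yields byte-identical output. Each record's truth
    satisfies ``truth_overall == aggregate_report(truth_left,
    truth_right)`` and is re-derivable from the trace via the rule
    engine.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = [PCOMLabel.ABSENT, PCOMLabel.UNIDENTIFIABLE, PCOMLabel.PRESENT]
    records: list[SynthRecord] = []
    rule_cfg = RuleConfig()
    for i in range(cfg.n_reports):
        overall_target = labels[rng.choice(3, p=cfg.class_mix)]
        t_left, t_right = _side_targets(overall_target, rng)
        left_sents, left_trace = _sample_ovary(t_left, "left", cfg, rng)
        right_sents, right_trace = _sample_ovary(t_right, "right", cfg, rng)
        left_sents, left_trace = _apply_typo(left_sents, left_trace, cfg, rng)
        right_sents, right_trace = _apply_typo(right_sents, right_trace, cfg, rng)

        u_dims = [f"{_round1(v):g}" for v in rng.uniform(5.0, 9.5, size=3)]
        lead = _LEAD_DISTRACTORS[rng.integers(len(_LEAD_DISTRACTORS))].format(
            u1=u_dims[0], u2=u_dims[1], u3=u_dims[2]
        )
        tail = _TAIL_DISTRACTORS[rng.integers(len(_TAIL_DISTRACTORS))]
        sentences = [lead, *right_sents, *left_sents, tail]

        truth_left = left_trace.derive_label(rule_cfg)
        truth_right = right_trace.derive_label(rule_cfg)
        records.append(
            SynthRecord(
                report=RawReport(report_id=f"synth-{i:05d}", text=" ".join(sentences)),
                truth_left=truth_left,
                truth_right=truth_right,
                truth_overall=aggregate_report(truth_left, truth_right),
                trace_left=left_trace,
                trace_right=right_trace,
            )
        )
    return records
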