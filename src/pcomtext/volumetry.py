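"""Measurement extraction and ellipsoid ovarian volume.

Dictated reports state ovarian size as one to three diameters joined by
``x`` (``3x3x5 cm``, ``30 x 28 x 41 mm``). Three diameters give the
ellipsoid (prolate) volume length*width*height*pi/6, with cm^3 = ml.
One- and two-dimensional measurements cannot yield a volume and are
excluded. A garbled measurement (dictation typo such as ``3.x4x5``)
simply fails to match and yields no volume — the documented failure mode.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "Dimensions",
    "extract_dimension_tuples",
    "normalize_units",
    "ellipsoid_volume",
    "ovary_volume",
    "MM_INFERENCE_THRESHOLD_CM",
]

# A dimension without an explicit unit and >= this many raw units is
# implausible as centimetres and is read as millimetres.
MM_INFERENCE_THRESHOLD_CM = 8.0

_NUM = r"(\d+(?:\.\d+)?)"
_SEP = r"\s*x\s*"
_MEASUREMENT = re.compile(
    rf"(?<![\d.x]){_NUM}(?:{_SEP}{_NUM}(?:{_SEP}{_NUM})?)?\s*(cm|mm|cc|ml)?(?!\w)"
)


@dataclass(frozen=True)
class Dimensions:
    """Up to three positive diameters, normalized to cm."""

    d1: float
    d2: float | None = None
    d3: float | None = None
    # explicit_cm | explicit_mm | inferred; "raw" marks an extracted
    # unitless tuple that normalize_units has not yet resolved
    unit_source: str = "inferred"

    def __post_init__(self) -> None:
        for d in self.values:
            if d <= 0:
                raise ValueError("dimensions must be positive")

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(d for d in (self.d1, self.d2, self.d3) if d is not None)

    @property
    def ndim(self) -> int:
        return len(self.values)


def extract_dimension_tuples(sentence: str) -> list[tuple[Dimensions, tuple[int, int]]]:
    """All raw measurement tuples in a cleaned sentence, with char spans.

    Recognizes 1-3 positive decimals joined by ``x`` with an optional
    trailing unit. A single bare number without a unit is not a
    measurement (it would match every count in the prose); 1-D tuples
    therefore require an explicit length unit. ``cc``/``ml`` matches are
    stated volumes, not diameters, and are skipped. Unparseable garbage
    yields no match.
    """
    out: list[tuple[Dimensions, tuple[int, int]]] = []
    for m in _MEASUREMENT.finditer(sentence):
        nums = [float(g) for g in m.groups()[:3] if g is not None]
        unit = m.group(4)
        if unit in ("cc", "ml"):
            continue
        if len(nums) == 1 and unit is None:
            continue
        if any(v <= 0 for v in nums):
            continue
        source = {"cm": "explicit_cm", "mm": "explicit_mm", None: "raw"}[unit]
        dims = Dimensions(*nums, unit_source=source)  # type: ignore[arg-type]
        out.append((dims, m.span()))
    return out


def normalize_units(dims: Dimensions) -> Dimensions:
    """Convert a raw tuple to cm.

    Explicit mm values are divided by 10; explicit cm pass through. With
    no unit stated, any dimension >= the inference threshold reads the
    tuple as mm, otherwise cm (``unit_source`` becomes ``inferred``).
    """
    if dims.unit_source == "explicit_cm":
        return dims
    if dims.unit_source == "explicit_mm":
        vals = [v / 10.0 for v in dims.values]
        return Dimensions(*vals, unit_source="explicit_mm")
    if any(v >= MM_INFERENCE_THRESHOLD_CM for v in dims.values):
        vals = [v / 10.0 for v in dims.values]
    else:
        vals = list(dims.values)
    return Dimensions(*vals, unit_source="inferred")


def ellipsoid_volume(dims: Dimensions) -> float:
    """Ellipsoid volume d1*d2*d3*pi/6 in ml from three cm diameters.

    Raises if fewer than three dimensions are present: 1- and 2-D
    measurements are excluded because no volume can be computed.
    """
    if dims.ndim != 3:
        raise ValueError("ellipsoid volume requires exactly three dimensions")
    return math.prod(dims.values) * math.pi / 6.0


def ovary_volume(
    sentences: list[str],
    token_sentences: list[list[str]] | None = None,
    ovary_stem: str = "ovari",
) -> tuple[Dimensions, float] | None:
    """Normalized dimensions and volume for one ovary document, if any.

    Prefers the first 3-D tuple whose sentence mentions the ovary (the
    organ measurement precedes internal structures in dictation), else
    the first 3-D tuple anywhere in the document. Returns ``None`` when
    no 3-D measurement exists.
    """
    first_any: Dimensions | None = None
    for i, sent in enumerate(sentences):
        for dims, _span in extract_dimension_tuples(sent):
            if dims.ndim != 3:
                continue
            mentioned = (
                token_sentences is not None
                and i < len(token_sentences)
                and ovary_stem in token_sentences[i]
            )
            if mentioned:
                norm = normalize_units(dims)
                return norm, ellipsoid_volume(norm)
            if first_any is None:
                first_any = dims
    if first_any is not None:
        norm = normalize_units(first_any)
        return norm, ellipsoid_volume(norm)
    return None
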