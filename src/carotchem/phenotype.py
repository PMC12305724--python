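"""Binary root-color phenotype codes and phenotypic diversity statistics.

Carrot roots are scored for presence (1) or absence (0) of purple
pigmentation in four concentric tissues - periderm (skin), cortex,
phloem, xylem - giving a 4-bit code written ":bbbb" (":1111" = fully
purple, ":0000" = non-purple).  Cohort-level phenotypic diversity is
summarised with S.H.E statistics: category richness S, Shannon-Wiener
index H (natural log), and Pielou evenness E = H / ln S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = ["PhenotypeCode", "DiversityResult", "parse_code", "she_diversity"]

TISSUES = ("periderm", "cortex", "phloem", "xylem")


@dataclass(frozen=True)
class PhenotypeCode:
    """Purple/non-purple flags for the four root tissues."""

    periderm: bool
    cortex: bool
    phloem: bool
    xylem: bool

    @property
    def code(self) -> str:
        """Canonical string form, e.g. ':1101'."""
        return ":" + "".join(
            "1" if flag else "0"
            for flag in (self.periderm, self.cortex, self.phloem, self.xylem)
        )

    @property
    def is_purple(self) -> bool:
        """True if any tissue is pigmented."""
        return self.periderm or self.cortex or self.phloem or self.xylem

    def __str__(self) -> str:
        return self.code


def parse_code(text: str) -> PhenotypeCode:
    """Parse a 4-bit phenotype string such as ':1111' or '1000'.

    The leading colon is optional on input; the canonical form always
    carries it.  Raises ``ValueError`` naming the first faulty digit
    position (1-based) for malformed input.
    """
    digits = text[1:] if text.startswith(":") else text
    if len(digits) != 4:
        raise ValueError(
            f"phenotype code {text!r} must have exactly 4 binary digits, got {len(digits)}"
        )
    flags = []
    for pos, ch in enumerate(digits, start=1):
        if ch not in "01":
            raise ValueError(
                f"phenotype code {text!r}: invalid character {ch!r} at position {pos}"
            )
        flags.append(ch == "1")
    return PhenotypeCode(*flags)


@dataclass(frozen=True)
class DiversityResult:
    """S.H.E summary of a categorical phenotype distribution.

    S is the number of categories observed, H the Shannon-Wiener index in
    nats, and E = H/ln S the evenness (defined as 0 for a single category).
    """

    S: int
    logS: float
    H: float
    E: float


def she_diversity(category_counts: Mapping[str, int | float]) -> DiversityResult:
    """S.H.E diversity of phenotype category counts.

    H = -sum p_i ln p_i over categories with positive count; categories
    with zero count do not contribute and do not enter S.
    """
    positive = [c for c in category_counts.values() if c > 0]
    if not positive:
        raise ValueError("at least one category count must be positive")
    if any(c < 0 for c in category_counts.values()):
        raise ValueError("category counts must be non-negative")
    total = float(sum(positive))
    h = -sum((c / total) * math.log(c / total) for c in positive)
    s = len(positive)
    log_s = math.log(s)
    e = h / log_s if s > 1 else 0.0
    return DiversityResult(S=s, logS=log_s, H=h, E=e)
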