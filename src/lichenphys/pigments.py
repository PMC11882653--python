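"""Chlorophyll quantification from DMSO thallus extracts.

Chlorophyll concentrations are linear combinations of the absorbances at
665 and 649 nm.  The coefficient sets are shipped as named, documented
constants transcribed from the spectrophotometric literature (selectable
by name) rather than anonymous magic numbers; an optional 750 nm reading
subtracts turbidity from both channels before the linear form is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .datamodel import PigmentMeasurement


@dataclass(frozen=True)
class ChlCoefficients:
    """µg/ml = a·A665 + b·A649 for each chlorophyll channel."""

    name: str
    chl_a_665: float
    chl_a_649: float
    chl_b_665: float
    chl_b_649: float


#: Arnon's 80%-acetone coefficients, as adopted for DMSO extracts
#: (identical coefficients applied at the DMSO wavelengths 665/649 nm).
ARNON_DMSO = ChlCoefficients(
    name="arnon_dmso",
    chl_a_665=12.7,
    chl_a_649=-2.69,
    chl_b_665=-4.68,
    chl_b_649=22.9,
)

#: Wellburn's re-determined coefficients for DMSO at 665.1/649.1 nm.
WELLBURN_DMSO = ChlCoefficients(
    name="wellburn_dmso",
    chl_a_665=12.19,
    chl_a_649=-3.45,
    chl_b_665=-5.32,
    chl_b_649=21.99,
)

COEFFICIENT_SETS: Dict[str, ChlCoefficients] = {
    c.name: c for c in (ARNON_DMSO, WELLBURN_DMSO)
}


@dataclass(frozen=True)
class ChlContent:
    chl_a: float  # µg per mg DM
    chl_b: float
    chl_ab: float
    ratio_ab_a: float
    flagged: bool  # negative computed concentration (turbid/failed extract)


def chlorophyll_content(
    measurement: PigmentMeasurement,
    coeffs: ChlCoefficients = ARNON_DMSO,
    *,
    a750: float = 0.0,
    second_extract: Optional[PigmentMeasurement] = None,
) -> ChlContent:
    """Chlorophyll a and a+b content in µg per mg dry mass.

    Concentration (µg/ml) is the linear form in the (turbidity-corrected)
    absorbances; content multiplies by extract volume and divides by dry
    mass.  When the protocol's second sequential extract is supplied, the
    two contents are summed.  Negative computed concentrations flag a
    turbid or failed extract; they are clipped to zero in the totals but
    reported via ``flagged``.
    """
    a665 = measurement.a665 - a750
    a649 = measurement.a649 - a750
    conc_a = coeffs.chl_a_665 * a665 + coeffs.chl_a_649 * a649
    conc_b = coeffs.chl_b_665 * a665 + coeffs.chl_b_649 * a649
    flagged = conc_a < 0 or conc_b < 0
    scale = measurement.extract_volume_ml / measurement.dm_mg
    chl_a = max(conc_a, 0.0) * scale
    chl_b = max(conc_b, 0.0) * scale
    if second_extract is not None:
        extra = chlorophyll_content(second_extract, coeffs, a750=a750)
        chl_a += extra.chl_a
        chl_b += extra.chl_b
        flagged = flagged or extra.flagged
    chl_ab = chl_a + chl_b
    return ChlContent(
        chl_a=chl_a,
        chl_b=chl_b,
        chl_ab=chl_ab,
        ratio_ab_a=chl_ab / chl_a if chl_a > 0 else float("nan"),
        flagged=flagged,
    )
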