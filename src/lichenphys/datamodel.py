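"""Domain types for hydration-resolved gas-exchange analysis.

Conventions used throughout the package:

* masses in mg, areas in cm², PPFD in µmol photons m⁻² s⁻¹;
* CO₂ assimilation in nmol per g dry mass per s, net photosynthesis
  positive and respiration negative;
* water content either as % of dry mass or as mm precipitation
  equivalent (1 mm rainfall ≡ 100 mg H₂O per cm²).

No unit autodetection is performed anywhere: silent unit errors are the
main hazard in this kind of data, so inputs are taken at face value and
validated against the invariants below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence


class ValidationError(ValueError):
    """An input record violates a domain-type invariant."""


class SchemaError(ValueError):
    """A tabular input is missing required columns or is unreadable."""


@dataclass(frozen=True)
class ThallusSample:
    """One physical thallus with its morphometric measurements."""

    sample_id: str
    species_code: str
    site: str
    dry_mass_mg: float
    area_cm2: float
    full_wet_mass_mg: float

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not (self.dry_mass_mg > 0):
            raise ValidationError(
                f"sample {self.sample_id}: dry_mass_mg must be > 0, got {self.dry_mass_mg}"
            )
        if not (self.area_cm2 > 0):
            raise ValidationError(
                f"sample {self.sample_id}: area_cm2 must be > 0, got {self.area_cm2}"
            )
        if self.full_wet_mass_mg < self.dry_mass_mg:
            raise ValidationError(
                f"sample {self.sample_id}: full_wet_mass_mg ({self.full_wet_mass_mg}) "
                f"< dry_mass_mg ({self.dry_mass_mg})"
            )


@dataclass(frozen=True)
class LightCurve:
    """A single light-response curve at one hydration state.

    ``ppfd_steps`` must start at 0 (the dark/respiration reading) and be
    strictly increasing.  ``mass_before_mg``/``mass_after_mg`` bracket the
    curve; the sample dries during measurement so before ≥ after.
    """

    curve_index: int
    ppfd_steps: tuple
    assim: tuple
    mass_before_mg: float
    mass_after_mg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ppfd_steps", tuple(float(p) for p in self.ppfd_steps))
        object.__setattr__(self, "assim", tuple(float(a) for a in self.assim))
        if len(self.assim) != len(self.ppfd_steps):
            raise ValidationError(
                f"curve {self.curve_index}: {len(self.assim)} assim values for "
                f"{len(self.ppfd_steps)} PPFD steps"
            )
        if len(self.ppfd_steps) < 2:
            raise ValidationError(f"curve {self.curve_index}: needs ≥ 2 PPFD steps")
        if self.ppfd_steps[0] != 0:
            raise ValidationError(
                f"curve {self.curve_index}: first PPFD step must be 0, got {self.ppfd_steps[0]}"
            )
        for a, b in zip(self.ppfd_steps, self.ppfd_steps[1:]):
            if not b > a:
                raise ValidationError(
                    f"curve {self.curve_index}: PPFD steps not strictly increasing "
                    f"({a} then {b})"
                )
        if self.mass_before_mg < self.mass_after_mg:
            raise ValidationError(
                f"curve {self.curve_index}: mass_before_mg ({self.mass_before_mg}) "
                f"< mass_after_mg ({self.mass_after_mg}); sample cannot gain water"
            )
        if any(not math.isfinite(a) for a in self.assim):
            raise ValidationError(f"curve {self.curve_index}: non-finite assimilation value")

    @property
    def mean_mass_mg(self) -> float:
        """Midpoint-convention mass for the curve."""
        return 0.5 * (self.mass_before_mg + self.mass_after_mg)

    @property
    def dark_respiration(self) -> float:
        """Assimilation at PPFD 0 (negative when the sample respires)."""
        return self.assim[0]


@dataclass(frozen=True)
class DryingRun:
    """An ordered series of light curves measured while one sample dries."""

    sample: ThallusSample
    curves: tuple
    temperature_c: float = 18.0
    rh_percent: float = 90.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        if len(self.curves) < 3:
            raise ValidationError(
                f"sample {self.sample.sample_id}: a drying run needs ≥ 3 curves, "
                f"got {len(self.curves)}"
            )
        masses = [c.mean_mass_mg for c in self.curves]
        for i, (a, b) in enumerate(zip(masses, masses[1:])):
            if b > a + 1e-9:
                raise ValidationError(
                    f"sample {self.sample.sample_id}: curve masses increase between "
                    f"curves {self.curves[i].curve_index} and {self.curves[i + 1].curve_index}"
                )


@dataclass
class CoreParameters:
    """Per-sample vector of extracted core parameters.

    Water contents are carried in both unit systems; ``dr_max`` and the
    respiration entering ``cge`` are magnitudes (positive numbers).
    ``max_wc_censored``/``min_wc_censored`` flag bounds that were not
    bracketed by data (e.g. no suprasaturation observed).
    """

    sample_id: str
    species_code: str
    lcp: float
    lsp: float
    max_np: float
    dr_max: float
    min_wc_mm: float
    max_wc_mm: float
    opt_wc_mm: float
    min_wc_pct: float
    max_wc_pct: float
    opt_wc_pct: float
    cge: float
    stm: float
    whc_mm: float
    chl_a: Optional[float] = None
    chl_ab: Optional[float] = None
    min_wc_censored: bool = False
    max_wc_censored: bool = False

    def __post_init__(self) -> None:
        if self.min_wc_mm > self.max_wc_mm + 1e-12:
            raise ValidationError(
                f"sample {self.sample_id}: min_wc_mm > max_wc_mm"
            )
        if not math.isclose(
            self.opt_wc_mm, self.max_wc_mm - self.min_wc_mm, rel_tol=0, abs_tol=1e-9
        ):
            raise ValidationError(
                f"sample {self.sample_id}: opt_wc_mm must equal max_wc_mm - min_wc_mm"
            )
        if not math.isclose(
            self.opt_wc_pct, self.max_wc_pct - self.min_wc_pct, rel_tol=0, abs_tol=1e-6
        ):
            raise ValidationError(
                f"sample {self.sample_id}: opt_wc_pct must equal max_wc_pct - min_wc_pct"
            )
        if math.isfinite(self.lcp) and math.isfinite(self.lsp) and self.lcp >= self.lsp:
            raise ValidationError(f"sample {self.sample_id}: lcp must be < lsp")


#: Canonical column order for core-parameter tables.
CORE_PARAMETER_COLUMNS = [f.name for f in fields(CoreParameters)]


@dataclass(frozen=True)
class HabitatRank:
    """Ordinal habitat-association rank for one species (1 = weakest)."""

    species_code: str
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError(f"{self.species_code}: rank must be ≥ 1")


def validate_rank_set(ranks: Sequence[HabitatRank]) -> None:
    """Ranks across a species set must form a permutation of 1..n."""
    got = sorted(r.rank for r in ranks)
    if got != list(range(1, len(ranks) + 1)):
        raise ValidationError(f"ranks {got} are not a permutation of 1..{len(ranks)}")


@dataclass(frozen=True)
class PigmentMeasurement:
    """Absorbance readings for one DMSO extract of one sample."""

    sample_id: str
    a665: float
    a649: float
    extract_volume_ml: float
    dm_mg: float

    def __post_init__(self) -> None:
        for name in ("a665", "a649"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: {name} must be finite and ≥ 0, got {v}"
                )
        if not (self.extract_volume_ml > 0):
            raise ValidationError(f"sample {self.sample_id}: extract_volume_ml must be > 0")
        if not (self.dm_mg > 0):
            raise ValidationError(f"sample {self.sample_id}: dm_mg must be > 0")
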