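"""Core-parameter extraction from drying runs.

This is the analytical heart of the pipeline: given one sample's ordered
series of light-response curves measured while the thallus dries, extract

* light compensation point (LCP): PPFD where net photosynthesis crosses
  zero, by linear interpolation between the bracketing steps;
* light saturation point (LSP): lowest PPFD reaching 90% of the curve's
  maximum NP, linearly interpolated;
* the NP/DR response to water content at saturating light, and from it
  MaxNP, the water-content bounds MinWC/MaxWC where NP stays above 90%
  of MaxNP, and their width OptWC = MaxWC − MinWC;
* morphometrics STM (dry mass per area) and WHC (water held at full
  hydration, mm precipitation equivalent), and carbon gain efficiency
  CGE = MaxNP / |DR at the MaxNP curve|.

All threshold crossings use plain linear interpolation on the raw data;
no smoothing is applied unless requested, keeping the estimator
transparent.  Water contents are interpolated on the % scale and
converted to mm via STM (the two scales are proportional per sample, so
the interpolation is equivalent in either).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    CoreParameters,
    DryingRun,
    LightCurve,
    PigmentMeasurement,
    ThallusSample,
    ValidationError,
)

#: Default relative threshold defining LSP and the optimal-WC bounds.
DEFAULT_THRESHOLD = 0.9

#: Sentinel for an LCP that does not exist (sample metabolically inactive).
UNDEFINED = float("nan")


class InactiveCurveError(ValueError):
    """Curve never reaches positive net photosynthesis."""


class ProtocolError(ValueError):
    """Curve violates the measurement protocol (e.g. no respiration at PPFD 0)."""


# ---------------------------------------------------------------------------
# water-content conversions


def water_content_pct(mass_mg: float, dry_mass_mg: float) -> float:
    """Water content as % of dry mass: 100·(mass − DM)/DM."""
    if dry_mass_mg <= 0:
        raise ValidationError("dry_mass_mg must be > 0")
    if mass_mg < dry_mass_mg:
        raise ValidationError(
            f"mass ({mass_mg} mg) below dry mass ({dry_mass_mg} mg): negative water content"
        )
    return 100.0 * (mass_mg - dry_mass_mg) / dry_mass_mg


def water_content_mm(mass_mg: float, dry_mass_mg: float, area_cm2: float) -> float:
    """Water content in mm precipitation equivalent.

    1 mm rainfall deposits 100 mg H₂O per cm², so the mm-equivalent is
    (mass − DM) / (100 · area).
    """
    if area_cm2 <= 0:
        raise ValidationError("area_cm2 must be > 0")
    if mass_mg < dry_mass_mg:
        raise ValidationError(
            f"mass ({mass_mg} mg) below dry mass ({dry_mass_mg} mg): negative water content"
        )
    return (mass_mg - dry_mass_mg) / (100.0 * area_cm2)


def stm(dry_mass_mg: float, area_cm2: float) -> float:
    """Specific thallus mass, mg per cm²."""
    if area_cm2 <= 0:
        raise ValidationError("area_cm2 must be > 0")
    if dry_mass_mg <= 0:
        raise ValidationError("dry_mass_mg must be > 0")
    return dry_mass_mg / area_cm2


def whc(full_wet_mass_mg: float, dry_mass_mg: float, area_cm2: float) -> float:
    """Water holding capacity at full hydration, mm precipitation equivalent."""
    return water_content_mm(full_wet_mass_mg, dry_mass_mg, area_cm2)


def curve_wc(
    curve: LightCurve, sample: ThallusSample, *, convention: str = "midpoint"
) -> Tuple[float, float]:
    """Water content (%, mm) assigned to a curve from its bracketing masses.

    ``convention`` is ``"midpoint"`` (mean of before/after, the default)
    or ``"endpoint"`` (mass before the curve).
    """
    if convention == "midpoint":
        mass = curve.mean_mass_mg
    elif convention == "endpoint":
        mass = curve.mass_before_mg
    else:
        raise ValueError(f"unknown mass convention {convention!r}")
    return (
        water_content_pct(mass, sample.dry_mass_mg),
        water_content_mm(mass, sample.dry_mass_mg, sample.area_cm2),
    )


# ---------------------------------------------------------------------------
# light-response thresholds


def _first_upward_crossing(x: Sequence[float], y: Sequence[float], level: float) -> float:
    """Lowest-x linear-interpolated upward crossing of ``level``; NaN if none."""
    for i in range(len(y) - 1):
        if y[i] < level <= y[i + 1]:
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return x[i] + frac * (x[i + 1] - x[i])
        if y[i] == level:
            return x[i]
    if y and y[-1] == level:
        return x[-1]
    return UNDEFINED


def lcp(curve: LightCurve) -> float:
    """Light compensation point: PPFD where NP first becomes positive.

    Returns NaN (undefined sentinel) for an all-negative curve — the
    sample is inactive at this hydration state.  An all-positive curve is
    a protocol violation: the PPFD-0 step must show respiration.
    """
    a = curve.assim
    if a[0] > 0:
        raise ProtocolError(
            f"curve {curve.curve_index}: positive assimilation at PPFD 0 "
            "(dark step must respire)"
        )
    if max(a) < 0:
        return UNDEFINED
    return _first_upward_crossing(curve.ppfd_steps, a, 0.0)


def lsp(curve: LightCurve, *, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Light saturation point: lowest PPFD reaching ``threshold`` × curve max NP."""
    a = np.asarray(curve.assim)
    max_np = float(a.max())
    if max_np <= 0:
        return UNDEFINED
    return _first_upward_crossing(curve.ppfd_steps, list(a), threshold * max_np)


# ---------------------------------------------------------------------------
# water-content response


@dataclass(frozen=True)
class WCResponseRow:
    curve_index: int
    wc_pct: float
    wc_mm: float
    np_sat: float  # NP at saturating light (plateau estimate)
    dr: float  # assimilation at PPFD 0 (negative when respiring)


@dataclass(frozen=True)
class WCResponse:
    """NP/DR response to water content at saturating light.

    Rows are ordered from wettest to driest (descending WC), reproducing
    the shape of the hydration-response curves.
    """

    rows: tuple
    lsp_ref: float

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


def reference_lsp(
    run: DryingRun, *, threshold: float = DEFAULT_THRESHOLD, drop_first: bool = False
) -> Tuple[float, LightCurve]:
    """LSP of the curve with the highest NP (the near-optimal-WC curve)."""
    curves = run.curves[1:] if drop_first and len(run.curves) > 3 else run.curves
    best = max(curves, key=lambda c: max(c.assim))
    ref = lsp(best, threshold=threshold)
    if math.isnan(ref):
        raise InactiveCurveError(
            f"sample {run.sample.sample_id}: no curve with positive net photosynthesis"
        )
    return ref, best


def np_wc_response(
    run: DryingRun,
    lsp_ref: float,
    *,
    drop_first: bool = False,
    convention: str = "midpoint",
) -> WCResponse:
    """Tabulate NP at saturating light and DR against water content.

    For each curve, NP is the maximum assimilation over steps with
    PPFD ≥ ``lsp_ref`` (a plateau estimate, robust to per-step noise) and
    DR the PPFD-0 reading.
    """
    curves = run.curves[1:] if drop_first and len(run.curves) > 3 else run.curves
    rows: List[WCResponseRow] = []
    for curve in curves:
        sat = [a for p, a in zip(curve.ppfd_steps, curve.assim) if p >= lsp_ref]
        if not sat:
            raise ProtocolError(
                f"sample {run.sample.sample_id} curve {curve.curve_index}: "
                f"no PPFD step ≥ reference LSP {lsp_ref:.1f}"
            )
        wc_pct, wc_mm = curve_wc(curve, run.sample, convention=convention)
        rows.append(
            WCResponseRow(
                curve_index=curve.curve_index,
                wc_pct=wc_pct,
                wc_mm=wc_mm,
                np_sat=max(sat),
                dr=curve.dark_respiration,
            )
        )
    rows.sort(key=lambda r: -r.wc_pct)
    return WCResponse(rows=tuple(rows), lsp_ref=lsp_ref)


@dataclass(frozen=True)
class WCBounds:
    min_wc_pct: float
    max_wc_pct: float
    opt_wc_pct: float
    min_wc_mm: float
    max_wc_mm: float
    opt_wc_mm: float
    max_np: float
    min_censored: bool
    max_censored: bool


def optimal_wc_bounds(
    response: WCResponse, *, threshold: float = DEFAULT_THRESHOLD
) -> WCBounds:
    """Water-content bounds where NP ≥ ``threshold`` × MaxNP.

    MinWC is the lowest-WC upward crossing of the threshold, MaxWC the
    highest-WC (downward) crossing; both linearly interpolated on the %
    scale.  When the driest (wettest) measured point is itself above the
    threshold the bound is censored at that point and flagged.
    """
    if not len(response):
        raise ValueError("empty water-content response")
    rows = sorted(response.rows, key=lambda r: r.wc_pct)  # ascending WC
    wc = np.array([r.wc_pct for r in rows])
    np_sat = np.array([r.np_sat for r in rows])
    ratio = np.array([r.wc_mm / r.wc_pct if r.wc_pct > 0 else np.nan for r in rows])
    mm_per_pct = float(np.nanmean(ratio)) if np.isfinite(np.nanmean(ratio)) else 0.0

    max_np = float(np_sat.max())
    level = threshold * max_np

    min_censored = bool(np_sat[0] >= level)
    if min_censored:
        min_pct = float(wc[0])
    else:
        min_pct = float(_first_upward_crossing(list(wc), list(np_sat), level))

    max_censored = bool(np_sat[-1] >= level)
    if max_censored:
        max_pct = float(wc[-1])
    else:
        # highest-WC crossing: scan from the wet end on the reversed series
        max_pct = float(
            _first_upward_crossing(list(wc[::-1]), list(np_sat[::-1]), level)
        )

    if min_pct > max_pct:  # single point above threshold, both collapse onto it
        min_pct = max_pct = float(wc[int(np.argmax(np_sat))])

    return WCBounds(
        min_wc_pct=min_pct,
        max_wc_pct=max_pct,
        opt_wc_pct=max_pct - min_pct,
        min_wc_mm=min_pct * mm_per_pct,
        max_wc_mm=max_pct * mm_per_pct,
        opt_wc_mm=(max_pct - min_pct) * mm_per_pct,
        max_np=max_np,
        min_censored=min_censored,
        max_censored=max_censored,
    )


# ---------------------------------------------------------------------------
# orchestration


def compile_core_parameters(
    run: DryingRun,
    pigments: Optional[Tuple[float, float]] = None,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    drop_first: bool = False,
    convention: str = "midpoint",
) -> CoreParameters:
    """Extract the full core-parameter vector for one drying run.

    ``pigments`` optionally supplies (chl_a, chl_a+b) in µg per mg DM.
    LCP and LSP come from the curve with the highest NP; CGE divides
    MaxNP by the magnitude of that same curve's dark respiration; dr_max
    is the deepest dark respiration across the run.
    """
    sample = run.sample
    lsp_ref, best_curve = reference_lsp(run, threshold=threshold, drop_first=drop_first)
    response = np_wc_response(run, lsp_ref, drop_first=drop_first, convention=convention)
    bounds = optimal_wc_bounds(response, threshold=threshold)

    try:
        lcp_val = lcp(best_curve)
    except ProtocolError:
        # measurement noise can push a near-zero dark reading positive;
        # LCP is then undefined for this sample rather than a hard failure
        lcp_val = UNDEFINED
    dr_best = abs(min(best_curve.dark_respiration, 0.0))
    cge = bounds.max_np / dr_best if dr_best > 0 else float("inf")
    dr_max = max(abs(min(r.dr, 0.0)) for r in response.rows)

    return CoreParameters(
        sample_id=sample.sample_id,
        species_code=sample.species_code,
        lcp=lcp_val,
        lsp=lsp_ref,
        max_np=bounds.max_np,
        dr_max=dr_max,
        min_wc_mm=bounds.min_wc_mm,
        max_wc_mm=bounds.max_wc_mm,
        opt_wc_mm=bounds.max_wc_mm - bounds.min_wc_mm,
        min_wc_pct=bounds.min_wc_pct,
        max_wc_pct=bounds.max_wc_pct,
        opt_wc_pct=bounds.max_wc_pct - bounds.min_wc_pct,
        cge=cge,
        stm=stm(sample.dry_mass_mg, sample.area_cm2),
        whc_mm=whc(sample.full_wet_mass_mg, sample.dry_mass_mg, sample.area_cm2),
        chl_a=pigments[0] if pigments else None,
        chl_ab=pigments[1] if pigments else None,
        min_wc_censored=bounds.min_censored,
        max_wc_censored=bounds.max_censored,
    )
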