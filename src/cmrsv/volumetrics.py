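"""Global left-ventricular quantities by short-axis slice summation.

Volumes follow the standard slice-summation (Simpson) rule: each delineated
slice contributes its contour area times the centre-to-centre slice spacing
(thickness + gap).  Trabeculations and papillary muscles are included in the
cavity (the endocardial contour is taken as delineated).  No partial-volume
weighting is applied to the basal slice: whether a basal slice counts is
decided by whether it carries a contour.

LV mass is myocardial volume at ED (epicardial minus endocardial) times the
muscle density 1.05 g/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry_core import (
    ED,
    ES,
    ContourStack,
    GeometryError,
    InputError,
    Slice,
    polygon_area,
)

__all__ = [
    "MUSCLE_DENSITY_G_PER_ML",
    "VolumetricsResult",
    "cavity_volume",
    "epicardial_volume",
    "lv_mass",
    "global_function",
]

MUSCLE_DENSITY_G_PER_ML = 1.05

_MM3_PER_ML = 1000.0


def _slice_area(slc: Slice, phase: str, surface: str) -> float | None:
    contour = getattr(slc.phase(phase), surface)
    if contour is None:
        return None
    return polygon_area(contour, normal=slc.normal, context=f"slice {slc.index} {phase}")


def _surface_volume_ml(stack: ContourStack, phase: str, surface: str) -> float:
    total_mm3 = 0.0
    n = 0
    for slc in stack.slices:
        area = _slice_area(slc, phase, surface)
        if area is None:
            continue
        total_mm3 += area * stack.spacing_mm
        n += 1
    if n == 0:
        raise InputError(f"no {surface} contours at {phase}")
    return total_mm3 / _MM3_PER_ML


def cavity_volume(stack: ContourStack, phase: str) -> float:
    """LV cavity volume (ml) at a phase: sum of endocardial slice areas times
    slice spacing.  Slices without an endocardial contour at that phase
    contribute nothing."""
    return _surface_volume_ml(stack, phase, "endocardial")


def epicardial_volume(stack: ContourStack, phase: str) -> float:
    """Total epicardial volume (ml) at a phase by slice summation."""
    return _surface_volume_ml(stack, phase, "epicardial")


def lv_mass(stack: ContourStack) -> float:
    """LV mass (g): ED myocardial volume times muscle density (1.05 g/ml).

    The myocardial area of a slice is its ED epicardial area minus its ED
    endocardial area (zero endocardial area for solid apical slices that are
    delineated epicardially only).
    """
    wall_mm3 = 0.0
    n = 0
    for slc in stack.slices:
        epi = _slice_area(slc, ED, "epicardial")
        if epi is None:
            continue
        endo = _slice_area(slc, ED, "endocardial") or 0.0
        wall = epi - endo
        if wall < 0:
            raise GeometryError(
                f"slice {slc.index}: endocardial area exceeds epicardial area at ED"
            )
        wall_mm3 += wall * stack.spacing_mm
        n += 1
    if n == 0:
        raise InputError("no epicardial contours at ED")
    return wall_mm3 / _MM3_PER_ML * MUSCLE_DENSITY_G_PER_ML


@dataclass
class VolumetricsResult:
    """Global LV function from slice summation.

    ``ef`` is stored as a fraction (rendered as % via :attr:`ef_percent`).
    ``sv_ml`` is exactly ``edv_ml - esv_ml``; a paradoxical ESV > EDV is
    representable and flagged in ``warnings`` rather than raised.
    """

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef: float
    mass_g: float
    cardiac_output_l_min: float | None = None
    ed_epicardial_areas_cm2: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ef_percent(self) -> float:
        return 100.0 * self.ef


def global_function(stack: ContourStack) -> VolumetricsResult:
    """EDV, ESV, SV, EF, mass and (when heart rate is known) cardiac output."""
    edv = cavity_volume(stack, ED)
    esv = cavity_volume(stack, ES)
    sv = edv - esv
    warnings: list[str] = []
    if sv < 0:
        warnings.append("paradoxical volumes: ESV exceeds EDV")
    ef = sv / edv if edv > 0 else float("nan")
    co = None
    if stack.heart_rate_bpm is not None:
        co = sv * stack.heart_rate_bpm / 1000.0
    areas = []
    for slc in stack.slices:
        a = _slice_area(slc, ED, "epicardial")
        if a is not None:
            areas.append(a / 100.0)  # mm^2 -> cm^2
    return VolumetricsResult(
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=sv,
        ef=ef,
        mass_g=lv_mass(stack),
        cardiac_output_l_min=co,
        ed_epicardial_areas_cm2=areas,
        warnings=warnings,
    )
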