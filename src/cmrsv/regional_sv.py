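"""Decomposition of LV stroke volume into longitudinal, lateral and septal
contributions.

The longitudinal contribution is driven by atrioventricular plane
displacement (AVPD): the valve plane sweeps a near-cylindrical basal volume
toward the apex during systole.  It is quantified as the mean ED->ES
displacement of six standardized AV-plane landmarks projected onto the long
axis, multiplied by the mean of the two largest ED epicardial short-axis
areas among slices encompassed by that motion.

The radial contributions are quantified per short-axis slice as the signed
area swept between the ED and ES epicardial contours, split at the RV
insertion points into a septal and a free-wall (lateral) part, then summed
over slices apical to the ES AV-plane position (so the basal band already
credited to the longitudinal term is not counted twice).  The septal term is
signed: positive when the septum moves toward the LV cavity in systole,
negative when its net motion is toward the right ventricle — the abnormal
pattern seen in ventricular dyssynchrony.

Because the myocardium is incompressible, the ejected blood volume equals
the total epicardial volume change, which is why every term here uses
epicardial contours.  The decomposition is not exactly conservative (basal
area averaging, slice discretization); the unexplained remainder is reported
as ``residual_pct`` and never redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShPolygon

from .geometry_core import (
    ED,
    ES,
    ContourStack,
    GeometryError,
    InputError,
    LANDMARK_LABELS,
    Slice,
    long_axis,
    orient_positive,
    polygon_area,
    project_to_plane,
    signed_area_2d,
    split_arcs,
)
from .volumetrics import VolumetricsResult, global_function

__all__ = [
    "AVPDResult",
    "BasalAreaResult",
    "RadialSliceAreas",
    "RadialSVResult",
    "RegionalSVResult",
    "compute_avpd",
    "basal_epicardial_area",
    "sv_long",
    "radial_slice_areas",
    "sv_radial",
    "decompose",
]


@dataclass
class AVPDResult:
    """Atrioventricular plane displacement, ED to ES.

    ``per_landmark_mm`` maps each of the six landmark labels to its ED->ES
    displacement projected on the long axis (positive toward the apex);
    ``mean_mm`` is their arithmetic mean.  ``axis`` and ``base_point`` record
    the ED long-axis frame used for all projections.
    """

    per_landmark_mm: dict[str, float]
    mean_mm: float
    axis: np.ndarray
    base_point: np.ndarray


def compute_avpd(stack: ContourStack) -> AVPDResult:
    """Mean AV-plane displacement over the six standardized landmarks."""
    if stack.landmarks is None:
        raise InputError("stack has no landmark set")
    axis, base = long_axis(stack)
    per: dict[str, float] = {}
    for lbl in LANDMARK_LABELS:
        ed_pt = stack.landmarks.ed.get(lbl)
        es_pt = stack.landmarks.es.get(lbl)
        if ed_pt is None or es_pt is None:
            raise InputError(f"missing landmark {lbl!r}")
        per[lbl] = float((es_pt - ed_pt) @ axis)
    mean = float(np.mean(list(per.values())))
    return AVPDResult(per_landmark_mm=per, mean_mm=mean, axis=axis, base_point=base)


def _slice_position(slc: Slice, avpd: AVPDResult) -> float:
    """Signed position of a slice plane along the long axis, measured from
    the ED AV-plane position (the ED landmark centroid), positive apically."""
    return float((slc.origin - avpd.base_point) @ avpd.axis)


@dataclass
class BasalAreaResult:
    """ED epicardial short-axis area representative of the AVPD-swept base."""

    area_cm2: float
    slice_indices: list[int]
    flag: str | None = None  # None | "single_in_band" | "fallback_most_basal"


def basal_epicardial_area(stack: ContourStack, avpd: AVPDResult) -> BasalAreaResult:
    """Mean of the two largest ED epicardial areas among slices encompassed
    by the AV-plane motion.

    A slice is in the band when its plane position along the long axis lies
    in the closed interval between the mean ED and mean ES AV-plane
    positions.  With exactly one in-band slice that slice's area is used
    (flagged); with none, the most basal delineated slice's area is used
    (flagged).
    """
    lo = min(0.0, avpd.mean_mm)
    hi = max(0.0, avpd.mean_mm)
    candidates: list[tuple[float, int]] = []  # (area_mm2, slice index)
    all_epi: list[tuple[float, float, int]] = []  # (position, area, index)
    for slc in stack.slices:
        contour = slc.ed.epicardial
        if contour is None:
            continue
        area = polygon_area(contour, normal=slc.normal, context=f"slice {slc.index} ED")
        pos = _slice_position(slc, avpd)
        all_epi.append((pos, area, slc.index))
        if lo - 1e-9 <= pos <= hi + 1e-9:
            candidates.append((area, slc.index))
    if not all_epi:
        raise InputError("no ED epicardial contours")
    if len(candidates) >= 2:
        top = sorted(candidates, reverse=True)[:2]
        return BasalAreaResult(
            area_cm2=(top[0][0] + top[1][0]) / 2.0 / 100.0,
            slice_indices=[t[1] for t in top],
        )
    if len(candidates) == 1:
        area, idx = candidates[0]
        return BasalAreaResult(area_cm2=area / 100.0, slice_indices=[idx],
                               flag="single_in_band")
    pos, area, idx = min(all_epi)  # most basal = smallest apical position
    return BasalAreaResult(area_cm2=area / 100.0, slice_indices=[idx],
                           flag="fallback_most_basal")


def sv_long(
    stack: ContourStack,
    avpd: AVPDResult | None = None,
    basal: BasalAreaResult | None = None,
    total_sv_ml: float | None = None,
) -> tuple[float, float]:
    """Longitudinal contribution to stroke volume.

    Returns ``(ml, percent_of_SV)``: AVPD (mm) times the basal epicardial
    area (cm^2), over the slice-summation SV.  When SV <= 0 the percentage is
    NaN but the millilitre value is still returned.
    """
    if avpd is None:
        avpd = compute_avpd(stack)
    if basal is None:
        basal = basal_epicardial_area(stack, avpd)
    if total_sv_ml is None:
        total_sv_ml = global_function(stack).sv_ml
    ml = avpd.mean_mm * basal.area_cm2 * 0.1  # mm * cm^2 = 0.1 ml
    pct = 100.0 * ml / total_sv_ml if total_sv_ml > 0 else float("nan")
    return ml, pct


@dataclass
class RadialSliceAreas:
    """Signed swept areas (mm^2) between ED and ES epicardium on one slice,
    split at the RV insertion points.  Positive = motion toward the LV."""

    septal_mm2: float
    lateral_mm2: float
    flags: list[str] = field(default_factory=list)


def _swept_signed_area(xy_ed: np.ndarray, xy_es: np.ndarray) -> tuple[float, bool]:
    """Signed area of the region swept between an ED arc and the matching ES
    arc, closed by straight connectors at the endpoints.

    Both arcs must be supplied in contour (positive/CCW) order; the ES arc is
    reversed internally.  With the CCW convention the shoelace sum is
    positive exactly when the ES arc lies displaced toward the contour
    interior.  A self-intersecting swept polygon is reported via the second
    return value; its signed-area sum (with partial cancellation) is still
    returned.
    """
    poly = np.vstack([xy_ed, xy_es[::-1]])
    area = signed_area_2d(poly)
    simple = _ShPolygon(poly).is_valid
    return area, simple


def radial_slice_areas(slc: Slice) -> RadialSliceAreas:
    """Septal and lateral signed swept areas for one short-axis slice.

    Requires epicardial contours and both RV insertion points at ED and ES.
    The ED and ES contours are orientation-normalised in the slice's plane
    basis, split at their respective insertion points, and the swept region
    between corresponding arcs is integrated by the shoelace formula (radial
    connectors contribute nothing).
    """
    flags: list[str] = []
    arcs_xy: dict[str, dict[str, np.ndarray]] = {}
    septal_start_ed: str | None = None
    for phase_name in (ED, ES):
        phase = slc.phase(phase_name)
        if phase.epicardial is None:
            raise InputError(f"slice {slc.index}: no epicardial contour at {phase_name}")
        if not phase.has_insertions():
            raise InputError(f"slice {slc.index}: missing RV insertion point(s) at {phase_name}")
        contour = orient_positive(phase.epicardial, slc.normal)
        split = split_arcs(
            contour,
            phase.insertion_anterior,
            phase.insertion_inferior,
            septal_hint=slc.septal_hint,
        )
        if phase_name == ED:
            septal_start_ed = split.septal_start
        elif split.septal_start != septal_start_ed:
            # Keep the ED/ES arc correspondence anchored at the same
            # insertion point; rebuild the ES septal arc accordingly.
            flags.append("es_septal_arc_realigned")
            from .geometry_core import _arc_indices  # local: internal helper

            n = len(contour)
            if septal_start_ed == "anterior":
                sept = _arc_indices(n, split.anterior_index, split.inferior_index)
            else:
                sept = _arc_indices(n, split.inferior_index, split.anterior_index)
            # free-wall interior in contour order starting after the septal arc
            free = _arc_indices(n, (sept[-1] + 1) % n, (sept[0] - 1) % n)
            split.septal_indices = sept
            split.free_indices = free
        xy = project_to_plane(contour.vertices, slc.origin, slc.normal)
        sept_xy = xy[split.septal_indices]
        # free-wall arc including its boundary insertion vertices, so that
        # septal + lateral regions tile the full swept annulus
        free_full = np.concatenate(
            [[split.septal_indices[-1]], split.free_indices, [split.septal_indices[0]]]
        )
        arcs_xy[phase_name] = {"septal": sept_xy, "free": xy[free_full]}
    sept_area, sept_simple = _swept_signed_area(
        arcs_xy[ED]["septal"], arcs_xy[ES]["septal"]
    )
    lat_area, lat_simple = _swept_signed_area(arcs_xy[ED]["free"], arcs_xy[ES]["free"])
    if not sept_simple:
        flags.append("septal_swept_region_self_intersects")
    if not lat_simple:
        flags.append("lateral_swept_region_self_intersects")
    return RadialSliceAreas(septal_mm2=sept_area, lateral_mm2=lat_area, flags=flags)


@dataclass
class RadialSVResult:
    """Septal and lateral contributions summed over eligible slices."""

    sept_ml: float
    sept_pct: float
    lat_ml: float
    lat_pct: float
    slice_indices: list[int]
    per_slice: dict[int, RadialSliceAreas]
    flags: list[str] = field(default_factory=list)


def sv_radial(
    stack: ContourStack,
    avpd: AVPDResult | None = None,
    total_sv_ml: float | None = None,
) -> RadialSVResult:
    """Septal and lateral contributions to SV.

    Eligible slices have epicardial contours and both insertion points at
    both phases and lie apical to the ES AV-plane position (strictly), so the
    basal band swept by the AV plane is not counted both longitudinally and
    radially.  Each slice contributes its signed swept area times the slice
    spacing.
    """
    if avpd is None:
        avpd = compute_avpd(stack)
    if total_sv_ml is None:
        total_sv_ml = global_function(stack).sv_ml
    es_plane = max(0.0, avpd.mean_mm)
    sept_mm3 = 0.0
    lat_mm3 = 0.0
    used: list[int] = []
    per_slice: dict[int, RadialSliceAreas] = {}
    flags: list[str] = []
    for slc in stack.slices:
        if _slice_position(slc, avpd) <= es_plane + 1e-9:
            continue
        if slc.ed.epicardial is None or slc.es.epicardial is None:
            continue
        if not (slc.ed.has_insertions() and slc.es.has_insertions()):
            continue
        areas = radial_slice_areas(slc)
        per_slice[slc.index] = areas
        sept_mm3 += areas.septal_mm2 * stack.spacing_mm
        lat_mm3 += areas.lateral_mm2 * stack.spacing_mm
        used.append(slc.index)
        for f in areas.flags:
            flags.append(f"slice {slc.index}: {f}")
    if not used:
        raise InputError("no slice eligible for radial computation")
    sept_ml = sept_mm3 / 1000.0
    lat_ml = lat_mm3 / 1000.0
    if total_sv_ml > 0:
        sept_pct = 100.0 * sept_ml / total_sv_ml
        lat_pct = 100.0 * lat_ml / total_sv_ml
    else:
        sept_pct = lat_pct = float("nan")
    return RadialSVResult(
        sept_ml=sept_ml,
        sept_pct=sept_pct,
        lat_ml=lat_ml,
        lat_pct=lat_pct,
        slice_indices=used,
        per_slice=per_slice,
        flags=flags,
    )


@dataclass
class RegionalSVResult:
    """Full stroke-volume decomposition for one subject.

    Percentages are relative to the slice-summation SV; ``sept_pct`` is
    signed (negative = net septal motion toward the right ventricle).
    ``residual_pct`` is ``100 - (long + lat + sept)`` and is reported, never
    redistributed.  When SV <= 0 the percentage fields are NaN and a flag is
    set.
    """

    avpd: AVPDResult
    basal_area: BasalAreaResult
    volumetrics: VolumetricsResult
    sv_long_ml: float
    sv_long_pct: float
    sv_lat_ml: float
    sv_lat_pct: float
    sv_sept_ml: float
    sv_sept_pct: float
    residual_pct: float
    flags: list[str] = field(default_factory=list)


def decompose(stack: ContourStack) -> RegionalSVResult:
    """Assemble the complete regional decomposition of stroke volume."""
    vol = global_function(stack)
    avpd = compute_avpd(stack)
    basal = basal_epicardial_area(stack, avpd)
    flags: list[str] = list(vol.warnings)
    if basal.flag:
        flags.append(f"basal area: {basal.flag}")
    long_ml, long_pct = sv_long(stack, avpd, basal, vol.sv_ml)
    radial = sv_radial(stack, avpd, vol.sv_ml)
    flags.extend(radial.flags)
    if vol.sv_ml <= 0:
        flags.append("non-positive stroke volume: percentages undefined")
        residual = float("nan")
    else:
        residual = 100.0 - (long_pct + radial.lat_pct + radial.sept_pct)
    return RegionalSVResult(
        avpd=avpd,
        basal_area=basal,
        volumetrics=vol,
        sv_long_ml=long_ml,
        sv_long_pct=long_pct,
        sv_lat_ml=radial.lat_ml,
        sv_lat_pct=radial.lat_pct,
        sv_sept_ml=radial.sept_ml,
        sv_sept_pct=radial.sept_pct,
        residual_pct=residual,
        flags=flags,
    )
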