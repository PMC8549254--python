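"""Synthetic inputs with known ground truth.

Two generators make every stage of the pipeline testable without any
acquired data:

* :func:`generate_phantom` builds a deforming-ventricle phantom — a cylinder
  or truncated half-ellipsoid with prescribed AV-plane descent (AVPD),
  free-wall inward motion and signed septal motion — as a
  :class:`~cmrsv.geometry_core.ContourStack`, together with the analytic
  swept-volume decomposition (:class:`PhantomTruth`).  The wall is treated as
  incompressible: the endocardium at ES is constructed so that total wall
  volume is conserved, which makes the analytic longitudinal + lateral +
  septal swept volumes sum exactly to the true stroke volume for
  independent-motion specs.

* :func:`generate_cohort` builds patient tables with the covariate and
  outcome structure of a CRT cohort (responder status from follow-up LVESV,
  binary covariates with prescribed prevalences and covariate-outcome odds
  ratios, regional-function summaries per responder class).  An exact-count
  mode lays out a supplied cross-tabulation exactly, so published count
  tables can be turned into analyzable per-patient data.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .geometry_core import (
    ContourStack,
    ED,
    ES,
    ENDOCARDIAL,
    EPICARDIAL,
    InputError,
    LandmarkSet,
    PlanarContour,
    Slice,
    SlicePhase,
    plane_basis,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "CovariateSpec",
    "ExactCounts",
    "CohortSpec",
    "COHORT_COLUMNS",
    "study_exact_counts",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# Deforming-ventricle phantom
# ---------------------------------------------------------------------------

#: Angular placement (degrees) of the six AV-plane landmarks on the basal
#: epicardial circumference; the septum is centred at 180 degrees.  The six
#: directions cancel pairwise so the landmark centroid sits on the long axis.
_LANDMARK_ANGLES_DEG = {
    "inferoseptal": 160.0,
    "anterolateral": 340.0,
    "anteroseptal": 200.0,
    "inferolateral": 20.0,
    "anterior": 270.0,
    "inferior": 90.0,
}

#: Total angular width of the septal/lateral displacement cross-fade.
_RAMP_DEG = 10.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic deforming ventricle.

    Defaults describe a healthy-control-like ventricle: basal epicardial
    area ~34 cm^2, AVPD 15.3 mm, modest concentric radial motion with a
    septum spanning 120 degrees of the circumference.  ``septal_inward_mm``
    is signed: positive displaces the septum toward the LV cavity, negative
    toward the right ventricle (the dyssynchronous pattern).  Noise is off
    by default; the phantom is then exact up to vertex discretization.
    """

    shape: str = "cylinder"  # "cylinder" | "ellipsoid"
    base_radius_mm: float = 33.0
    length_mm: float = 80.0
    wall_thickness_mm: float = 10.0
    n_slices: int = 10
    n_vertices: int = 120
    avpd_mm: float = 15.3
    lateral_inward_mm: float = 3.0
    septal_inward_mm: float = 2.0
    septal_span_deg: float = 120.0
    landmark_jitter_mm: float = 0.0
    contour_noise_mm: float = 0.0
    heart_rate_bpm: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("cylinder", "ellipsoid"):
            raise InputError(f"unknown phantom shape {self.shape!r}")
        if not (self.base_radius_mm > self.wall_thickness_mm > 0):
            raise InputError("need base radius > wall thickness > 0")
        if self.n_slices < 4:
            raise InputError("need at least 4 slices")
        if self.n_vertices < 36:
            raise InputError("need at least 36 vertices per contour")
        if not (0.0 < self.septal_span_deg < 180.0):
            raise InputError("septal span must be in (0, 180) degrees")
        if not (0.0 <= self.avpd_mm < self.length_mm):
            raise InputError("AVPD must be non-negative and below the LV length")

    @property
    def spacing_mm(self) -> float:
        return self.length_mm / self.n_slices


@dataclass
class PhantomTruth:
    """Analytic ground truth of a phantom's volumes and decomposition (ml).

    For independent longitudinal/radial motion the three swept volumes sum
    exactly to ``sv_ml`` (cylinder: closed form; ellipsoid: fine quadrature).
    """

    edv_ml: float
    esv_ml: float
    sv_ml: float
    long_ml: float
    lat_ml: float
    sept_ml: float


def _displacement_profile(spec: PhantomSpec, phi: np.ndarray) -> np.ndarray:
    """Inward radial displacement (mm) as a function of circumferential angle.

    Septal value inside the septal span, lateral value on the free wall,
    cross-faded linearly over a 10-degree transition centred on each
    insertion point; the analytic truth integrates this same profile.
    """
    half = np.radians(spec.septal_span_deg) / 2.0
    ramp = np.radians(_RAMP_DEG) / 2.0
    a = np.abs((phi - np.pi + np.pi) % (2 * np.pi) - np.pi)  # distance from pi
    w = np.clip((half + ramp - a) / (2 * ramp), 0.0, 1.0)
    w = np.where(a <= half - ramp, 1.0, w)
    return spec.lateral_inward_mm + (spec.septal_inward_mm - spec.lateral_inward_mm) * w


def _epi_radius_ed(spec: PhantomSpec, s) -> np.ndarray:
    """ED epicardial radius at apical depth ``s`` (mm from the base plane)."""
    s = np.asarray(s, dtype=float)
    if spec.shape == "cylinder":
        return np.full_like(s, spec.base_radius_mm)
    frac = np.clip(1.0 - (s / spec.length_mm) ** 2, 0.0, None)
    return spec.base_radius_mm * np.sqrt(frac)


def _endo_radius_ed(spec: PhantomSpec, s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    a = spec.base_radius_mm - spec.wall_thickness_mm
    if spec.shape == "cylinder":
        return np.full_like(s, a)
    c = spec.length_mm - spec.wall_thickness_mm
    frac = np.clip(1.0 - (s / c) ** 2, 0.0, None)
    return a * np.sqrt(frac)


def _epi_radius_es(spec: PhantomSpec, s, phi: np.ndarray) -> np.ndarray:
    """ES epicardial radius: ED radius minus the inward displacement profile,
    tapered toward the apex in proportion to the local radius (ellipsoid)."""
    r_ed = _epi_radius_ed(spec, s)
    delta = _displacement_profile(spec, phi)
    if spec.shape == "cylinder":
        return r_ed - delta
    return r_ed - delta * (r_ed / spec.base_radius_mm)


_QUAD_ANGLES = 4096  # circumferential quadrature resolution for truths


def _phantom_truth(spec: PhantomSpec) -> PhantomTruth:
    phi = np.linspace(0.0, 2.0 * np.pi, _QUAD_ANGLES, endpoint=False)
    dphi = 2.0 * np.pi / _QUAD_ANGLES
    half = np.radians(spec.septal_span_deg) / 2.0
    a = np.abs((phi - np.pi + np.pi) % (2 * np.pi) - np.pi)
    septal_mask = a <= half
    d = spec.avpd_mm
    L = spec.length_mm
    R = spec.base_radius_mm
    w = spec.wall_thickness_mm

    def swept_area_split(s: float) -> tuple[float, float]:
        """Signed swept area per unit length at depth s: (septal, lateral)."""
        r_ed = float(_epi_radius_ed(spec, s))
        r_es = _epi_radius_es(spec, s, phi)
        integrand = 0.5 * (r_ed**2 - r_es**2)
        sept = float(np.sum(integrand[septal_mask]) * dphi)
        lat = float(np.sum(integrand[~septal_mask]) * dphi)
        return sept, lat

    if spec.shape == "cylinder":
        long_mm3 = np.pi * R**2 * d
        sept_a, lat_a = swept_area_split(0.0)
        sept_mm3 = sept_a * (L - d)
        lat_mm3 = lat_a * (L - d)
        edv_mm3 = np.pi * (R - w) ** 2 * L
    else:
        # axial quadrature at 100x the slice resolution
        n_ax = 100 * spec.n_slices
        s_long = np.linspace(0.0, d, max(2, int(n_ax * d / L) + 1))
        long_mm3 = float(np.trapezoid(np.pi * _epi_radius_ed(spec, s_long) ** 2, s_long))
        s_rad = np.linspace(d, L, n_ax + 1)
        sept_prof = np.empty_like(s_rad)
        lat_prof = np.empty_like(s_rad)
        for i, s in enumerate(s_rad):
            sept_prof[i], lat_prof[i] = swept_area_split(float(s))
        sept_mm3 = float(np.trapezoid(sept_prof, s_rad))
        lat_mm3 = float(np.trapezoid(lat_prof, s_rad))
        edv_mm3 = (2.0 / 3.0) * np.pi * (R - w) ** 2 * (L - w)
    sv_mm3 = long_mm3 + lat_mm3 + sept_mm3  # incompressible wall
    return PhantomTruth(
        edv_ml=edv_mm3 / 1000.0,
        esv_ml=(edv_mm3 - sv_mm3) / 1000.0,
        sv_ml=sv_mm3 / 1000.0,
        long_ml=long_mm3 / 1000.0,
        lat_ml=lat_mm3 / 1000.0,
        sept_ml=sept_mm3 / 1000.0,
    )


def _wall_area_scale(spec: PhantomSpec) -> float:
    """Factor by which per-slice ED wall areas are inflated at ES so that
    total wall volume is conserved over the shortened (L - AVPD) extent."""
    d = spec.avpd_mm
    L = spec.length_mm
    if spec.shape == "cylinder":
        return L / (L - d)
    s = np.linspace(0.0, L, 2000)
    wall = np.pi * (_epi_radius_ed(spec, s) ** 2 - _endo_radius_ed(spec, s) ** 2)
    total = float(np.trapezoid(wall, s))
    s_es = np.linspace(d, L, 2000)
    wall_es = np.pi * (
        _epi_radius_ed(spec, s_es) ** 2 - _endo_radius_ed(spec, s_es) ** 2
    )
    below = float(np.trapezoid(wall_es, s_es))
    return total / below


def _ring(origin, u, v, radii: np.ndarray, phi: np.ndarray) -> np.ndarray:
    return (
        origin[None, :]
        + radii[:, None] * np.cos(phi)[:, None] * u[None, :]
        + radii[:, None] * np.sin(phi)[:, None] * v[None, :]
    )


def generate_phantom(spec: PhantomSpec) -> tuple[ContourStack, PhantomTruth]:
    """Generate a deforming-ventricle phantom and its analytic truth.

    The base plane sits at z = 0 with the apex at z = -length; slice k is
    centred at apical depth (k + 1/2) * spacing.  At ES the AV plane
    (landmarks and basal band) has moved apically by ``avpd_mm``, and the
    epicardium below it is displaced inward by the septal/lateral profile.
    The ES endocardium is a circle whose area conserves total wall volume.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _phantom_truth(spec)
    normal = np.array([0.0, 0.0, -1.0])
    u, v = plane_basis(normal)
    phi = 2.0 * np.pi * np.arange(spec.n_vertices) / spec.n_vertices
    phi_fine = np.linspace(0.0, 2.0 * np.pi, _QUAD_ANGLES, endpoint=False)
    d = spec.avpd_mm
    half = np.radians(spec.septal_span_deg) / 2.0
    ant_angle = np.pi + half  # toward the "anterior" landmark at 270 deg
    inf_angle = np.pi - half
    wall_scale = _wall_area_scale(spec)

    def jitter(points: np.ndarray, sigma: float, in_plane: bool) -> np.ndarray:
        if sigma <= 0:
            return points
        if in_plane:
            eps = np.clip(rng.normal(0.0, sigma, (len(points), 2)), -3 * sigma, 3 * sigma)
            return points + eps[:, 0:1] * u[None, :] + eps[:, 1:2] * v[None, :]
        eps = np.clip(rng.normal(0.0, sigma, points.shape), -3 * sigma, 3 * sigma)
        return points + eps

    slices: list[Slice] = []
    for k in range(spec.n_slices):
        s = (k + 0.5) * spec.spacing_mm
        origin = np.array([0.0, 0.0, -s])
        hint = origin + _epi_radius_ed(spec, s) * (
            np.cos(np.pi) * u + np.sin(np.pi) * v
        )  # a point on the septal side
        ed = SlicePhase()
        r_epi = float(_epi_radius_ed(spec, s))
        if r_epi > 0.5:
            pts = _ring(origin, u, v, np.full_like(phi, r_epi), phi)
            ed.epicardial = PlanarContour(
                jitter(pts, spec.contour_noise_mm, in_plane=True), EPICARDIAL, ED
            )
            ed.insertion_anterior = origin + r_epi * (
                np.cos(ant_angle) * u + np.sin(ant_angle) * v
            )
            ed.insertion_inferior = origin + r_epi * (
                np.cos(inf_angle) * u + np.sin(inf_angle) * v
            )
        r_endo = float(_endo_radius_ed(spec, s))
        if r_endo > 0.5:
            pts = _ring(origin, u, v, np.full_like(phi, r_endo), phi)
            ed.endocardial = PlanarContour(
                jitter(pts, spec.contour_noise_mm, in_plane=True), ENDOCARDIAL, ED
            )
        es = SlicePhase()
        if s >= d - 1e-9 and r_epi > 0.5:
            r_es = _epi_radius_es(spec, s, phi)
            if np.any(r_es <= 0.5):
                raise InputError(
                    "radial displacement collapses the epicardium "
                    f"(slice at depth {s:.1f} mm): non-simple contour"
                )
            pts = _ring(origin, u, v, r_es, phi)
            es.epicardial = PlanarContour(
                jitter(pts, spec.contour_noise_mm, in_plane=True), EPICARDIAL, ES
            )
            r_ant = float(_epi_radius_es(spec, s, np.array([ant_angle]))[0])
            r_inf = float(_epi_radius_es(spec, s, np.array([inf_angle]))[0])
            es.insertion_anterior = origin + r_ant * (
                np.cos(ant_angle) * u + np.sin(ant_angle) * v
            )
            es.insertion_inferior = origin + r_inf * (
                np.cos(inf_angle) * u + np.sin(inf_angle) * v
            )
            # endocardium: circle conserving total wall volume
            r_es_fine = _epi_radius_es(spec, s, phi_fine)
            a_epi_es = 0.5 * float(np.sum(r_es_fine**2)) * (2 * np.pi / _QUAD_ANGLES)
            wall_ed = np.pi * (r_epi**2 - r_endo**2) if r_endo > 0 else np.pi * r_epi**2
            a_endo_es = a_epi_es - wall_scale * wall_ed
            if a_endo_es > np.pi * 0.5**2:
                r_c = float(np.sqrt(a_endo_es / np.pi))
                pts = _ring(origin, u, v, np.full_like(phi, r_c), phi)
                es.endocardial = PlanarContour(
                    jitter(pts, spec.contour_noise_mm, in_plane=True), ENDOCARDIAL, ES
                )
        slices.append(
            Slice(index=k, origin=origin, normal=normal, ed=ed, es=es, septal_hint=hint)
        )

    R = spec.base_radius_mm
    ed_marks = {}
    es_marks = {}
    for lbl, ang_deg in _LANDMARK_ANGLES_DEG.items():
        ang = np.radians(ang_deg)
        p = R * (np.cos(ang) * u + np.sin(ang) * v)  # on the base plane z=0
        ed_marks[lbl] = p
        es_marks[lbl] = p + d * normal
    if spec.landmark_jitter_mm > 0:
        for marks in (ed_marks, es_marks):
            for lbl in marks:
                marks[lbl] = jitter(
                    marks[lbl][None, :], spec.landmark_jitter_mm, in_plane=False
                )[0]
    landmarks = LandmarkSet(
        ed=ed_marks, es=es_marks, apex_ed=np.array([0.0, 0.0, -spec.length_mm])
    )
    stack = ContourStack(
        subject_id=f"phantom-{spec.shape}-seed{spec.seed}",
        slices=slices,
        slice_thickness_mm=spec.spacing_mm,
        slice_gap_mm=0.0,
        landmarks=landmarks,
        heart_rate_bpm=spec.heart_rate_bpm,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id",
    "sex",
    "age",
    "qrs_ms",
    "lbbb",
    "ischemic",
    "dyssync",
    "lge",
    "lvesv_base_ml",
    "lvesv_fu_ml",
    "avpd_mm",
    "sv_long_pct",
    "sv_lat_pct",
    "sv_sept_pct",
]


@dataclass
class CovariateSpec:
    """Marginal prevalence and covariate-outcome odds ratio of one binary
    covariate (outcome = responder)."""

    prevalence: float
    odds_ratio: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.prevalence <= 1.0):
            raise InputError("prevalence must be in [0, 1]")
        if self.odds_ratio <= 0:
            raise InputError("odds ratio must be positive")


@dataclass
class ExactCounts:
    """Exact cross-tabulation layout: class sizes, per-covariate exposed
    counts (responders, non-responders), optional per-class missing counts,
    and optional negative-septal-contribution counts per class."""

    n_responders: int
    n_nonresponders: int
    exposed: dict[str, tuple[int, int]] = field(default_factory=dict)
    missing: dict[str, tuple[int, int]] = field(default_factory=dict)
    negative_septal: tuple[int, int] | None = None

    def validate(self):
        for name, (a, c) in self.exposed.items():
            miss = self.missing.get(name, (0, 0))
            if not (0 <= a <= self.n_responders - miss[0]):
                raise InputError(f"infeasible exact counts for {name!r} (responders)")
            if not (0 <= c <= self.n_nonresponders - miss[1]):
                raise InputError(f"infeasible exact counts for {name!r} (non-responders)")
        if self.negative_septal is not None:
            a, c = self.negative_septal
            if not (0 <= a <= self.n_responders and 0 <= c <= self.n_nonresponders):
                raise InputError("infeasible negative-septal counts")


def study_exact_counts() -> ExactCounts:
    """Cross-tabulation of the CRT study cohort: 65 patients, 37 responders
    (>= 15% LVESV reduction at 6 months) and 28 non-responders, with the
    published per-covariate counts.  Dyssynchrony (radial-strain delay >=
    130 ms) was not assessable in two non-responders."""
    return ExactCounts(
        n_responders=37,
        n_nonresponders=28,
        exposed={
            "ischemic": (14, 18),
            "lbbb": (34, 22),
            "qrs150": (34, 23),
            "male": (27, 19),
            "lge": (23, 17),
            "dyssync": (15, 12),
        },
        missing={"dyssync": (0, 2)},
        negative_septal=(16, 12),
    )


def _default_covariates() -> dict[str, CovariateSpec]:
    # marginal prevalences and responder odds ratios of the study cohort
    return {
        "ischemic": CovariateSpec(32 / 65, 0.34),
        "lbbb": CovariateSpec(56 / 65, 3.09),
        "qrs150": CovariateSpec(57 / 65, 2.46),
        "male": CovariateSpec(46 / 65, 1.28),
        "lge": CovariateSpec(40 / 65, 1.06),
        "dyssync": CovariateSpec(27 / 63, 1.26),
    }


def _default_continuous() -> dict[str, tuple[float, float, float, float]]:
    # (responder mean, SD, non-responder mean, SD)
    return {
        "avpd_mm": (8.0, 3.1, 8.8, 3.2),
        "sv_long_pct": (53.0, 18.0, 53.0, 19.0),
        "sv_lat_pct": (38.0, 15.0, 45.0, 16.0),
        "sv_sept_pct": (-1.0, 17.0, 1.0, 11.0),
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic CRT cohort.

    Defaults reproduce the structure of the study population: 65 patients,
    57% responders, the published covariate prevalences and odds ratios, and
    per-class summaries of the regional-function measures.  ``exact_counts``
    switches to exact-count mode, reproducing a supplied cross-tabulation
    verbatim (covariates are then assigned within outcome class in a
    seed-permuted order, so different covariates are not artificially
    collinear).
    """

    n_patients: int = 65
    responder_fraction: float = 37 / 65
    covariates: dict[str, CovariateSpec] = field(default_factory=_default_covariates)
    continuous: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_continuous
    )
    lvesv_base_mean: float = 246.0
    lvesv_base_sd: float = 110.0
    lvesv_base_min: float = 50.0
    #: (responder mean, SD, non-responder mean, SD) of the LVESV change in
    #: percent; responders are truncated to <= -15, non-responders to > -15.
    delta_lvesv: tuple[float, float, float, float] = (-32.0, 12.0, 0.0, 12.0)
    age_mean: float = 67.0
    age_sd: float = 9.0
    seed: int = 0
    exact_counts: ExactCounts | None = None

    def __post_init__(self):
        if self.n_patients < 0:
            raise InputError("n_patients must be non-negative")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise InputError("responder fraction must be in [0, 1]")
        if self.exact_counts is not None:
            self.exact_counts.validate()
            if self.exact_counts.n_responders + self.exact_counts.n_nonresponders != self.n_patients:
                raise InputError("exact counts do not total n_patients")


def _class_probabilities(prevalence: float, odds_ratio: float, f_resp: float):
    """Solve per-class exposure probabilities matching a marginal prevalence
    and a covariate-outcome odds ratio."""
    if prevalence in (0.0, 1.0) or odds_ratio == 1.0:
        return prevalence, prevalence

    def p1(p0: float) -> float:
        return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)

    def g(p0: float) -> float:
        return f_resp * p1(p0) + (1.0 - f_resp) * p0 - prevalence

    p0 = brentq(g, 1e-12, 1.0 - 1e-12)
    return p1(p0), p0


def _truncnorm(rng, mean, sd, size, lower=-np.inf, upper=np.inf):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate a per-patient cohort table (see :data:`COHORT_COLUMNS`).

    Booleans are stored as 0/1 floats; ``dyssync`` may be NaN (not
    assessable).  Responder status is encoded in the baseline/follow-up
    LVESV pair and is recovered downstream by the >= 15% reduction rule.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_patients
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    if spec.exact_counts is not None:
        n_resp = spec.exact_counts.n_responders
    else:
        n_resp = int(rng.binomial(n, spec.responder_fraction))
    responder = np.zeros(n, dtype=bool)
    responder[:n_resp] = True
    class_index = {True: np.where(responder)[0], False: np.where(~responder)[0]}

    cols: dict[str, np.ndarray] = {}
    # binary covariates
    cov_names = list(
        spec.exact_counts.exposed if spec.exact_counts is not None else spec.covariates
    )
    for name in cov_names:
        x = np.zeros(n)
        if spec.exact_counts is not None:
            counts = spec.exact_counts.exposed[name]
            miss = spec.exact_counts.missing.get(name, (0, 0))
            for is_resp, k_exposed, k_missing in (
                (True, counts[0], miss[0]),
                (False, counts[1], miss[1]),
            ):
                idx = rng.permutation(class_index[is_resp])
                x[idx[:k_exposed]] = 1.0
                if k_missing:
                    x[idx[len(idx) - k_missing:]] = np.nan
        else:
            cv = spec.covariates[name]
            f = n_resp / n if n else 0.0
            p_resp, p_non = _class_probabilities(cv.prevalence, cv.odds_ratio, f)
            for is_resp, p in ((True, p_resp), (False, p_non)):
                idx = class_index[is_resp]
                x[idx] = (rng.random(len(idx)) < p).astype(float)
        cols[name] = x

    # continuous regional-function measures per responder class
    for name, (m1, s1, m0, s0) in spec.continuous.items():
        x = np.empty(n)
        x[class_index[True]] = rng.normal(m1, s1, n_resp)
        x[class_index[False]] = rng.normal(m0, s0, n - n_resp)
        cols[name] = x
    # exact-count mode pins the sign pattern of the septal contribution
    if spec.exact_counts is not None and spec.exact_counts.negative_septal is not None:
        sept = np.abs(cols["sv_sept_pct"])
        for is_resp, k_neg in zip((True, False), spec.exact_counts.negative_septal):
            idx = rng.permutation(class_index[is_resp])
            sept[idx[:k_neg]] *= -1.0
            sept[idx[:k_neg]] -= 1e-9  # keep strictly negative
        cols["sv_sept_pct"] = sept

    base = _truncnorm(rng, spec.lvesv_base_mean, spec.lvesv_base_sd, n,
                      lower=spec.lvesv_base_min)
    m1, s1, m0, s0 = spec.delta_lvesv
    delta = np.empty(n)
    delta[class_index[True]] = _truncnorm(rng, m1, s1, n_resp, upper=-15.0)
    delta[class_index[False]] = _truncnorm(rng, m0, s0, n - n_resp, lower=-15.0)
    cols["lvesv_base_ml"] = base
    cols["lvesv_fu_ml"] = base * (1.0 + delta / 100.0)

    qrs = np.empty(n)
    q150 = cols.get("qrs150")
    if q150 is None:
        q150 = (rng.random(n) < 0.85).astype(float)
    hi = q150 == 1.0
    qrs[hi] = _truncnorm(rng, 172.0, 15.0, int(hi.sum()), lower=150.0)
    qrs[~hi] = _truncnorm(rng, 138.0, 9.0, int((~hi).sum()), lower=120.0, upper=149.9)
    cols["qrs_ms"] = qrs
    cols["age"] = np.round(rng.normal(spec.age_mean, spec.age_sd, n))

    male = cols.get("male", (rng.random(n) < 46 / 65).astype(float))
    df = pd.DataFrame(
        {
            "id": [f"P{i + 1:03d}" for i in range(n)],
            "sex": np.where(male == 1.0, "M", "F"),
            "age": cols["age"],
            "qrs_ms": cols["qrs_ms"],
            "lbbb": cols.get("lbbb", np.full(n, np.nan)),
            "ischemic": cols.get("ischemic", np.full(n, np.nan)),
            "dyssync": cols.get("dyssync", np.full(n, np.nan)),
            "lge": cols.get("lge", np.full(n, np.nan)),
            "lvesv_base_ml": cols["lvesv_base_ml"],
            "lvesv_fu_ml": cols["lvesv_fu_ml"],
            "avpd_mm": cols["avpd_mm"],
            "sv_long_pct": cols["sv_long_pct"],
            "sv_lat_pct": cols["sv_lat_pct"],
            "sv_sept_pct": cols["sv_sept_pct"],
        }
    )
    # non-standard covariates ("qrs150" and "male" are encoded in qrs_ms and
    # sex; the rest of the schema is fixed) are appended as extra columns
    for name in cov_names:
        if name not in df.columns and name not in ("qrs150", "male"):
            df[name] = cols[name]
    # shuffle rows so responder status is not positional
    order = rng.permutation(n)
    return df.iloc[order].reset_index(drop=True)
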