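import numpy as np
import pytest

from cmrsv.geometry_core import (
    ContourStack,
    ED,
    ENDOCARDIAL,
    EPICARDIAL,
    ES,
    LANDMARK_LABELS,
    LandmarkSet,
    PlanarContour,
    Slice,
    SlicePhase,
)
from cmrsv.synthetic_data import PhantomSpec, generate_phantom


def circle_contour(radius, z, n=120, surface=EPICARDIAL, phase=ED, center=(0.0, 0.0)):
    """Regular n-gon approximating a circle in the z-plane."""
    phi = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [center[0] + radius * np.cos(phi), center[1] + radius * np.sin(phi),
         np.full(n, float(z))]
    )
    return PlanarContour(pts, surface, phase)


def square_contour(side, z, surface=ENDOCARDIAL, phase=ED):
    """Axis-aligned square of exact area side^2 in the z-plane."""
    h = side / 2.0
    pts = np.array(
        [[-h, -h, z], [h, -h, z], [h, h, z], [-h, h, z]], dtype=float
    )
    return PlanarContour(pts, surface, phase)


def simple_landmarks(apex_z=-100.0, avpd=0.0, radius=30.0):
    """Six landmarks on a circle in the base plane (centroid at the origin),
    ES copies shifted apically by ``avpd``."""
    angles = np.radians([160, 340, 200, 20, 270, 90])
    ed = {
        lbl: np.array([radius * np.cos(a), radius * np.sin(a), 0.0])
        for lbl, a in zip(LANDMARK_LABELS, angles)
    }
    es = {lbl: p + np.array([0.0, 0.0, -avpd]) for lbl, p in ed.items()}
    return LandmarkSet(ed=ed, es=es, apex_ed=np.array([0.0, 0.0, apex_z]))


def stack_of_squares(areas_cm2_ed, spacing=10.0, areas_cm2_es=None, avpd=0.0):
    """Stack whose k-th slice holds a square endocardial contour of the given
    area (cm^2); ES areas optional.  Slice k is centred at depth (k+1/2)*spacing."""
    slices = []
    n = len(areas_cm2_ed)
    for k in range(n):
        z = -(k + 0.5) * spacing
        ed = SlicePhase()
        if areas_cm2_ed[k] is not None:
            side = np.sqrt(areas_cm2_ed[k] * 100.0)
            ed.endocardial = square_contour(side, z, ENDOCARDIAL, ED)
            ed.epicardial = square_contour(side * 1.3, z, EPICARDIAL, ED)
        es = SlicePhase()
        if areas_cm2_es is not None and areas_cm2_es[k] is not None:
            side = np.sqrt(areas_cm2_es[k] * 100.0)
            es.endocardial = square_contour(side, z, ENDOCARDIAL, ES)
            es.epicardial = square_contour(side * 1.3, z, EPICARDIAL, ES)
        slices.append(
            Slice(index=k, origin=np.array([0.0, 0.0, z]),
                  normal=np.array([0.0, 0.0, -1.0]), ed=ed, es=es)
        )
    return ContourStack(
        subject_id="squares",
        slices=slices,
        slice_thickness_mm=spacing,
        slice_gap_mm=0.0,
        landmarks=simple_landmarks(apex_z=-n * spacing, avpd=avpd),
    )


@pytest.fixture(scope="session")
def control_phantom():
    """Fine-sliced control-like cylinder phantom and its analytic truth."""
    spec = PhantomSpec(n_slices=20, avpd_mm=15.3, lateral_inward_mm=3.0,
                       septal_inward_mm=2.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    spec = PhantomSpec(shape="ellipsoid", n_slices=10, seed=5)
    return generate_phantom(spec)
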