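import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lvgpm.geometry import SlicePlane
from lvgpm.phantom import (acquire_study, control_spec, infarct_spec,
                           make_phantom)
from lvgpm.study import CineStudy, StudySlice

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_truth():
    """Noise-free control phantom at the preset group-mean geometry."""
    return make_phantom(control_spec(seed=0, noise_sd_mm=0.0, jitter=False))


@pytest.fixture(scope="session")
def control_study(control_truth):
    """Noise-free acquisition of the control phantom (1 mm / 50 um)."""
    return acquire_study(control_truth)


@pytest.fixture(scope="session")
def infarct_truth39():
    """Noise-free infarcted phantom calibrated to a 39% akinetic area."""
    return make_phantom(infarct_spec(seed=1, noise_sd_mm=0.0,
                                     akinetic_fraction_pct=39.0,
                                     jitter=False))


def synthetic_study(n_sax: int, n_frames: int = 2, radius: float = 2.0,
                    thickness: float = 1.0) -> CineStudy:
    """Minimal hand-built study: circular contours on a parallel SAX stack.

    Slice radii shrink linearly toward the apex; frame 1 contours are 20%
    smaller than frame 0 so ED/ES selection is non-trivial.
    """
    theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    slices = []
    for k in range(n_sax):
        r0 = radius * (1.0 - 0.08 * k)
        plane = SlicePlane(origin=np.array([0.0, 0.0, -k * thickness]),
                           normal=np.array([0.0, 0.0, -1.0]),
                           axis_u=np.array([1.0, 0.0, 0.0]),
                           axis_v=np.array([0.0, -1.0, 0.0]),
                           slice_label="SAX", sax_index=k + 1)
        endo, epi = [], []
        for f in range(n_frames):
            r = r0 * (1.0 - 0.2 * f / max(n_frames - 1, 1))
            ring = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)
            endo.append(ring)
            epi.append(1.3 * ring)
        slices.append(StudySlice(plane=plane, endo=endo, epi=epi))
    for label, nrm in (("LAX_2CH", np.array([0.0, 1.0, 0.0])),
                       ("LAX_4CH", np.array([1.0, 0.0, 0.0]))):
        axis = np.array([0.0, 0.0, -1.0])
        plane = SlicePlane(origin=np.zeros(3), normal=nrm, axis_u=axis,
                           axis_v=np.cross(nrm, axis), slice_label=label)
        pts = np.array([[0.0, radius], [-n_sax * thickness, 0.0],
                        [0.0, -radius]])
        slices.append(StudySlice(plane=plane,
                                 endo=[pts.copy() for _ in range(n_frames)],
                                 epi=[1.3 * pts for _ in range(n_frames)]))
    mv = np.zeros((n_frames, 4, 3))
    mv[:, 0] = [radius, 0, 0.5]
    mv[:, 1] = [-radius, 0, 0.5]
    mv[:, 2] = [0, radius, 0.5]
    mv[:, 3] = [0, -radius, 0.5]
    return CineStudy(slices=slices, mv_points=mv, n_frames=n_frames,
                     slice_thickness_mm=thickness, pixel_size_mm=0.05)


@pytest.fixture
def study_factory():
    return synthetic_study
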