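import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cvmstage import Point2D, SubjectAnnotation, VertebraLandmarks, load_reference

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)


def make_square_subject(subject_id="S1", true_stage=None):
    """A hand-built subject with simple axis-aligned vertebrae.

    C3/C4 are 10x10 squares (SWIA 90, BW 5, BH 10, BS 0.5) with a 1 mm
    lower-border concavity; C2 has a 1 mm concavity.
    """
    def body(vid):
        return VertebraLandmarks(vid, {
            "lp": Point2D(0.0, 0.0), "la": Point2D(10.0, 0.0), "d": Point2D(5.0, 1.0),
            "up": Point2D(0.0, 10.0), "ua": Point2D(10.0, 10.0),
            "um": Point2D(5.0, 10.0), "am": Point2D(10.0, 5.0),
        })

    c2 = VertebraLandmarks("C2", {
        "lp": Point2D(0.0, 30.0), "la": Point2D(14.0, 30.0), "d": Point2D(7.0, 31.0),
    })
    return SubjectAnnotation(subject_id=subject_id, c2=c2, c3=body("C3"), c4=body("C4"),
                             true_stage=true_stage)


@pytest.fixture()
def square_subject():
    return make_square_subject()
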