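import numpy as np
import pytest

from faceswell import CameraModel, CohortConfig, FaceAnnotation, TrajectoryParams, build_head


@pytest.fixture(scope="session")
def head():
    return build_head()


@pytest.fixture(scope="session")
def planar_head():
    return build_head(nose_protrusion=0.0)


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def close_camera():
    """Short-focal camera for close-range distance sweeps (200-600 mm)."""
    return CameraModel(focal_px=3000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def square_annotation():
    """Hand-checkable annotation: level canthus line, nose on the bisector."""
    return FaceAnnotation(
        rat_id="r1",
        group="control",
        day=1,
        left_canthus=(100.0, 200.0),
        right_canthus=(400.0, 200.0),
        nose_tip=(250.0, 500.0),
        outline=np.array([(0.0, 0.0), (600.0, 0.0), (600.0, 700.0), (0.0, 700.0)]),
        image_size=(3000, 4000),
    )


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Small, fast cohort for pipeline tests (2 rats/arm, 3 days)."""
    return CohortConfig(
        n_control=2,
        n_model=2,
        n_positive=2,
        days=(1, 7, 12),
        trajectory=TrajectoryParams(),
    )


def random_annotation(gen: np.random.Generator) -> FaceAnnotation:
    """Random valid annotation: star-shaped (hence simple) outline around
    a random centre, canthi and nose drawn inside it."""
    cx, cy = gen.uniform(300, 2500), gen.uniform(300, 3500)
    n = int(gen.integers(6, 40))
    angles = np.sort(gen.uniform(0, 2 * np.pi, size=n))
    radii = gen.uniform(80, 250, size=n)
    outline = np.column_stack(
        [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
    )
    # landmarks well inside the minimal radius so the annotation validates
    r = 60.0
    a1, a2, a3 = gen.uniform(0, 2 * np.pi, size=3)
    left = (cx + gen.uniform(10, r) * np.cos(a1), cy + gen.uniform(10, r) * np.sin(a1))
    right = (cx + gen.uniform(10, r) * np.cos(a2), cy + gen.uniform(10, r) * np.sin(a2))
    nose = (cx + gen.uniform(0, r) * np.cos(a3), cy + gen.uniform(0, r) * np.sin(a3))
    return FaceAnnotation(
        rat_id="rand",
        group="model",
        day=0,
        left_canthus=left,
        right_canthus=right,
        nose_tip=nose,
        outline=outline,
    )
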