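"""Shared fixtures: reference runs and the condensation study are expensive
(seconds each), so they are computed once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

import embryodose as ed


@pytest.fixture(scope="session")
def default_masks() -> ed.GroundTruthMasks:
    return ed.make_embryo_geometry(ed.EmbryoGeometrySpec())


@pytest.fixture(scope="session")
def default_stack(default_masks) -> ed.ImageStack:
    return ed.render_stack(default_masks, snr=10, seed=2)


@pytest.fixture(scope="session")
def reference_1e4() -> ed.ReferenceResult:
    """Reference embryo, full imaging chain, 10^4 protons."""
    return ed.run_reference(ed.StudyConfig(seed=1, n_protons=10_000))


@pytest.fixture(scope="session")
def reference_1e3() -> ed.ReferenceResult:
    """Reference embryo, 10^3 protons (the lower delivered dose)."""
    return ed.run_reference(ed.StudyConfig(seed=1, n_protons=1_000))


@pytest.fixture(scope="session")
def study_result():
    """The 40-cell condensation study at 10^3 protons per cell."""
    return ed.run_condensation_study(ed.StudyConfig(seed=1))


@pytest.fixture()
def small_spec() -> ed.EmbryoGeometrySpec:
    """A miniature embryo for pitch-scaling and error-path tests."""
    return ed.EmbryoGeometrySpec(
        embryo_semiaxes=(6.0, 4.0, 3.0),
        ab_nucleus_center=(-2.0, 0.0, 0.0), ab_nucleus_diameter=2.4,
        p1_nucleus_center=(2.5, 0.0, 0.0), p1_nucleus_diameter=1.6,
        chromatin_state="metaphase", chromatin_volume=1.0)


@pytest.fixture()
def slab_phantom() -> ed.VoxelPhantom:
    """A 6 × 6 × 6 µm uniform water slab labelled as embryo tissue."""
    n = 30
    lab = np.full((n, n, n), 1, np.uint8)
    pitch = (0.2, 0.2, 0.2)
    shift = tuple(-(n - 1) / 2 * p for p in pitch)
    return ed.VoxelPhantom(label_grid=lab, voxel_pitch=pitch,
                           position_shift=shift)
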