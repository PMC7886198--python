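import numpy as np
import pytest
from hypothesis import settings

from strokedti.gradients import default_scheme
from strokedti.phantom import PhantomSpec, _tissues_for_stack, build_label_volume, simulate_dwi
from strokedti.tensor import eigendecompose, fit_tensor, scalar_maps

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """Study-geometry phantom: 64x64x16 grid, 0.156x0.156x0.75 mm voxels."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarser, smaller phantom for tests that iterate; same structure."""
    return PhantomSpec(
        grid_shape=(32, 32, 10),
        voxel_size=(0.25, 0.25, 0.6),
        brain_semiaxes=(3.5, 3.2, 2.6),
        bundle_radius=0.7,
        bundle_center_yz=(-1.2, 0.0),
        ventricle_semiaxes=(0.4, 0.8, 0.8),
        ventricle_center=(1.1, 1.2, 0.0),
        lesion_center=(1.8, -1.2, 0.0),
        lesion_radius_by_timepoint=(1.2, 0.8, 0.5),
    )


@pytest.fixture(scope="session")
def noiseless_day1(default_spec):
    """Noiseless day-1 phantom with its fitted maps (shared, read-only)."""
    labels = build_label_volume(default_spec, "day1")
    tissues = _tissues_for_stack(default_spec, "day1", None)
    dwi = simulate_dwi(labels, tissues, default_scheme(), snr=None, seed=0)
    eigs = eigendecompose(fit_tensor(dwi))
    return {
        "labels": labels,
        "tissues": tissues,
        "dwi": dwi,
        "eigs": eigs,
        "maps": scalar_maps(eigs),
    }


@pytest.fixture(scope="session")
def noiseless_symmetric(default_spec):
    """Noiseless lesion-free phantom: exactly mirror-symmetric by construction."""
    from dataclasses import replace

    spec = replace(default_spec, lesion_radius_by_timepoint=(0.0, 0.0, 0.0))
    labels = build_label_volume(spec, "day1")
    tissues = _tissues_for_stack(spec, "day1", None)
    dwi = simulate_dwi(labels, tissues, default_scheme(), snr=None, seed=0)
    eigs = eigendecompose(fit_tensor(dwi))
    return {
        "spec": spec,
        "labels": labels,
        "tissues": tissues,
        "eigs": eigs,
        "maps": scalar_maps(eigs),
    }
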