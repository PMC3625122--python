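import numpy as np
import pytest

from avmvpa import synth


@pytest.fixture(scope="session")
def small_geometry():
    """20x20x10 grid with three 30-voxel ROIs: fast but fully structured."""
    return synth.default_geometry((20, 20, 10), roi_voxels=30)


@pytest.fixture(scope="session")
def design_spec():
    return synth.DesignSpec()


@pytest.fixture(scope="session")
def design(design_spec):
    return synth.generate_design(design_spec, seed=101)


@pytest.fixture(scope="session")
def truth(small_geometry):
    return synth.default_ground_truth(small_geometry, seed=202)


@pytest.fixture(scope="session")
def patterns(truth, design):
    return synth.generate_trial_patterns(truth, design, seed=303)


def make_subject_patterns(
    seed,
    roi="V2",
    roi_voxels=150,
    n_runs=18,
    sigma=synth.DEFAULT_SIGMA,
    sigma_incongruent=synth.DEFAULT_SIGMA_INCONGRUENT,
    modulated_roi="V2",
    geometry=None,
):
    """One subject's trial patterns for a single ROI (helper, not a fixture)."""
    if geometry is None:
        geometry = synth.default_geometry(roi_voxels=roi_voxels)
    rng = np.random.default_rng(seed)
    s_design, s_truth, s_noise = (int(x) for x in rng.integers(2 ** 31, size=3))
    spec = synth.DesignSpec(n_runs=n_runs)
    design = synth.generate_design(spec, s_design)
    truth = synth.default_ground_truth(
        geometry,
        s_truth,
        sigma=sigma,
        sigma_incongruent=sigma_incongruent,
        modulated_roi=modulated_roi,
    )
    return synth.generate_trial_patterns(truth, design, s_noise)[roi]
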