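import numpy as np
import pytest

from herbniche.grid import GridSpec, RasterLayer, RasterStack
from herbniche.occurrences import OccurrenceRecord, OccurrenceSet


@pytest.fixture
def small_spec():
    return GridSpec(n_rows=30, n_cols=30, x_min=105.0, y_min=25.0, cell_size=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_stack(spec, arrays: dict) -> RasterStack:
    return RasterStack([RasterLayer(spec, n, v) for n, v in arrays.items()])


@pytest.fixture
def smooth_stack(small_spec, rng):
    """Three smooth environmental fields on a small grid."""
    from scipy.ndimage import gaussian_filter

    arrays = {}
    for name, mean, sd in [("precip", 1000.0, 200.0), ("temp", 15.0, 3.0),
                           ("noise", 0.0, 1.0)]:
        f = gaussian_filter(rng.standard_normal((30, 30)), 3, mode="reflect")
        f = (f - f.mean()) / f.std()
        arrays[name] = mean + sd * f
    return make_stack(small_spec, arrays)


@pytest.fixture
def niche_scene(smooth_stack, small_spec):
    """Presences drawn from a known Gaussian niche on the precip variable."""
    from herbniche.synth import TruthTerm, sample_presences, synth_truth_suitability

    truth = synth_truth_suitability(
        smooth_stack, (TruthTerm("precip", 1150.0, 80.0, 1.0),))
    occ = sample_presences(truth, 60, seed=7)
    return smooth_stack, truth, occ


@pytest.fixture
def occ_cluster():
    """20 points clustered within a few km plus some spread-out points."""
    rng = np.random.default_rng(3)
    base = [(110.0 + 0.01 * rng.standard_normal(),
             28.0 + 0.01 * rng.standard_normal()) for _ in range(20)]
    spread = [(100.0, 20.0), (101.0, 21.0), (102.5, 23.0)]
    return OccurrenceSet([OccurrenceRecord(lo, la) for lo, la in base + spread])
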