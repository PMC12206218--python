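import numpy as np
import pytest

from crosslight.data_model import BrainMask, LabeledDataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_mask():
    """5x5x5 all-inside mask with 3 mm voxels."""
    return BrainMask(inside=np.ones((5, 5, 5), dtype=bool), voxel_size_mm=3.0)


def make_dataset(n_trials_per_class=4, volumes_per_trial=3, n_features=6,
                 domain="source", seed=0, class_effect=1.0, trial_sd=0.0):
    """Small trial-structured dataset with an optional class effect on the
    first feature."""
    rng = np.random.default_rng(seed)
    rows, y, trial, run = [], [], [], []
    t = 0
    for cls in (0, 1):
        for _ in range(n_trials_per_class):
            u = rng.normal(0, trial_sd, n_features)
            for _ in range(volumes_per_trial):
                x = rng.normal(0, 1.0, n_features) + u
                x[0] += class_effect * (2 * cls - 1)
                rows.append(x)
                y.append(cls)
                trial.append(t)
                run.append(t % 2)
            t += 1
    return LabeledDataset(X=np.array(rows), y=np.array(y),
                          trial_id=np.array(trial), run_id=np.array(run),
                          domain=domain)


@pytest.fixture()
def toy_pair():
    src = make_dataset(domain="source", seed=1)
    tgt = make_dataset(domain="target", seed=2)
    return src, tgt
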