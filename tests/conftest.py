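import numpy as np
import pytest

from tumorline import synthetic


@pytest.fixture(scope="session")
def paper_cohort():
    """14 lines x 5 tumors with default parameters and missingness."""
    spec = synthetic.paper_like_cohort_spec(seed=11)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A full-featured noiseless marker-image phantom plus its truth."""
    spec = synthetic.ImagePhantomSpec(
        width=192, height=192, stain_fraction_target=0.3, n_vessels=8,
        perfused_fraction_target=0.75, n_nuclei=100, labeling_index_target=0.2,
        necrosis_fraction=0.15, noise_sd=0.0, seed=7)
    return synthetic.generate_marker_image(spec)


@pytest.fixture(scope="session")
def noiseless_volume():
    spec = synthetic.VolumePhantomSpec(dims=(40, 40, 20), semi_axes=(7.0, 7.0, 4.0),
                                       plateau_suv=2.0, background_suv=0.1,
                                       noise_sd=0.0, seed=5)
    return synthetic.generate_uptake_volume(spec)


def make_noise_table(n_lines=14, n_per_line=5, n_params=9, seed=0, prefix="p"):
    """Feature table whose columns carry no line information at all."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = n_lines * n_per_line
    lines = np.repeat([f"L{i + 1:02d}" for i in range(n_lines)], n_per_line)
    data = {f"{prefix}{j}": rng.normal(size=n) for j in range(n_params)}
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "line": lines,
        **data,
    })


def make_separable_table(n_lines=14, n_per_line=5, n_params=9, seed=0,
                         between_sd=5.0, within_sd=1.0):
    """Feature table with strong line separation on every parameter."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = n_lines * n_per_line
    line_idx = np.repeat(np.arange(n_lines), n_per_line)
    lines = np.array([f"L{i + 1:02d}" for i in range(n_lines)])[line_idx]
    data = {}
    for j in range(n_params):
        centers = rng.normal(0.0, between_sd, size=n_lines)
        data[f"p{j}"] = centers[line_idx] + rng.normal(0.0, within_sd, size=n)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "line": lines,
        **data,
    })
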