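import numpy as np
import pytest

from ddspls import BlockDataset, SyntheticSpec


def random_dataset(seed=0, n=12, block_sizes=(4, 3), q=2):
    """Unstructured Gaussian dataset for generic property tests."""
    rng = np.random.default_rng(seed)
    blocks = {
        f"B{t + 1}": rng.standard_normal((n, p)) * rng.uniform(0.5, 5)
        for t, p in enumerate(block_sizes)
    }
    return BlockDataset(
        blocks=blocks,
        block_column_names={
            name: [f"{name}c{j}" for j in range(X.shape[1])]
            for name, X in blocks.items()
        },
        response=rng.standard_normal((n, q)) * 7 + 50,
        response_names=[f"Y{m + 1}" for m in range(q)],
        row_ids=[f"id{i}" for i in range(n)],
    )


def planted_spec(seed=0, n=50, noise=0.1, q=3):
    """1-factor, 2-block spec with 3 active covariates (2 + 1)."""
    return SyntheticSpec(
        n=n,
        block_sizes=[20, 20],
        q=q,
        r_true=1,
        support=[[[0, 1]], [[0]]],
        x_loadings=[[[1.0, -1.0]], [[1.0]]],
        y_loadings=[[1.0, 0.5] + [0.0] * (q - 2)],
        noise_sd_x=noise,
        noise_sd_y=noise,
        seed=seed,
    )


@pytest.fixture
def small_data():
    return random_dataset(seed=1)
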