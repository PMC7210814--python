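import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mirtfnet.preprocess import ExpressionProfile


@pytest.fixture
def small_profile() -> ExpressionProfile:
    """Six features x six samples, 3 tumor + 3 normal, fixed values."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(6, 6)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(6)],
    )
    group = pd.Series([1, 1, 1, 0, 0, 0], index=values.columns)
    return ExpressionProfile(values, group)


def make_block_profile(
    blocks: list[tuple[int, float]],
    n_noise: int,
    n_samples: int = 40,
    seed: int = 0,
) -> tuple[ExpressionProfile, list[set[str]]]:
    """Genes in correlated blocks plus independent noise genes.

    Each (size, rho) block shares one latent factor with loading
    sqrt(rho/(1-rho)) against unit noise, giving pairwise correlation rho.
    """
    rng = np.random.default_rng(seed)
    rows, members, names = [], [], []
    for b, (size, rho) in enumerate(blocks):
        z = rng.normal(size=n_samples)
        loading = np.sqrt(rho / (1 - rho))
        block_names = [f"B{b}_{i}" for i in range(size)]
        for name in block_names:
            rows.append(loading * z + rng.normal(size=n_samples))
            names.append(name)
        members.append(set(block_names))
    for i in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        names.append(f"N{i}")
    values = pd.DataFrame(
        rows, index=names, columns=[f"S{i}" for i in range(n_samples)]
    )
    group = pd.Series(
        [1] * (n_samples // 2) + [0] * (n_samples - n_samples // 2),
        index=values.columns,
    )
    return ExpressionProfile(values, group), members
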