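from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from markermatch.manifest_io import Manifest


def random_manifest(
    rng: np.random.Generator,
    label: str,
    n: int,
    chroms=("1", "2"),
    pos_max: int = 50_000,
    name_prefix: str = "P",
    missing_frac: float = 0.1,
    positions=None,
) -> Manifest:
    """A random valid manifest; some annotations missing, co-located probes possible."""
    chrom = rng.choice(chroms, size=n)
    if positions is None:
        pos = rng.integers(1, pos_max + 1, size=n)
    else:
        pos = np.asarray(positions)

    def ann(low, high):
        vals = rng.uniform(low, high, size=n)
        vals[rng.random(n) < missing_frac] = np.nan
        return vals

    df = pd.DataFrame({
        "name": [f"{name_prefix}{i}" for i in range(n)],
        "chrom": chrom,
        "pos": pos,
        "baf": ann(0, 1),
        "lrr_mean": ann(-0.05, 0.05),
        "lrr_sd": ann(0.01, 0.3),
    })
    return Manifest(label, df)


def random_manifest_pair(rng: np.random.Generator, n_ref: int, n_match: int):
    """A reference/matching pair with some shared positions for the exact stage."""
    ref = random_manifest(rng, "ref", n_ref, name_prefix="R")
    match = random_manifest(rng, "match", n_match, name_prefix="M")
    # overwrite ~20% of matching positions with reference loci to force
    # exact-stage hits (and occasional contested co-located candidates)
    k = max(1, n_match // 5)
    take = rng.integers(0, n_ref, size=k)
    put = rng.choice(n_match, size=k, replace=False)
    df = match.df.copy()
    df.loc[df.index[put], "chrom"] = ref.df["chrom"].to_numpy()[take]
    df.loc[df.index[put], "pos"] = ref.df["pos"].to_numpy()[take]
    return ref, Manifest("match", df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture
def toy_manifest():
    return Manifest(
        "toy",
        pd.DataFrame({
            "name": ["p1", "p2", "p3", "q1", "q2"],
            "chrom": ["1", "1", "1", "2", "2"],
            "pos": [100, 200, 300, 50, 250],
            "baf": [0.1, 0.5, 0.9, 0.3, np.nan],
            "lrr_mean": [-0.002, 0.001, 0.0, np.nan, -0.01],
            "lrr_sd": [0.1, 0.12, 0.09, 0.2, 0.15],
        }),
    )
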