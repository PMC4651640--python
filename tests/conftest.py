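import numpy as np
import pytest

from intrameth.io import Dataset
from intrameth.measures import GeneProfile
from intrameth.synthetic import EffectSpec, generate_betas, generate_manifest


def make_planted_dataset(
    n_genes: int,
    n_planted: int,
    measure: str = "MEAN",
    effect_size: float = 0.2,
    noise_sd: float = 0.05,
    n_class0: int = 31,
    n_class1: int = 35,
    seed: int = 0,
) -> tuple[Dataset, list[str]]:
    """Synthetic two-class dataset with a planted one-measure effect."""
    manifest = generate_manifest(n_genes, (5, 20), seed=seed)
    genes = sorted(set(manifest["gene"]))
    rng = np.random.default_rng(seed + 1)
    planted = sorted(rng.choice(genes, size=n_planted, replace=False).tolist())
    effects = []
    if n_planted:
        effects = [EffectSpec(tuple(planted), measure, effect_size, noise_sd)]
    data = generate_betas(
        manifest, n_class0, n_class1, effects, noise_sd=noise_sd, seed=seed + 2
    )
    return Dataset(betas=data.betas, manifest=manifest, labels=data.labels), planted


def random_profile(rng: np.random.Generator, n: int | None = None) -> GeneProfile:
    n = n or int(rng.integers(5, 21))
    coords = np.cumsum(rng.integers(1, 500, size=n))
    return GeneProfile("G", rng.uniform(0, 1, size=n), coords)


@pytest.fixture(scope="session")
def small_planted():
    """200 genes, 20 with a strong MEAN shift; cheap enough to share."""
    return make_planted_dataset(200, 20, "MEAN", 0.2, 0.05, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 genes, no planted effect; for plumbing tests."""
    ds, _ = make_planted_dataset(60, 0, n_class0=10, n_class1=12, seed=7)
    return ds
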