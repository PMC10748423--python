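import numpy as np
import pytest

from screenrank import ScreenResult, SyntheticConfig, build_base_ranker, simulate_screens


@pytest.fixture
def small_config():
    """A desk-scale synthetic study: fast but structurally faithful."""
    return SyntheticConfig(
        n_genes=300,
        n_screens=4,
        coverages=(0.1, 0.25, 1.0, 1.0),
        n_true=12,
        seed=7,
    )


@pytest.fixture
def small_study(small_config):
    return simulate_screens(small_config)


def random_screen(rng: np.random.Generator, n_genes: int = 30, screen_id: str = "s"):
    """A random screen over ad-hoc symbols, some genes tested-only."""
    genes = [f"R{i:04d}" for i in range(n_genes)]
    tested = set(genes)
    records = {}
    for g in genes:
        if rng.random() < 0.9:  # ~10% tested-but-unmeasured
            records[g] = float(rng.random())
    return ScreenResult(
        screen_id=screen_id, measure_name="p", records=records, tested=tested
    )


def random_rankers(rng, n_screens=6, n_genes=50, alpha=0.3):
    """Base rankers over overlapping random subsets of a shared gene pool."""
    pool = [f"R{i:04d}" for i in range(n_genes)]
    rankers = []
    for s in range(n_screens):
        size = int(rng.integers(5, n_genes + 1))
        idx = rng.choice(n_genes, size=size, replace=False)
        tested = {pool[i] for i in idx}
        records = {g: float(rng.random()) for g in tested}
        screen = ScreenResult(
            screen_id=f"s{s}", measure_name="p", records=records, tested=tested
        )
        rankers.append(build_base_ranker(screen, alpha=alpha))
    return pool, rankers
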