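import numpy as np
import pytest

from pasbench.types import PasSet, PasSite


def make_set(positions, role="ground_truth", strand="+", chrom="chr1", scores=None, prefix=None):
    prefix = prefix or ("gt" if role == "ground_truth" else "pd")
    scores = scores if scores is not None else [1.0] * len(positions)
    sites = [
        PasSite(chrom, pos, strand, score, f"{prefix}{i}")
        for i, (pos, score) in enumerate(zip(positions, scores))
    ]
    return PasSet(f"{prefix}_sample", role, sites)


def random_pas_set(rng, n, role, max_pos=3000, chroms=("chr1", "chr2")):
    sites = []
    for i in range(n):
        sites.append(
            PasSite(
                chrom=str(rng.choice(chroms)),
                pos=int(rng.integers(0, max_pos)),
                strand=str(rng.choice(["+", "-"])),
                score=float(rng.uniform(0, 100)),
                site_id=f"{role[:2]}{i}",
            )
        )
    return PasSet("rand", role, sites)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    """Noise-free scenario: predictions coincide with ground truth."""
    from pasbench.synth import SyntheticScenario, generate

    ds = generate(SyntheticScenario(seed=11, n_genes=40, pas_per_te=2, equal_usage=True))
    paths = ds.write(tmp_path_factory.mktemp("noiseless"))
    return ds, paths
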