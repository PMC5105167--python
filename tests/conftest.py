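import numpy as np
import pytest

from glycosim import (
    GlycanComposition,
    ModificationIsoform,
    ProteinModel,
    SiteTable,
)


def random_model(rng: np.random.Generator, n_sites: int, max_isoforms: int = 4,
                 backbone: float = 20_000.0) -> ProteinModel:
    """Small random model with raw-mass isoforms, for oracle comparisons."""
    sites = []
    for i in range(n_sites):
        k = int(rng.integers(1, max_isoforms + 1))
        isoforms = tuple(
            ModificationIsoform(
                label=f"iso{j}",
                delta=float(rng.uniform(0.0, 2_000.0)),
                abundance=float(rng.uniform(0.05, 10.0)),
            )
            for j in range(k)
        )
        sites.append(SiteTable(f"S{i}", isoforms))
    return ProteinModel(name="random", backbone_mass=backbone, sites=tuple(sites))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_site_model():
    """2 sites x 2 isoforms, uniform, deltas 0/100 Da on a 1 kDa backbone."""
    site = lambda sid: SiteTable(
        sid,
        (
            ModificationIsoform("none", GlycanComposition(), 1.0),
            ModificationIsoform("plus100", 100.0, 1.0),
        ),
    )
    return ProteinModel(name="toy", backbone_mass=1_000.0, sites=(site("A"), site("B")))
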