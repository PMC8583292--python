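import sys
from pathlib import Path

import pytest
from shapely.geometry import Polygon

from ecodegrade.features import EcosystemFeature
from ecodegrade.io import load_bundled_scheme
from ecodegrade.scoring import batch_score
from ecodegrade.synthetic import SimulationSpec, simulate_grassland

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

ALL_KINDS = ("grassland", "cave", "river", "lake", "coastal")


@pytest.fixture(scope="session")
def base_spec():
    """Mid-size clustered landscape shared across read-only tests."""
    return SimulationSpec(
        n_features={k: 300 for k in ALL_KINDS},
        prevalence={k: 0.3 for k in ALL_KINDS} | {"forest": 0.2},
        cluster_count=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def scored_grassland(base_spec):
    feats = simulate_grassland(base_spec)
    feats, _ = batch_score(feats, load_bundled_scheme("grassland"))
    return feats


def square(x, y, side=1000.0, **kw):
    """Square polygon feature helper centered at (x, y)."""
    h = side / 2
    geom = Polygon([(x - h, y - h), (x + h, y - h), (x + h, y + h), (x - h, y + h)])
    defaults = dict(feature_id=f"sq-{x}-{y}", kind="grassland", geometry=geom)
    defaults.update(kw)
    return EcosystemFeature(**defaults)
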