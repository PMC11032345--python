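import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

from acprop.aadata import AA_ORDER  # noqa: E402
from acprop.synthetic import StudyConfig, generate_study  # noqa: E402


def random_sequences(n: int, length_range=(40, 120), seed: int = 0) -> list[str]:
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        length = int(rng.integers(*length_range))
        out.append("".join(AA_ORDER[i] for i in rng.integers(0, 20, size=length)))
    return out


@pytest.fixture(scope="session")
def small_bundle():
    """A compact study: 12 kinases, 6 scaffolds x 4 substituents each."""
    cfg = StudyConfig(
        n_kinases=12,
        class_mixture={"No ACs": 0.34, "Low ACs": 0.33, "High ACs": 0.33},
        seq_length_range=(120, 300),
        n_scaffolds_per_kinase=10,
        substituents_per_scaffold=5,
        cliff_rate={"No ACs": 0.0, "Low ACs": 0.005, "High ACs": 0.05},
        seed=42,
    )
    return generate_study(cfg)
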