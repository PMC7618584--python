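import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kneealign.landmarks import SchemaId
from kneealign.synthetic import make_template

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def templates():
    """One deterministic template per schema at the default 512 px frame."""
    return {sid: make_template(sid) for sid in SchemaId}


@pytest.fixture(scope="session")
def pre_original_template(templates):
    return templates[SchemaId.PRE_ORIGINAL]


def random_landmark_sets(n, seed, schemas=tuple(SchemaId)):
    """Valid random landmark sets: template + injected angle + jitter."""
    from kneealign.synthetic import SimulationConfig, degrade, inject_alignment

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sid = schemas[i % len(schemas)]
        tpl = make_template(sid)
        t = float(rng.uniform(-15, 15))
        cfg = SimulationConfig(
            point_noise_sd_px=float(rng.uniform(0, 2)),
            global_rotation_deg=float(rng.uniform(-10, 10)),
            seed=int(rng.integers(0, 2**31 - 1)))
        out.append(degrade(inject_alignment(tpl, t), cfg))
    return out
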