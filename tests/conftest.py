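import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def toy_binary(tmp_path):
    """4-row binary validation CSV: outcomes {1,1,0,0}."""
    path = tmp_path / "binary.csv"
    path.write_text(
        "outcome,model\n"
        "1,0.9\n"
        "1,0.2\n"
        "0,0.6\n"
        "0,0.1\n"
    )
    return path


@pytest.fixture
def toy_survival(tmp_path):
    path = tmp_path / "survival.csv"
    rows = ["time,event,model"]
    gen = np.random.default_rng(7)
    t = gen.weibull(1.3, 40) * 15
    e = (gen.random(40) < 0.8).astype(int)
    r = gen.random(40)
    for ti, ei, ri in zip(t, e, r):
        rows.append(f"{max(ti, 0.01):.4f},{ei},{ri:.4f}")
    path.write_text("\n".join(rows) + "\n")
    return path
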