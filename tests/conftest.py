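import numpy as np
import pandas as pd
import pytest

from simmg_eval import FunctionalProfile, SyntheticConfig, generate_study

SMALL_REGION_COUNTS = {
    "MG-only": 5,
    "MT-only": 4,
    "sim-only": 3,
    "MG∩MT-only": 2,
    "MG∩sim-only": 2,
    "MT∩sim-only": 2,
    "MG∩MT∩sim": 10,
}


@pytest.fixture(scope="session")
def default_study():
    """The default-condition synthetic study (9 samples, planted regions)."""
    return generate_study(SyntheticConfig(seed=42))


@pytest.fixture()
def small_noiseless_study():
    """A small noiseless study with 4 planted contaminants."""
    cfg = SyntheticConfig(
        region_counts=dict(SMALL_REGION_COUNTS),
        contaminant_count=4,
        presence_noise=0.0,
        n_asvs=30,
        n_high_nsti=3,
        seed=7,
    )
    return generate_study(cfg)


def make_profile(
    presence_by_method: dict[str, dict[str, list[int]]],
    samples: list[str],
    level: str = "pathway",
) -> dict[str, FunctionalProfile]:
    """Build per-method profiles from explicit 0/1 presence patterns.

    ``presence_by_method[method][feature]`` is a 0/1 list over samples.
    """
    out = {}
    for method, rows in presence_by_method.items():
        df = pd.DataFrame(
            {f: pd.Series(np.asarray(v, dtype=float), index=samples) for f, v in rows.items()}
        ).T
        df = df * 7.5  # arbitrary positive abundance where present
        out[method] = FunctionalProfile(method, level, df)
    return out
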