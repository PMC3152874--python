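import numpy as np
import pandas as pd
import pytest

from lactqtl.wood import WoodParams


def wood_records(a, b, c, days=None, noise_sd=0.0, rng=None):
    """Records generated exactly (or with lognormal noise) from a Wood curve."""
    if days is None:
        days = np.arange(2, 201, 2.0)
    w = a * days**b * np.exp(-c * days)
    if noise_sd > 0:
        w = w * np.exp(rng.normal(0.0, noise_sd, days.size))
    return pd.DataFrame({"day": days, "value": w})


def random_wood_params(rng, n=1):
    """Valid declining Wood parameter draws spanning realistic curves."""
    out = []
    for _ in range(n):
        out.append(
            WoodParams(
                a=float(rng.uniform(0.5, 20.0)),
                b=float(rng.uniform(0.05, 1.0)),
                c=float(rng.uniform(0.005, 0.08)),
                n_obs=10,
            )
        )
    return out[0] if n == 1 else out


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """Small synthetic study bundle shared across integration tests."""
    from lactqtl.simulate import SimulationConfig, QTLSpec, end_to_end_fixture

    cfg = SimulationConfig(
        n_daughters=80,
        n_chromosomes=3,
        n_markers=12,
        n_lactations=1,
        qtl=[QTLSpec(chromosome=1, position_cM=60.0, target="direct",
                     trait="MY", measure="persistency", effect_sd=0.9)],
        seed=77,
    )
    outdir = tmp_path_factory.mktemp("study")
    bundle = end_to_end_fixture(cfg, outdir)
    bundle["config"] = cfg
    bundle["outdir"] = outdir
    return bundle
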