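import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import twinmeth as tm
from twinmeth.core_io import BetaMatrix, TwinDesign

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_discordant_design(pair_values, age_wave=10, covariates=None):
    """Build (BetaMatrix, TwinDesign) from {probe: [(beta_aff, beta_unaff), ...]}.

    Every probe shares the same pairs; ``pair_values`` maps probe id to the
    per-pair (affected, unaffected) beta tuples.
    """
    probes = list(pair_values)
    n_pairs = len(next(iter(pair_values.values())))
    rows, values = [], {}
    for i in range(n_pairs):
        pid = f"P{i + 1:02d}"
        values[f"{pid}A"] = [pair_values[p][i][0] for p in probes]
        values[f"{pid}U"] = [pair_values[p][i][1] for p in probes]
        rows.append((f"{pid}A", pid, "affected", "discordant", age_wave))
        rows.append((f"{pid}U", pid, "unaffected", "discordant", age_wave))
    frame = pd.DataFrame(rows, columns=["sample_id", "pair_id", "role", "group", "age_wave"])
    if covariates:
        for name, mapping in covariates.items():
            frame[name] = frame["sample_id"].map(mapping)
    beta = BetaMatrix(pd.DataFrame(values, index=pd.Index(probes, name="probe_id")))
    return beta, TwinDesign(frame)


@pytest.fixture(scope="session")
def small_study():
    """A compact generated twin study reused across read-only tests."""
    cfg = tm.SimulationConfig(
        n_probes=800,
        n_discordant_pairs=12,
        n_concordant_pairs=8,
        n_pairs_age5=8,
        n_spiked=6,
        spike_delta_range=(0.05, 0.09),
        seed=7,
    )
    return tm.simulate_twin_methylome(cfg)


@pytest.fixture(scope="session")
def null_study():
    """No spiked effects: every probe obeys the within-pair null."""
    cfg = tm.SimulationConfig(
        n_probes=2000,
        n_discordant_pairs=24,
        n_concordant_pairs=4,
        n_pairs_age5=0,
        n_spiked=0,
        seed=19,
    )
    return tm.simulate_twin_methylome(cfg)
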