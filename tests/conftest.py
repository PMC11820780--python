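import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_registry():
    from srmquant.datasets import fixture_registry

    return fixture_registry()


@pytest.fixture(scope="session")
def small_run():
    """A 10-analyte simulated validation run with ground truth.

    Session-scoped: several test modules probe the same run from different
    angles (calibration, recovery, quantification).
    """
    from srmquant import pipeline, synthetic

    ids = [f"a{i:02d}" for i in range(10)]
    truth = synthetic.make_truth(ids, seed=11)
    plan = synthetic.plan_validation_sequence(ids, sample_ids=["s1", "s2"], seed=11)
    table = synthetic.simulate_peak_table(truth, plan, seed=12)
    corrected = pipeline.bracket_drift_correct(table)
    curves = pipeline.fit_curves(corrected)
    designs = {
        a: synthetic.build_spiking_design(a, native_conc=truth.native_conc[a])
        for a in ids
    }
    return {
        "ids": ids,
        "truth": truth,
        "plan": plan,
        "table": table,
        "corrected": corrected,
        "curves": curves,
        "designs": designs,
    }
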