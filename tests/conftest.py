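import numpy as np
import pytest

from atonia import staging, synthetic


@pytest.fixture(scope="session")
def control_animal():
    """One staged control animal (2-h session) shared across test modules."""
    params = synthetic.phenotype_for_group("control_young")
    rng = np.random.default_rng(12345)
    truth = synthetic.simulate_hypnogram(params, 1800, 900, rng)
    rec = synthetic.synthesize_signals(
        truth, params, rng, animal_id="ctrl01", group="control_young"
    )
    rec.lights_off_at = 3600.0
    hyp, features, thresholds = staging.stage_recording(rec)
    return {
        "params": params,
        "truth": truth,
        "recording": rec,
        "hypnogram": hyp,
        "features": features,
        "thresholds": thresholds,
    }
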