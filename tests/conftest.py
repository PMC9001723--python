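import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def mixed_session():
    """One simulated session cycling through WAKE/NREM/REM bouts, with truth."""
    from sleepgate import synth

    plan = synth.Hypnogram.from_bouts(
        [
            (120, "WAKE"), (240, "NREM"), (120, "REM"), (240, "NREM"),
            (120, "REM"), (120, "WAKE"), (240, "NREM"), (120, "REM"),
            (240, "NREM"), (120, "WAKE"),
        ]
    )
    rec, truth = synth.simulate_session(plan, rng=3)
    return rec, truth


@pytest.fixture(scope="session")
def learner_table():
    """Long power table from a learner-cohort NREM simulation (3 sounds,
    6 animals x 7 presentations each), states taken from ground truth."""
    from sleepgate import power, synth

    eps = []
    kids = np.random.SeedSequence(7).spawn(3)
    for k, sound in zip(kids, synth.SOUND_TYPES):
        eps += synth.simulate_presentation_epochs(
            42, "NREM", sound, cohort="learner", seed=k, n_animals=6
        )
    pows = power.run_pipeline(eps, use_scored_state=False)
    return power.to_long_table(pows)
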