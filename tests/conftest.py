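import numpy as np
import pytest

from fastscore.fixture import study_fixture
from fastscore.scoring import EncounterObservation


@pytest.fixture(scope="session")
def fixture_data():
    """The reconstructed 118-encounter development cohort."""
    return study_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_observation(rng, missing_rate=0.1):
    """A random valid EncounterObservation with independent missingness."""
    def maybe(v):
        return None if rng.random() < missing_rate else v

    return EncounterObservation(
        encounter_id=f"R{rng.integers(1e6):06d}",
        bun_trend_pct=maybe(float(rng.normal(-10, 25))),
        urine_specific_gravity=maybe(float(rng.uniform(0.992, 1.045))),
        fluid_balance_ml_kg_day=maybe(float(rng.normal(20, 25))),
        weight_change_pct=maybe(float(rng.normal(6, 7))),
        urine_output_ml_kg_h=maybe(float(rng.uniform(0, 6))),
        on_diuretics_or_renal_failure=bool(rng.random() < 0.2),
        fontanelle=maybe(str(rng.choice(["flat", "full", "bulging", "bulging_tense", "closed"]))),
        eyes=maybe(str(rng.choice(["normal", "swollen", "puffy_conjunctival_edema", "puffy_unable_to_open"]))),
        liver_cm_below_costal_margin=maybe(float(rng.uniform(0, 5))),
        skin=maybe(str(rng.choice(["no_edema", "limbs_or_abdomen", "limbs_and_face", "anasarca"]))),
        cxr_grade=maybe(str(rng.choice(["none", "mild", "moderate", "severe"]))),
    )
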