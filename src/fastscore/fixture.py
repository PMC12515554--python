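"""The reconstructed 118-encounter FAST development cohort.

The pilot cohort behind the score — 118 PICU encounters from 32 patients,
78 TFC-high and 40 TFC-normal — was published only as a cut-point table
(sensitivity / specificity / correctly classified for cuts 0..8).  Those
two columns are per-class survivor functions of the integer score, so the
score x label dataset is recoverable exactly: differencing adjacent
survivor values and scaling by the class size gives the per-score counts
(scores >= 8 lumped at 8, which cannot affect any cut <= 8).

This module embeds those published proportions as constants and rebuilds
the cohort on demand; :data:`FIXTURE_CSV` is the same dataset shipped as
a versioned CSV asset.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .validation import LabeledScore, reconstruct_fixture

__all__ = [
    "SENSITIVITY",
    "SPECIFICITY",
    "N_POS",
    "N_NEG",
    "CUTS",
    "study_fixture",
    "fixture_frame",
    "write_fixture_csv",
    "load_fixture_csv",
    "FIXTURE_CSV",
]

#: Published operating characteristics per cut (proportions, cuts 0..8).
CUTS = tuple(range(9))
SENSITIVITY = (1.0000, 0.9872, 0.9487, 0.9231, 0.7949, 0.6154, 0.3590, 0.2308, 0.1154)
SPECIFICITY = (0.0000, 0.3000, 0.5000, 0.6750, 0.8000, 0.9000, 0.9250, 0.9250, 0.9500)

#: Class sizes: 78 of 118 encounters exhibited high TFC.
N_POS = 78
N_NEG = 40

FIXTURE_CSV = "data/study_fixture.csv"


def study_fixture() -> list[LabeledScore]:
    """Rebuild the 118-encounter cohort from the embedded survivor proportions."""
    survivor_neg = tuple(1 - s for s in SPECIFICITY)
    return reconstruct_fixture(SENSITIVITY, survivor_neg, N_POS, N_NEG)


def fixture_frame() -> pd.DataFrame:
    """The fixture as a tidy frame: encounter_id, score, tfc_high (0/1)."""
    data = study_fixture()
    return pd.DataFrame(
        {
            "encounter_id": [d.encounter_id for d in data],
            "score": [d.score for d in data],
            "tfc_high": [int(d.tfc_high) for d in data],
        }
    )


def write_fixture_csv(path) -> None:
    """Regenerate the packaged fixture CSV at ``path``."""
    fixture_frame().to_csv(path, index=False)


def load_fixture_csv() -> pd.DataFrame:
    """Load the packaged CSV asset (identical to :func:`fixture_frame`)."""
    with resources.files(__package__).joinpath(FIXTURE_CSV).open() as fh:
        return pd.read_csv(fh)
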