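"""Seeded synthetic PICU cohorts with a known latent fluid-overload state.

Each encounter carries a latent binary state (fluid-overloaded or not);
raw FAST variables are emitted from state-conditional distributions —
normals for the numeric variables (clipped into their physiologic
domains), two probability vectors over the four ordinal levels for each
categorical exam finding.  TFC is emitted from its own state-conditional
normal and thresholded into the binary high-TFC reference label, so the
label is a noisy proxy of the latent state, as in real impedance
cardiography.  Outcomes are negative-binomial day counts built
cumulatively (ventilator <= PICU <= hospital by construction).

The defaults emulate a moderately separated ~two-thirds-prevalence
cohort of 118 encounters.  They are illustrative — chosen so the two
latent classes' FAST-score distributions resemble the reconstructed
development cohort (class means near 5 and 2) — not estimates of any
real population.  Everything is reproducible byte-for-byte from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import scoring
from .outcomes import OutcomeRecord
from .scoring import EncounterObservation, score_frame
from .validation import DegenerateInputError, LabeledScore, cutpoint_table

__all__ = [
    "NormalEmission",
    "CategoricalEmission",
    "TFCModel",
    "OutcomeModel",
    "SyntheticCohortParams",
    "SyntheticCohort",
    "default_params",
    "generate_cohort",
    "recover_operating_characteristics",
    "RecoveryReport",
]


@dataclass(frozen=True)
class NormalEmission:
    """State-conditional normal: (normal-state, overloaded-state) location/scale."""

    loc: tuple
    scale: tuple
    clip: tuple = (None, None)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scales must be positive, got {self.scale}")

    def draw(self, rng: np.random.Generator, state: np.ndarray) -> np.ndarray:
        loc = np.where(state, self.loc[1], self.loc[0])
        scale = np.where(state, self.scale[1], self.scale[0])
        x = rng.normal(loc, scale)
        lo, hi = self.clip
        if lo is not None or hi is not None:
            x = np.clip(x, lo, hi)
        return x


@dataclass(frozen=True)
class CategoricalEmission:
    """State-conditional probability vectors over the four ordinal levels."""

    probs: tuple  # (4-vector for normal state, 4-vector for overloaded state)

    def __post_init__(self) -> None:
        for p in self.probs:
            arr = np.asarray(p, dtype=float)
            if arr.shape != (4,) or np.any(arr < 0) or abs(arr.sum() - 1) > 1e-9:
                raise ValueError(f"probability vector must be 4 non-negatives summing to 1: {p}")

    def draw(self, rng: np.random.Generator, state: np.ndarray, levels: tuple) -> np.ndarray:
        out = np.empty(len(state), dtype=object)
        for s in (0, 1):
            idx = np.flatnonzero(state == s)
            if len(idx):
                draws = rng.choice(4, size=len(idx), p=np.asarray(self.probs[s], dtype=float))
                out[idx] = np.array(levels, dtype=object)[draws]
        return out


@dataclass(frozen=True)
class TFCModel:
    """State-conditional TFC emission and the high-TFC threshold."""

    loc: tuple = (32.0, 52.0)
    scale: tuple = (8.0, 12.0)
    threshold: float = 40.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scales must be positive, got {self.scale}")


@dataclass(frozen=True)
class OutcomeModel:
    """Negative-binomial day counts, built cumulatively per state.

    ``vent_mean`` is the mean ventilator days; PICU adds
    ``picu_extra_mean`` days on top, hospital adds ``hosp_extra_mean``
    more, so the nesting ventilator <= PICU <= hospital always holds.
    """

    vent_mean: tuple = (9.0, 12.0)
    picu_extra_mean: tuple = (6.0, 8.0)
    hosp_extra_mean: tuple = (3.0, 4.0)
    dispersion: float = 2.5

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _default_emissions() -> dict:
    return {
        "bun_trend_pct": NormalEmission(loc=(-5.0, -12.0), scale=(8.0, 12.0)),
        "urine_specific_gravity": NormalEmission(
            loc=(1.014, 1.010), scale=(0.006, 0.005), clip=(0.991, 1.040)
        ),
        "fluid_balance_ml_kg_day": NormalEmission(loc=(5.0, 15.0), scale=(10.0, 13.0)),
        "weight_change_pct": NormalEmission(loc=(2.0, 5.0), scale=(3.0, 4.0)),
        "urine_output_ml_kg_h": NormalEmission(
            loc=(2.2, 2.8), scale=(0.7, 1.0), clip=(0.05, None)
        ),
        "liver_cm_below_costal_margin": NormalEmission(
            loc=(0.5, 1.0), scale=(0.7, 1.0), clip=(0.0, None)
        ),
        "fontanelle": CategoricalEmission(
            probs=((0.85, 0.10, 0.04, 0.01), (0.40, 0.30, 0.20, 0.10))
        ),
        "eyes": CategoricalEmission(
            probs=((0.85, 0.10, 0.04, 0.01), (0.55, 0.25, 0.13, 0.07))
        ),
        "skin": CategoricalEmission(
            probs=((0.85, 0.10, 0.04, 0.01), (0.55, 0.25, 0.13, 0.07))
        ),
        "cxr_grade": CategoricalEmission(
            probs=((0.80, 0.12, 0.06, 0.02), (0.50, 0.28, 0.15, 0.07))
        ),
    }


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Everything that determines a synthetic cohort, seed included."""

    n_encounters: int = 118
    prevalence: float = 0.66
    emissions: dict = field(default_factory=_default_emissions)
    fontanelle_closed_rate: float = 0.60
    diuretics_rate: float = 0.30
    missing_rate: float = 0.05
    tfc_model: TFCModel = field(default_factory=TFCModel)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be positive")
        for name in ("prevalence", "fontanelle_closed_rate", "diuretics_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        missing = set(_default_emissions()) - set(self.emissions)
        if missing:
            raise ValueError(f"emissions missing for variables: {sorted(missing)}")


def default_params(**overrides) -> SyntheticCohortParams:
    """The default parameter set, with keyword overrides."""
    return replace(SyntheticCohortParams(), **overrides)


@dataclass
class SyntheticCohort:
    """One generated cohort: raw observations, TFC, outcomes, latent truth."""

    observations: list
    observations_frame: pd.DataFrame
    tfc: pd.DataFrame  # encounter_id, tfc_value, tfc_high
    outcomes: list
    latent: np.ndarray  # 1 = fluid-overloaded

    def labeled_scores(self, valid_only: bool = True) -> list:
        """Score the raw observations and pair with the TFC label.

        By default, encounters with more than two missing variables are
        excluded, mirroring the scoring module's validity policy.
        """
        scored = score_frame(self.observations_frame)
        out = []
        for e, t, v, h in zip(
            scored["encounter_id"], scored["total"], scored["valid"], self.tfc["tfc_high"]
        ):
            if v or not valid_only:
                out.append(LabeledScore(str(e), int(t), bool(h)))
        return out


_NUM_FIELDS = (
    "bun_trend_pct",
    "urine_specific_gravity",
    "fluid_balance_ml_kg_day",
    "weight_change_pct",
    "urine_output_ml_kg_h",
    "liver_cm_below_costal_margin",
)
_CAT_FIELDS = {
    "fontanelle": scoring.FONTANELLE_LEVELS,
    "eyes": scoring.EYES_LEVELS,
    "skin": scoring.SKIN_LEVELS,
    "cxr_grade": scoring.CXR_LEVELS,
}


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB parameterized by mean m and shape k: p = k / (k + m)
    k = dispersion
    return rng.negative_binomial(k, k / (k + np.asarray(mean, dtype=float)))


def _sample_frame(params: SyntheticCohortParams, n: int, seed: int):
    """Draw n encounters as plain frames (fast path for large n)."""
    rng = np.random.default_rng(seed)
    latent = (rng.random(n) < params.prevalence).astype(int)
    ids = np.array([f"S{i + 1:06d}" for i in range(n)], dtype=object)

    obs = pd.DataFrame({"encounter_id": ids, "patient_id": ids})
    for name in _NUM_FIELDS:
        obs[name] = params.emissions[name].draw(rng, latent)
    obs["on_diuretics_or_renal_failure"] = rng.random(n) < params.diuretics_rate
    for name, levels in _CAT_FIELDS.items():
        obs[name] = params.emissions[name].draw(rng, latent, levels)
    closed = rng.random(n) < params.fontanelle_closed_rate
    obs.loc[closed, "fontanelle"] = scoring.FONTANELLE_CLOSED
    # independent per-variable missingness on every optional variable
    for name in _NUM_FIELDS + tuple(_CAT_FIELDS):
        drop = rng.random(n) < params.missing_rate
        obs.loc[drop, name] = np.nan

    t = params.tfc_model
    tfc_value = rng.normal(
        np.where(latent, t.loc[1], t.loc[0]), np.where(latent, t.scale[1], t.scale[0])
    )
    tfc = pd.DataFrame(
        {
            "encounter_id": ids,
            "tfc_value": tfc_value,
            "tfc_high": (tfc_value >= t.threshold).astype(int),
        }
    )

    om = params.outcome_model
    vent = _negbin(rng, np.where(latent, om.vent_mean[1], om.vent_mean[0]), om.dispersion)
    picu = vent + _negbin(
        rng, np.where(latent, om.picu_extra_mean[1], om.picu_extra_mean[0]), om.dispersion
    )
    hosp = picu + _negbin(
        rng, np.where(latent, om.hosp_extra_mean[1], om.hosp_extra_mean[0]), om.dispersion
    )
    out = pd.DataFrame(
        {
            "encounter_id": ids,
            "ventilator_days": vent,
            "picu_days": picu,
            "hospital_days": hosp,
        }
    )
    return obs, tfc, out, latent


def generate_cohort(params: SyntheticCohortParams) -> SyntheticCohort:
    """Generate one cohort from validated params; identical seed, identical cohort."""
    obs_df, tfc, out_df, latent = _sample_frame(params, params.n_encounters, params.seed)
    observations = []
    for _, row in obs_df.iterrows():
        kwargs = {"encounter_id": row["encounter_id"], "patient_id": row["patient_id"]}
        for name in _NUM_FIELDS:
            if pd.notna(row[name]):
                kwargs[name] = float(row[name])
        for name in _CAT_FIELDS:
            if isinstance(row[name], str):
                kwargs[name] = row[name]
        kwargs["on_diuretics_or_renal_failure"] = bool(row["on_diuretics_or_renal_failure"])
        observations.append(EncounterObservation(**kwargs))
    outcomes = [
        OutcomeRecord(
            encounter_id=str(r["encounter_id"]),
            ventilator_days=float(r["ventilator_days"]),
            picu_days=float(r["picu_days"]),
            hospital_days=float(r["hospital_days"]),
        )
        for _, r in out_df.iterrows()
    ]
    return SyntheticCohort(
        observations=observations,
        observations_frame=obs_df,
        tfc=tfc,
        outcomes=outcomes,
        latent=latent,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Small-sample bias/RMSE of the operating characteristics at one cut."""

    cut: int
    truth_sensitivity: float
    truth_specificity: float
    bias_sensitivity: float
    bias_specificity: float
    rmse_sensitivity: float
    rmse_specificity: float
    n_replicates: int
    n_per_replicate: int
    oracle_n: int


def _operating_point(obs_df, tfc, cut):
    scored = score_frame(obs_df)
    scores = scored["total"].to_numpy()
    valid = scored["valid"].to_numpy(dtype=bool)
    labels = tfc["tfc_high"].to_numpy(dtype=bool)
    scores, labels = scores[valid], labels[valid]
    if labels.all() or not labels.any():
        raise DegenerateInputError("synthetic cohort produced a single TFC class")
    sens = float((scores[labels] >= cut).mean())
    spec = float((scores[~labels] < cut).mean())
    return sens, spec


def recover_operating_characteristics(
    params: SyntheticCohortParams,
    n_replicates: int = 500,
    cut: int = 3,
    n_per_replicate: int = 118,
    oracle_n: int = 1_000_000,
) -> RecoveryReport:
    """Bias and RMSE of sensitivity/specificity at the study sample size.

    Ground truth comes from a single large Monte-Carlo cohort (same
    params, ``oracle_n`` encounters); each replicate re-estimates the
    operating point at ``n_per_replicate`` encounters.  Demonstrates the
    small-sample variability inherent to a 118-encounter pilot.
    """
    seeds = np.random.SeedSequence(params.seed).generate_state(n_replicates + 1) % (2**31)
    obs_df, tfc, _, _ = _sample_frame(params, oracle_n, int(seeds[0]))
    truth_sens, truth_spec = _operating_point(obs_df, tfc, cut)
    est = []
    for r in range(n_replicates):
        obs_df, tfc, _, _ = _sample_frame(params, n_per_replicate, int(seeds[r + 1]))
        est.append(_operating_point(obs_df, tfc, cut))
    est = np.array(est)
    return RecoveryReport(
        cut=cut,
        truth_sensitivity=truth_sens,
        truth_specificity=truth_spec,
        bias_sensitivity=float(est[:, 0].mean() - truth_sens),
        bias_specificity=float(est[:, 1].mean() - truth_spec),
        rmse_sensitivity=float(np.sqrt(((est[:, 0] - truth_sens) ** 2).mean())),
        rmse_specificity=float(np.sqrt(((est[:, 1] - truth_spec) ** 2).mean())),
        n_replicates=n_replicates,
        n_per_replicate=n_per_replicate,
        oracle_n=oracle_n,
    )
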