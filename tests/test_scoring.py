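"""Unit and property tests for the per-variable scorers and the FAST total."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastscore import scoring
from fastscore.scoring import (
    EncounterObservation,
    ValidationError,
    compute_fast,
    read_encounters,
    score_bun_trend,
    score_cxr,
    score_eyes,
    score_fluid_balance,
    score_fontanelle,
    score_frame,
    score_liver,
    score_skin,
    score_urine_output,
    score_urine_sg,
    score_weight_change,
    write_results,
)

from .conftest import random_observation


@pytest.mark.parametrize(
    "fn, value, expected",
    [
        # BUN trend: decrease magnitude binned at 15 / 26 / 50
        (score_bun_trend, -10, 0),
        (score_bun_trend, +20, 0),
        (score_bun_trend, -15, 1),
        (score_bun_trend, -25.9, 1),
        (score_bun_trend, -26, 2),
        (score_bun_trend, -40, 2),
        (score_bun_trend, -50, 2),
        (score_bun_trend, -60, 3),
        # urine specific gravity: dilute urine scores higher
        (score_urine_sg, 1.010, 0),
        (score_urine_sg, 1.025, 0),
        (score_urine_sg, 1.007, 1),
        (score_urine_sg, 1.005, 1),
        (score_urine_sg, 1.002, 2),
        (score_urine_sg, 1.000, 2),
        (score_urine_sg, 0.999, 3),
        # fluid balance mL/kg/day at 15 / 30 / 50
        (score_fluid_balance, 10, 0),
        (score_fluid_balance, -20, 0),
        (score_fluid_balance, 15, 1),
        (score_fluid_balance, 45, 2),
        (score_fluid_balance, 50, 2),
        (score_fluid_balance, 50.1, 3),
        # weight change % at 7 / 11 / 15
        (score_weight_change, 3, 0),
        (score_weight_change, -5, 0),
        (score_weight_change, 7, 1),
        (score_weight_change, 12, 2),
        (score_weight_change, 15, 2),
        (score_weight_change, 16, 3),
        # liver cm below costal margin at 1 / 2 / 3
        (score_liver, 0.5, 0),
        (score_liver, 1.0, 1),
        (score_liver, 2.0, 2),
        (score_liver, 3.0, 2),
        (score_liver, 3.5, 3),
    ],
)
def test_numeric_scorer_examples(fn, value, expected):
    assert fn(value) == expected


@pytest.mark.parametrize(
    "value, flag, expected",
    [
        (2.0, False, 0),
        (3.0, False, 0),
        (0.5, False, 0),  # oliguria: outside the normal band but not overload
        (3.2, False, 1),
        (3.5, False, 1),
        (3.7, False, 2),
        (4.0, False, 2),
        (5.0, False, 3),
        (2.0, True, None),  # unmeasurable on diuretics / in renal failure
    ],
)
def test_urine_output(value, flag, expected):
    assert score_urine_output(value, flag) == expected


@pytest.mark.parametrize(
    "fn, value, expected",
    [
        (score_fontanelle, "flat", 0),
        (score_fontanelle, "full", 1),
        (score_fontanelle, "bulging", 2),
        (score_fontanelle, "bulging_tense", 3),
        (score_fontanelle, "closed", None),
        (score_eyes, "normal", 0),
        (score_eyes, "puffy_unable_to_open", 3),
        (score_skin, "no_edema", 0),
        (score_skin, "anasarca", 3),
        (score_cxr, "none", 0),
        (score_cxr, "moderate", 2),
    ],
)
def test_categorical_scorers(fn, value, expected):
    assert fn(value) == expected
    assert fn(None) is None


@pytest.mark.parametrize(
    "call",
    [
        lambda: score_bun_trend(float("nan")),
        lambda: score_bun_trend(float("inf")),
        lambda: score_urine_sg(1.2),  # outside physiologic range
        lambda: score_urine_sg(0.9),
        lambda: score_urine_output(-1.0),
        lambda: score_liver(-0.1),
        lambda: score_fontanelle("sunken"),
        lambda: score_eyes("bloodshot"),
        lambda: EncounterObservation("e1", urine_specific_gravity=2.0),
        lambda: EncounterObservation("e1", liver_cm_below_costal_margin=-1),
        lambda: EncounterObservation("e1", skin="wrinkly"),
    ],
)
def test_validation_errors(call):
    with pytest.raises(ValidationError):
        call()


NUMERIC_SCORERS = [
    (score_bun_trend, st.floats(-100, 100), -1),  # overload direction: more negative
    (score_urine_sg, st.floats(0.990, 1.060), -1),  # more dilute
    (score_fluid_balance, st.floats(-100, 150), +1),
    (score_weight_change, st.floats(-30, 40), +1),
    (lambda v: score_urine_output(v, False), st.floats(0, 10), +1),
    (score_liver, st.floats(0, 10), +1),
]


@pytest.mark.parametrize("fn, strat, direction", NUMERIC_SCORERS)
@settings(max_examples=200, deadline=None)
@given(data=st.data())
def test_monotone_and_total(fn, strat, direction, data):
    """Every valid numeric input maps to exactly one subscore, and moving
    further in the overload direction never decreases it."""
    a = data.draw(strat)
    b = data.draw(strat)
    sa, sb = fn(a), fn(b)
    assert sa in (0, 1, 2, 3) and sb in (0, 1, 2, 3)
    lo, hi = (a, b) if direction * a <= direction * b else (b, a)
    assert fn(lo) <= fn(hi)


def test_totality_dense_grid():
    """Dense grids over each numeric domain: no gaps, no multi-mapping."""
    grids = [
        (score_bun_trend, np.linspace(-120, 120, 4801)),
        (score_urine_sg, np.linspace(0.990, 1.060, 1401)),
        (score_fluid_balance, np.linspace(-50, 120, 3401)),
        (score_weight_change, np.linspace(-20, 40, 1201)),
        (lambda v: score_urine_output(v, False), np.linspace(0, 8, 1601)),
        (score_liver, np.linspace(0, 8, 1601)),
    ]
    for fn, grid in grids:
        vals = {fn(float(v)) for v in grid}
        assert vals <= {0, 1, 2, 3}


def _all_normal():
    return EncounterObservation(
        encounter_id="n",
        bun_trend_pct=0.0,
        urine_specific_gravity=1.020,
        fluid_balance_ml_kg_day=0.0,
        weight_change_pct=0.0,
        urine_output_ml_kg_h=2.0,
        fontanelle="flat",
        eyes="normal",
        liver_cm_below_costal_margin=0.0,
        skin="no_edema",
        cxr_grade="none",
    )


def test_compute_fast_all_normal_is_zero():
    r = compute_fast(_all_normal())
    assert r.total == 0 and r.n_missing == 0 and r.valid


def test_compute_fast_all_severe_is_thirty():
    obs = EncounterObservation(
        encounter_id="s",
        bun_trend_pct=-80.0,
        urine_specific_gravity=0.995,
        fluid_balance_ml_kg_day=80.0,
        weight_change_pct=20.0,
        urine_output_ml_kg_h=6.0,
        fontanelle="bulging_tense",
        eyes="puffy_unable_to_open",
        liver_cm_below_costal_margin=5.0,
        skin="anasarca",
        cxr_grade="severe",
    )
    r = compute_fast(obs)
    assert r.total == 30 and r.valid


def test_compute_fast_missing_policy():
    """Up to two missing variables is tolerated; a third invalidates."""
    obs = _all_normal()
    obs.fontanelle = None
    obs.cxr_grade = None
    r = compute_fast(obs)
    assert r.n_missing == 2 and r.valid and r.total == 0
    obs.urine_specific_gravity = None
    r = compute_fast(obs)
    assert r.n_missing == 3 and not r.valid and r.total == 0


def test_diuretics_flag_makes_urine_output_missing():
    obs = _all_normal()
    obs.on_diuretics_or_renal_failure = True
    r = compute_fast(obs)
    assert r.subscores["urine_output"] is None and r.n_missing == 1


def test_compute_fast_matches_independent_subscores(rng):
    """Total equals the brute-force sum of the ten independent scorers."""
    for _ in range(200):
        obs = random_observation(rng)
        r = compute_fast(obs)
        parts = [
            None if obs.bun_trend_pct is None else score_bun_trend(obs.bun_trend_pct),
            None if obs.urine_specific_gravity is None else score_urine_sg(obs.urine_specific_gravity),
            None if obs.fluid_balance_ml_kg_day is None else score_fluid_balance(obs.fluid_balance_ml_kg_day),
            None if obs.weight_change_pct is None else score_weight_change(obs.weight_change_pct),
            None
            if obs.urine_output_ml_kg_h is None
            else score_urine_output(obs.urine_output_ml_kg_h, obs.on_diuretics_or_renal_failure),
            score_fontanelle(obs.fontanelle),
            score_eyes(obs.eyes),
            None if obs.liver_cm_below_costal_margin is None else score_liver(obs.liver_cm_below_costal_margin),
            score_skin(obs.skin),
            score_cxr(obs.cxr_grade),
        ]
        assert r.total == sum(p for p in parts if p is not None)
        assert r.n_missing == sum(p is None for p in parts)
        assert 0 <= r.total <= 3 * (10 - r.n_missing)
        assert r.valid == (r.n_missing <= 2)


def test_score_frame_equals_rowwise_compute(rng, tmp_path):
    """The vectorized frame scorer agrees with compute_fast row by row,
    and the CSV round trip preserves everything."""
    observations = [random_observation(rng) for _ in range(150)]
    path = tmp_path / "enc.csv"
    rows = []
    for o in observations:
        rows.append({f.name: getattr(o, f.name) for f in o.__dataclass_fields__.values()})
    pd.DataFrame(rows).to_csv(path, index=False)

    back = read_encounters(path)
    assert back == observations

    frame = score_frame(pd.read_csv(path, dtype=str))
    for i, o in enumerate(observations):
        r = compute_fast(o)
        assert int(frame.loc[i, "total"]) == r.total
        assert int(frame.loc[i, "n_missing"]) == r.n_missing
        assert bool(frame.loc[i, "valid"]) == r.valid
        for name in scoring.VARIABLES:
            got = frame.loc[i, name]
            want = r.subscores[name]
            assert (pd.isna(got) and want is None) or int(got) == want

    out = tmp_path / "scored.csv"
    write_results([compute_fast(o) for o in observations], out)
    scored = pd.read_csv(out)
    assert list(scored["total"]) == [compute_fast(o).total for o in observations]


def test_read_encounters_requires_id(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("score,tfc_high\n3,1\n")
    with pytest.raises(ValidationError):
        read_encounters(p)
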