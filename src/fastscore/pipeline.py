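"""End-to-end workflow: score -> ROC table -> cut selection -> CV -> outcomes.

A :class:`RunConfig` binds the input tables, the cut range, the
cross-validation settings and the cut-point policy; :func:`run_pipeline`
executes the whole chain and writes every artifact, logging the seed of
each random operation so runs regenerate byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import outcomes as outcomes_mod
from . import scoring, validation

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "labeled_scores_from_frame"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    scores_csv: str
    out_dir: str = "fast_out"
    outcomes_csv: Optional[str] = None
    cuts: tuple = tuple(range(9))  # candidate cut points 0..8
    cv_folds: int = 10
    cv_repeats: int = 200
    seed: int = 0
    policy: str = "balanced"
    tfc_threshold: Optional[float] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        cuts = tuple(int(c) for c in self.cuts)
        if any(c < 0 for c in cuts) or any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cuts must be non-negative and strictly increasing")
        self.cuts = cuts
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def labeled_scores_from_frame(
    df: pd.DataFrame, tfc_threshold: Optional[float] = None
) -> list:
    """Build LabeledScores from a table of scores (or raw observations).

    Accepts either a ``score`` column or the raw observation columns
    (routed through the scoring module; invalid encounters dropped), and
    either a binary ``tfc_high`` column or ``tfc_value`` plus a threshold.
    """
    if "score" not in df.columns:
        if "encounter_id" not in df.columns:
            raise scoring.ValidationError("input table needs 'encounter_id'")
        scored = scoring.score_frame(df)
        n_invalid = int((~scored["valid"]).sum())
        if n_invalid:
            logger.info("dropping %d encounters with >2 missing variables", n_invalid)
        keep = scored["valid"].to_numpy(bool)
        df = df.loc[keep].assign(score=scored.loc[keep, "total"].to_numpy())
    if "tfc_high" in df.columns:
        labels = df["tfc_high"].astype(int).to_numpy() == 1
    elif "tfc_value" in df.columns:
        if tfc_threshold is None:
            raise scoring.ValidationError(
                "input has tfc_value but no tfc_high: a tfc_threshold is required"
            )
        labels = validation.label_from_tfc(df["tfc_value"].to_numpy(float), tfc_threshold)
    else:
        raise scoring.ValidationError("input table needs 'tfc_high' or 'tfc_value'")
    return [
        validation.LabeledScore(str(e), int(s), bool(l))
        for e, s, l in zip(df["encounter_id"], df["score"], labels)
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow and write artifacts under ``config.out_dir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    df = pd.read_csv(config.scores_csv)
    if df.empty:
        raise scoring.ValidationError(f"{config.scores_csv}: empty input table")
    data = labeled_scores_from_frame(df, config.tfc_threshold)

    table = validation.cutpoint_table(data, cuts=config.cuts)
    table.to_dataframe(percent=True).to_csv(out / "roc_table.csv", index=False)
    table.polygon().to_csv(out / "roc_polygon.csv", index=False)

    chosen = validation.select_cutpoint(table, policy=config.policy)
    logger.info("selected cut %d under policy %s", chosen.cut, config.policy)

    logger.info("cv_auc seed=%d folds=%d repeats=%d", config.seed, config.cv_folds, config.cv_repeats)
    cv = validation.cv_auc(
        data,
        n_folds=config.cv_folds,
        cut=chosen.cut,
        seed=config.seed,
        n_repeats=config.cv_repeats,
    )
    with open(out / "cv_auc.json", "w") as fh:
        json.dump(cv.to_dict(), fh, indent=2)

    summary = {
        "n_encounters": len(data),
        "n_pos": table.n_pos,
        "n_neg": table.n_neg,
        "auc": table.auc,
        "policy": config.policy,
        "selected_cut": chosen.cut,
        "sensitivity": chosen.sensitivity,
        "specificity": chosen.specificity,
        "correctly_classified": chosen.correctly_classified,
        "cv_mean_auc": cv.mean_auc,
        "cv_ci95": list(cv.ci95),
        "seed": config.seed,
    }

    if config.outcomes_csv:
        recs = outcomes_mod.read_outcomes(config.outcomes_csv)
        comps = outcomes_mod.compare_outcomes(data, recs, cut=chosen.cut)
        outcomes_mod.comparison_frame(comps).to_csv(out / "outcome_comparison.csv", index=False)
        summary["outcomes"] = [
            {"outcome": c.outcome_name, "chi2": c.chi2, "p_value": c.p_value} for c in comps
        ]

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
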