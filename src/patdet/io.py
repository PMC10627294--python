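"""File formats and the end-to-end analysis pipeline.

Sessions are stored as a CSV (``trial,sequence,true_label``; sequences
as fixed-length '0'/'1' strings) plus a JSON sidecar carrying the
generator parameters, trial count and master seed.  Responses use a
``trial,response`` CSV.  ``run_pipeline`` ties everything together:
simulate a cohort, featurize, fit all 15 subset models per observer,
compare them by AICc, and compute SDT metrics and efficiencies, writing
every intermediate file plus a JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import feature_models, model_selection, sdt
from .features import feature_matrix
from .generators import (
    DMS,
    RANDOM,
    GeneratorParams,
    Session,
    TrialRecord,
    as_sequence,
    resolve_params,
)
from .ideal_observer import exact_performance
from .observers import heterogeneous_cohort_specs, simulate_cohort

logger = logging.getLogger("patdet")

_SIDECAR_KEYS = ("p_r", "p_d", "n", "n_trials", "seed")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_session(session: Session, csv_path) -> Path:
    """Write a session CSV plus its JSON parameter sidecar."""
    csv_path = Path(csv_path)
    session.to_frame().to_csv(csv_path, index=False)
    sidecar = {
        "p_r": session.params.p_r,
        "p_d": session.params.p_d,
        "n": session.params.n,
        "n_trials": session.n_trials,
        "seed": session.seed,
        "condition": session.condition,
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=2) + "\n")
    return csv_path


def read_session(csv_path) -> Session:
    """Read and validate a session CSV + sidecar back into a Session."""
    csv_path = Path(csv_path)
    side_path = _sidecar_path(csv_path)
    if not side_path.exists():
        raise FileNotFoundError(f"missing sidecar JSON {side_path}")
    sidecar = json.loads(side_path.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar {side_path} lacks key(s) {missing}")
    params = GeneratorParams(p_r=sidecar["p_r"], p_d=sidecar["p_d"], n=sidecar["n"])
    df = pd.read_csv(csv_path, dtype={"sequence": str})
    expected_cols = {"trial", "sequence", "true_label"}
    if set(df.columns) != expected_cols:
        raise ValueError(
            f"{csv_path}: expected columns {sorted(expected_cols)}, got {list(df.columns)}"
        )
    if len(df) != sidecar["n_trials"]:
        raise ValueError(
            f"{csv_path}: sidecar says {sidecar['n_trials']} trials, file has {len(df)}"
        )
    trials = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        seq_str = row.sequence
        if len(seq_str) != params.n:
            raise ValueError(
                f"{csv_path} line {row_no}: sequence has {len(seq_str)} tokens, "
                f"expected {params.n}"
            )
        if row.true_label not in (RANDOM, DMS):
            raise ValueError(
                f"{csv_path} line {row_no}: true_label must be RANDOM or DMS, "
                f"got {row.true_label!r}"
            )
        try:
            seq = as_sequence(seq_str)
        except ValueError as exc:
            raise ValueError(f"{csv_path} line {row_no}: {exc}") from None
        trials.append(
            TrialRecord(index=int(row.trial), sequence=seq, true_label=row.true_label)
        )
    return Session(
        params=params,
        seed=sidecar["seed"],
        trials=trials,
        condition=sidecar.get("condition"),
    )


def write_responses(responses: pd.DataFrame, path) -> Path:
    path = Path(path)
    responses.to_csv(path, index=False)
    return path


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    if not {"trial", "response"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns trial,response")
    bad = set(df["response"]) - {RANDOM, DMS}
    if bad:
        raise ValueError(f"{path}: invalid response value(s) {sorted(bad)}")
    return df


@dataclass
class RunConfig:
    """Configuration of a full simulate-fit-compare pipeline run."""

    condition: str = "LD"
    params: GeneratorParams | None = None
    n_observers: int = 5
    n_trials: int = 100
    seed: int = 0
    mc_reps: int = 5000
    criterion: float = 10.0
    out_dir: Path | str = "pipeline_out"
    lapse_range: tuple[float, float] = (0.0, 0.15)
    strength_range: tuple[float, float] = (0.3, 2.5)

    def resolve(self) -> GeneratorParams:
        return resolve_params(self.condition, self.params)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on a synthetic cohort and write all outputs.

    Stages: simulate cohort -> featurize -> fit 15 GLMs per observer ->
    AICc comparison -> SDT metrics and efficiency.  Everything is
    reproducible from ``config.seed``; the JSON report is written with
    sorted keys so identical configs give byte-identical reports.
    """
    params = config.resolve()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline start: condition=%s p_r=%.3g p_d=%.3g n=%d observers=%d "
        "trials=%d seed=%d",
        config.condition, params.p_r, params.p_d, params.n,
        config.n_observers, config.n_trials, config.seed,
    )

    spec_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    specs = heterogeneous_cohort_specs(
        config.n_observers,
        params,
        spec_rng,
        strength_range=config.strength_range,
        lapse_range=config.lapse_range,
    )
    cohort = simulate_cohort(
        specs, params=params, n_trials=config.n_trials, seed=config.seed
    )

    logger.info("stage exact-model: full-model enumeration at n=%d", params.n)
    full = exact_performance(params)
    feature_dprimes = {}
    for fid in (1, 2, 3, 4):
        clf = feature_models.single_feature_classifier(
            feature_models.exact_feature_distribution(fid, params)
        )
        feature_dprimes[f"F{fid}"] = clf.exact_performance().d_prime

    observers_report = {}
    tables = []
    for i, (spec, (session, responses)) in enumerate(zip(specs, cohort)):
        obs_id = spec.label or f"obs{i + 1:02d}"
        write_session(session, out_dir / f"{obs_id}_session.csv")
        write_responses(responses, out_dir / f"{obs_id}_responses.csv")
        X = feature_matrix(session.sequences())
        X.to_csv(out_dir / f"{obs_id}_features.csv", index=False)
        y = (responses["response"] == DMS).to_numpy()

        logger.info("stage fit: observer %s, 15 subset models", obs_id)
        fits = feature_models.fit_all_subsets(X, y)
        table, summary = model_selection.multimodel_table(
            fits, criterion=config.criterion
        )
        table.to_csv(out_dir / f"{obs_id}_models.csv", index=False)
        tables.append(table)
        dom = feature_models.dominant_feature(fits["1234"])

        labels = session.labels()
        is_dms = labels == DMS
        resp_dms = y
        est = sdt.sdt_from_counts(
            hits=int((resp_dms & is_dms).sum()),
            misses=int((~resp_dms & is_dms).sum()),
            fas=int((resp_dms & ~is_dms).sum()),
            crs=int((~resp_dms & ~is_dms).sum()),
        )
        try:
            eff_value = sdt.efficiency(est.d_prime, params).efficiency
        except ValueError:  # full-model d' <= 0 (e.g. p_d = 0.5): undefined
            eff_value = None
        observers_report[obs_id] = {
            "d_prime": est.d_prime,
            "criterion_c": est.criterion_c,
            "hit_rate": est.hit_rate,
            "fa_rate": est.fa_rate,
            "corrected": est.corrected,
            "efficiency": eff_value,
            "dominant_feature": f"F{dom.feature_id}",
            "dominance_reliable": dom.reliable,
            "best_model": summary["best"],
            "supported_models": table.loc[table["supported"], "model"].tolist(),
            "n_models": int(len(table)),
            "generative": {
                "beta0": spec.beta0,
                "betas": list(spec.betas),
                "lapse": spec.lapse,
            },
        }

    avg = model_selection.average_aicc_table(tables)
    avg.to_csv(out_dir / "aicc_averaged.csv", index=False)

    report = {
        "config": {
            "condition": config.condition,
            "p_r": params.p_r,
            "p_d": params.p_d,
            "n": params.n,
            "n_observers": config.n_observers,
            "n_trials": config.n_trials,
            "seed": config.seed,
            "criterion": config.criterion,
        },
        "full_model": {
            "d_prime": full.d_prime,
            "hit_rate": full.hit_rate,
            "fa_rate": full.fa_rate,
        },
        "single_feature_d_primes": feature_dprimes,
        "observers": observers_report,
        "aicc_averaged": {
            row.model: row.aicc for row in avg.itertuples(index=False)
        },
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline done: report at %s", out_dir / "report.json")
    return report
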