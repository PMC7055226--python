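"""Readers/writers, configuration, and the simulate-score-fit-report pipeline.

All tabular data travels as RFC-4180 CSV with mandatory headers
(dialect defined in :mod:`cgtcal.task`); configuration is YAML or
JSON. Ingest re-validates every engine invariant — the zero floor,
turn-to-turn balance conservation, block/turn counts, estimate
categories — and rejects corrupt files with the offending row number.
External files with different column names are adapted through a
user-supplied header mapping rather than guessed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import (
    CorruptDataError,
    IncompleteSessionError,
    InvalidCategoryError,
    InvalidConfigError,
)
from .inference import (
    MCMCConfig,
    MODEL_SPECS,
    PriorSpec,
    default_linear_mcmc,
    default_probit_mcmc,
    fit_lmm,
    fit_probit_glmm,
    render_summary,
    summarize,
)
from .scoring import build_model_tables, write_model_tables
from .synthetic import CohortConfig, simulate_cohort
from .task import (
    CATEGORIES,
    COVARIATE_COLUMNS,
    DECKS,
    ESTIMATE_COLUMNS,
    TURN_COLUMNS,
    BlockSummary,
    Cohort,
    EstimateRecord,
    GameConfig,
    ParticipantSession,
    TurnRecord,
    write_covariates_csv,
    write_estimates_csv,
    write_turns_csv,
)

logger = logging.getLogger("cgtcal")

#: Default ROPE half-widths per outcome (the practical-equivalence
#: bands used in reporting): 0.01 on the safe-card fraction, 0.5
#: stickers on payoffs, 0.1 probit units on overconfidence and the
#: miscalibration robustness model.
DEFAULT_ROPE_HALF_WIDTHS = {
    "relative_safe": 0.01,
    "payoffs": 0.5,
    "overconfidence": 0.1,
    "miscalibration": 0.1,
}


def _read_csv(path, required, header_map=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if header_map:
        df = df.rename(columns=header_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CorruptDataError(f"{path}: missing columns {missing}")
    return df


def read_sessions(
    turns_csv,
    estimates_csv,
    covariates_csv,
    game: GameConfig | None = None,
    header_maps: dict | None = None,
) -> Cohort:
    """Load and validate a cohort from the three-file CSV dialect.

    ``header_maps`` optionally holds ``{"turns": {...}, "estimates":
    {...}, "covariates": {...}}`` external-to-internal column renames.
    Every engine invariant is re-checked on ingest; violations raise
    :class:`CorruptDataError` naming the first offending row (1-based
    data row in the turns file).
    """
    if game is None:
        game = GameConfig()
    maps = header_maps or {}
    turns = _read_csv(turns_csv, TURN_COLUMNS, maps.get("turns"))
    estimates = _read_csv(estimates_csv, ESTIMATE_COLUMNS, maps.get("estimates"))
    covariates = _read_csv(covariates_csv, COVARIATE_COLUMNS, maps.get("covariates"))

    est_by_pid = dict(tuple(estimates.groupby("participant_id", sort=False)))
    sessions = []
    turn_groups = dict(tuple(turns.groupby("participant_id", sort=False)))
    for _, cov in covariates.iterrows():
        pid = cov["participant_id"]
        if pid not in turn_groups:
            raise IncompleteSessionError(f"participant {pid}: no turn data")
        g = turn_groups[pid].sort_values("turn")
        if len(g) != game.n_turns:
            raise CorruptDataError(
                f"participant {pid}: expected {game.n_turns} turns, found {len(g)}"
            )
        balance = int(cov["start_balance"])
        turn_records = []
        for idx, row in g.iterrows():
            rownum = int(idx) + 1
            deck = row["deck"]
            if deck not in DECKS:
                raise CorruptDataError(f"participant {pid}: bad deck {deck!r}", rownum)
            after = int(row["balance_after"])
            realized = int(row["realized_delta"])
            raw = int(row["raw_value"])
            if after < 0:
                raise CorruptDataError(
                    f"participant {pid}: negative balance {after}", rownum
                )
            if after != balance + realized:
                raise CorruptDataError(
                    f"participant {pid}: balance not conserved at turn {row['turn']}",
                    rownum,
                )
            if after != max(0, balance + raw):
                raise CorruptDataError(
                    f"participant {pid}: floor rule violated at turn {row['turn']}",
                    rownum,
                )
            balance = after
            turn_records.append(
                TurnRecord(
                    turn_index=int(row["turn"]),
                    block_index=int(row["block"]),
                    deck=deck,
                    raw_value=raw,
                    realized_delta=realized,
                    balance_after=after,
                )
            )
        blocks = []
        for b in range(1, game.n_blocks + 1):
            in_block = [t for t in turn_records if t.block_index == b]
            if len(in_block) != game.turns_per_block:
                raise CorruptDataError(
                    f"participant {pid}: block {b} has {len(in_block)} turns"
                )
            n_safe = sum(t.deck == "SAFE" for t in in_block)
            blocks.append(
                BlockSummary(
                    block_index=b,
                    n_safe=n_safe,
                    relative_safe=n_safe / game.turns_per_block,
                    block_payoff=sum(t.realized_delta for t in in_block),
                    balance_end=in_block[-1].balance_after,
                )
            )
        est_records = []
        pid_est = est_by_pid.get(pid)
        n_occ = len(game.estimate_occasions)
        if pid_est is None or len(pid_est) != n_occ:
            found = 0 if pid_est is None else len(pid_est)
            raise IncompleteSessionError(
                f"participant {pid}: expected {n_occ} estimates, found {found}"
            )
        for _, e in pid_est.sort_values("occasion").iterrows():
            cat = e["category"]
            if cat not in CATEGORIES:
                raise InvalidCategoryError(
                    f"participant {pid}: unknown category {cat!r}"
                )
            occ = int(e["occasion"])
            if not 1 <= occ <= n_occ:
                raise IncompleteSessionError(
                    f"participant {pid}: occasion {occ} out of range"
                )
            ref = game.estimate_occasions[occ - 1]
            est_records.append(
                EstimateRecord(
                    occasion=occ, category=cat, reference_block=ref,
                    target_block=ref + 1,
                )
            )
        if sorted(e.occasion for e in est_records) != list(range(1, n_occ + 1)):
            raise IncompleteSessionError(f"participant {pid}: duplicate/missing occasion")
        sessions.append(
            ParticipantSession(
                participant_id=pid,
                arm=int(cov["arm"]),
                female=int(cov["female"]),
                age_months=int(cov["age_months"]),
                age_group=int(cov["age_group"]),
                start_balance=int(cov["start_balance"]),
                turns=turn_records,
                blocks=blocks,
                estimates=est_records,
            )
        )
    return Cohort(sessions)


def write_cohort(cohort: Cohort, directory) -> dict[str, str]:
    """Write a cohort to ``directory`` in the three-file dialect."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "turns": os.path.join(directory, "turns.csv"),
        "estimates": os.path.join(directory, "estimates.csv"),
        "covariates": os.path.join(directory, "covariates.csv"),
    }
    write_turns_csv(cohort, paths["turns"])
    write_estimates_csv(cohort, paths["estimates"])
    write_covariates_csv(cohort, paths["covariates"])
    return paths


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from YAML/JSON."""

    out_dir: str = "cgtcal_out"
    seed: int = 0
    models: tuple[str, ...] = ("relative_safe", "payoffs", "overconfidence")
    cohort: CohortConfig = field(default_factory=CohortConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: dict[str, MCMCConfig] = field(default_factory=dict)
    rope_half_widths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROPE_HALF_WIDTHS)
    )
    input_paths: dict[str, str] | None = None  # ingest instead of simulate
    header_maps: dict | None = None
    export_draws: bool = False

    def __post_init__(self):
        for m in self.models:
            if m not in MODEL_SPECS:
                raise InvalidConfigError(f"unknown model outcome {m!r}")
            if self.rope_half_widths.get(m, 0.1) <= 0:
                raise InvalidConfigError("ROPE half-widths must be positive")

    def mcmc_for(self, outcome: str) -> MCMCConfig:
        if outcome in self.mcmc:
            return self.mcmc[outcome]
        if MODEL_SPECS[outcome]().link == "probit":
            return default_probit_mcmc(seed=1234 + self.seed)
        return default_linear_mcmc(seed=12345 + self.seed)


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML or JSON file."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    raw = raw or {}
    kwargs = {}
    for key in ("out_dir", "seed", "input_paths", "header_maps", "export_draws"):
        if key in raw:
            kwargs[key] = raw[key]
    if "models" in raw:
        kwargs["models"] = tuple(raw["models"])
    if "cohort" in raw:
        cc = dict(raw["cohort"])
        if "agent_params" in cc:
            from .synthetic import AgentParams

            cc["agent_params"] = AgentParams(**cc["agent_params"])
        if "game" in cc:
            cc["game"] = GameConfig(**cc["game"])
        kwargs["cohort"] = CohortConfig(**cc)
    if "priors" in raw:
        kwargs["priors"] = PriorSpec(**raw["priors"])
    if "mcmc" in raw:
        kwargs["mcmc"] = {k: MCMCConfig(**v) for k, v in raw["mcmc"].items()}
    if "rope_half_widths" in raw:
        rhw = dict(DEFAULT_ROPE_HALF_WIDTHS)
        rhw.update(raw["rope_half_widths"])
        kwargs["rope_half_widths"] = rhw
    return PipelineConfig(**kwargs)


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute simulate/ingest -> score -> fit -> report.

    Returns a bundle dict with the cohort, model tables, posterior
    draws, summaries, and output paths. ``dry_run`` echoes the
    configuration and writes nothing.
    """
    if dry_run:
        logger.info("dry run: %s", config)
        return {"config": config, "dry_run": True}

    os.makedirs(config.out_dir, exist_ok=True)
    log = {"seed": config.seed, "models": list(config.models)}

    try:
        if config.input_paths:
            cohort = read_sessions(
                config.input_paths["turns"],
                config.input_paths["estimates"],
                config.input_paths["covariates"],
                game=config.cohort.game,
                header_maps=config.header_maps,
            )
            truth = None
            logger.info("ingested %d sessions", len(cohort))
        else:
            cohort, truth = simulate_cohort(config.cohort)
            write_cohort(cohort, os.path.join(config.out_dir, "cohort"))
            truth.to_json(os.path.join(config.out_dir, "cohort", "ground_truth.json"))
            logger.info("simulated %d sessions (seed %d)", len(cohort), config.cohort.seed)
    except Exception as exc:  # stage-tagged abort
        raise type(exc)(f"[stage: data] {exc}") from exc

    try:
        tables = build_model_tables(cohort)
        write_model_tables(tables, config.out_dir)
    except Exception as exc:
        raise type(exc)(f"[stage: score] {exc}") from exc

    summaries, draws_by_model = {}, {}
    report_chunks = []
    for outcome in config.models:
        try:
            spec = MODEL_SPECS[outcome]()
            table = tables["overconfidence"] if outcome in (
                "overconfidence", "miscalibration") else tables[outcome]
            mcmc = config.mcmc_for(outcome)
            if spec.link == "probit":
                draws = fit_probit_glmm(table, spec, config.priors, mcmc)
            else:
                draws = fit_lmm(table, spec, config.priors, mcmc)
            summary = summarize(
                draws,
                rope_half_width=config.rope_half_widths.get(outcome, 0.1),
                as_percent=False,
            )
            summaries[outcome] = summary
            draws_by_model[outcome] = draws
            summary.to_csv(
                os.path.join(config.out_dir, f"summary_{outcome}.csv"), index=False
            )
            if config.export_draws:
                draws.to_dataframe().to_csv(
                    os.path.join(config.out_dir, f"draws_{outcome}.csv"), index=False
                )
            report_chunks.append(render_summary(summary, title=f"Model: {outcome}"))
            log[f"mcmc_{outcome}"] = {
                "n_chains": mcmc.n_chains, "burn_in": mcmc.burn_in,
                "n_iterations": mcmc.n_iterations, "thinning": mcmc.thinning,
                "seed": mcmc.seed,
            }
            logger.info("fitted %s (%d chains x %d kept draws)",
                        outcome, mcmc.n_chains, mcmc.kept_per_chain)
        except Exception as exc:
            raise type(exc)(f"[stage: fit:{outcome}] {exc}") from exc

    report_path = os.path.join(config.out_dir, "report.txt")
    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write("\n\n".join(report_chunks) + "\n")
    with open(os.path.join(config.out_dir, "run_log.json"), "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2)
    return {
        "cohort": cohort,
        "tables": tables,
        "draws": draws_by_model,
        "summaries": summaries,
        "report_path": report_path,
        "config": config,
    }
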