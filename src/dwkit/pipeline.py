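"""End-to-end pipeline: configuration, file I/O, seeding, and the full run.

The pipeline executes, in order: quality-control filtering, the
paired-comparison probit fit, the PHE interval regression, the
anchoring regression, Monte Carlo means, the respondent bootstrap, and
the descriptive reports.  Every stochastic stage derives an independent
random stream from the run seed combined with a CRC-32 hash of the
stage name, so stage results do not depend on the order or number of
draws taken elsewhere; (data, config, seed) fully determine every
output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import anchoring, interval, probit, reporting
from .catalog import CatalogError, load_catalog, load_reference_dws
from .survey import (
    PC_COLUMNS,
    PHE_COLUMNS,
    SurveyConfig,
    SurveyError,
    qc_filter,
)

log = logging.getLogger("dwkit")

__all__ = ["RunConfig", "run_pipeline", "stage_seed",
           "read_respondents", "read_pc_responses", "read_phe_responses"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC-32 of the stage name mixed with
    the run seed (kept below 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of a full estimation run.

    Defaults follow the modeled survey design: 16 PC questions, 3 PHE
    questions, a 180 s web minimum completion time, and 1000 bootstrap
    replicates / Monte Carlo draws.
    """

    seed: int = 0
    catalog: str | None = None          # None -> packaged catalog
    respondents: str = "respondents.csv"
    pc_responses: str = "pc_responses.csv"
    phe_responses: str = "phe_responses.csv"
    reference: str | None = None
    out_dir: str = "results"
    # estimation options.  The pipeline defaults form the coherent
    # generative-estimation chain: log-scale interval regression (the
    # PHE choice noise is multiplicative) and the raw latent index as
    # the anchoring regressor (so final DWs are invariant to the probit
    # location constraint and the bootstrap intervals are calibrated).
    # The literal-reading alternatives ("logit" interval scale,
    # "probability" regressor) remain available as options.
    penalty: float = 1e-6
    interval_scale: str = "log"
    regressor: str = "index"
    dependent_scale: str = "logit"
    constraint: str = "sum_zero"
    n_bootstrap: int = 1000
    n_mc: int = 1000
    # survey design / QC
    n_pc_questions: int = 16
    repeated_positions: tuple[int, ...] = (3, 10, 16)
    n_phe_questions: int = 3
    min_completion_seconds: float = 180.0

    def survey_config(self) -> SurveyConfig:
        return SurveyConfig(
            n_pc_questions=self.n_pc_questions,
            repeated_positions=tuple(self.repeated_positions),
            n_phe_questions=self.n_phe_questions,
            min_completion_seconds=self.min_completion_seconds,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SurveyError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["repeated_positions"] = list(self.repeated_positions)
        return d


def _require_columns(frame: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SurveyError(f"{what} file missing column(s): {missing}")


def read_respondents(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    _require_columns(frame, ("respondent_id", "mode", "completion_seconds"), "respondents")
    bad = set(frame["mode"]) - {"household", "web"}
    if bad:
        raise SurveyError(f"invalid respondent mode(s): {sorted(bad)}")
    if (frame["completion_seconds"] < 0).any():
        raise SurveyError("negative completion_seconds")
    return frame


def read_pc_responses(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    _require_columns(frame, PC_COLUMNS, "pc_responses")
    bad = set(frame["choice"]) - {"first", "second"}
    if bad:
        raise SurveyError(f"invalid PC choice value(s): {sorted(bad)}")
    return frame


def read_phe_responses(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    _require_columns(frame, PHE_COLUMNS, "phe_responses")
    bad = set(frame["choice"]) - {"fatal_program", "nonfatal_program"}
    if bad:
        raise SurveyError(f"invalid PHE choice value(s): {sorted(bad)}")
    return frame


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _round3(frame: pd.DataFrame, columns) -> pd.DataFrame:
    out = frame.copy()
    for c in columns:
        out[c] = out[c].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
    return out


def estimate_dws(
    pc_responses: pd.DataFrame,
    phe_responses: pd.DataFrame,
    respondents: pd.DataFrame,
    catalog,
    config: RunConfig,
) -> dict:
    """Probit -> interval -> anchor -> MC mean -> bootstrap, on clean data.

    Returns a dict with the fitted objects, the point/mean DW maps, the
    bootstrap UIs and the assembled results table.
    """
    design = probit.build_design(pc_responses, catalog)
    log.info(
        "fit-pc: %d responses, %d states, %d dropped",
        design.n_responses, design.n_states, design.n_dropped,
    )
    pfit = probit.fit_probit(
        design, penalty=config.penalty, constraint=config.constraint
    )
    log.info("fit-pc: converged in %d iterations, loglik %.2f", pfit.n_iter, pfit.loglik)

    ifit = interval.fit_interval_regression(
        phe_responses, catalog, scale=config.interval_scale
    )
    phe_dws = interval.phe_dw_estimates(ifit)
    log.info(
        "fit-phe: %d observations, %d anchor states, sigma %.3f",
        ifit.n_observations, len(phe_dws), ifit.sigma,
    )

    # anchor states pinned at the DW boundary carry no PHE information
    usable_anchors = [s for s in phe_dws if s not in ifit.boundary_states]
    anchor = anchoring.fit_anchor(
        phe_dws,
        pfit,
        anchor_states=usable_anchors,
        dependent_scale=config.dependent_scale,
        regressor=config.regressor,
    )
    log.info(
        "anchor: a=%.4f b=%.4f R2=%.3f over %d anchors",
        anchor.intercept, anchor.slope, anchor.r_squared, anchor.n_anchors,
    )
    point = anchoring.predict_dws(anchor, pfit, catalog)
    dw_mean = anchoring.monte_carlo_mean(
        anchor, pfit, n_draws=config.n_mc, seed=stage_seed(config.seed, "monte_carlo")
    )
    ui, boot_report = anchoring.bootstrap_ui(
        pc_responses,
        phe_responses,
        respondents,
        n_reps=config.n_bootstrap,
        seed=stage_seed(config.seed, "bootstrap"),
        penalty=config.penalty,
        scale=config.interval_scale,
        regressor=config.regressor,
        dependent_scale=config.dependent_scale,
        constraint=config.constraint,
    )
    log.info(
        "bootstrap: %d replicates, %d failed, %d unreliable states",
        boot_report["n_reps"], boot_report["n_failed"],
        len(boot_report["unreliable_states"]),
    )
    results = anchoring.assemble_estimates(
        dw_mean, ui, catalog, n_bootstrap=config.n_bootstrap
    )
    return {
        "design": design,
        "probit_fit": pfit,
        "interval_fit": ifit,
        "phe_dws": phe_dws,
        "anchor": anchor,
        "dw_point": point,
        "dw_mean": dw_mean,
        "ui": ui,
        "bootstrap_report": boot_report,
        "results": results,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline from files and write the results bundle.

    Writes ``results.csv`` (DW means and 95% UIs, rounded to 3
    decimals), ``bins.csv``, ``exclusions.csv`` and ``manifest.json``
    into ``config.out_dir``; when a reference table is configured, also
    ``comparison.csv`` and ``symptom_regression.csv``.  Identical inputs
    and config produce byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    if config.catalog is None:
        from .catalog import packaged_catalog

        catalog = packaged_catalog()
    else:
        catalog = load_catalog(config.catalog)
        inputs["catalog"] = _sha256(config.catalog)
    if not catalog:
        raise CatalogError("empty catalog: estimation refuses to run")

    respondents = read_respondents(config.respondents)
    pc = read_pc_responses(config.pc_responses)
    phe = read_phe_responses(config.phe_responses)
    for key, path in (
        ("respondents", config.respondents),
        ("pc_responses", config.pc_responses),
        ("phe_responses", config.phe_responses),
    ):
        inputs[key] = _sha256(path)

    survey_cfg = config.survey_config()
    retained, exclusions = qc_filter(respondents, pc, survey_cfg)
    log.info(
        "qc: %d respondents in, %d retained, %d excluded",
        len(respondents), len(retained), len(exclusions),
    )
    kept = set(retained["respondent_id"])
    pc = pc[pc["respondent_id"].isin(kept)].reset_index(drop=True)
    phe = phe[phe["respondent_id"].isin(kept)].reset_index(drop=True)

    bundle = estimate_dws(pc, phe, retained, catalog, config)
    results = bundle["results"]

    bins = reporting.bin_distribution(
        results["dw_mean"], denominator=len(catalog)
    )

    exclusions.to_csv(out_dir / "exclusions.csv", index=False)
    _round3(results, ("dw_mean", "ui_low", "ui_high")).to_csv(
        out_dir / "results.csv", index=False
    )
    bins.assign(pct=bins["pct"].round(1)).to_csv(out_dir / "bins.csv", index=False)

    comparison = None
    if config.reference is not None:
        reference = load_reference_dws(config.reference, catalog)
        inputs["reference"] = _sha256(config.reference)
        local = dict(zip(results["state_id"], results["dw_mean"]))
        comparison = reporting.build_comparison(local, reference, catalog)
        comparison.to_csv(out_dir / "comparison.csv", index=False)
        try:
            reg = reporting.symptom_regression(comparison)
        except reporting.ReportingError as exc:
            log.warning("symptom regression skipped: %s", exc)
            bundle["symptom_regression"] = None
        else:
            reg.round(6).to_csv(out_dir / "symptom_regression.csv", index=False)
            bundle["symptom_regression"] = reg
        r, p = reporting.pearson_correlation(local, reference)
        bundle["pearson"] = (r, p)
        log.info("compare: %d states, Pearson r=%.3f", len(comparison), r)

    from importlib.metadata import version

    try:
        pkg_version = version("dwkit")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "config": config.to_dict(),
        "inputs_sha256": inputs,
        "n_respondents_retained": len(retained),
        "n_exclusions": len(exclusions),
        "version": pkg_version,
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
        f.write("\n")

    bundle.update(
        {
            "retained": retained,
            "exclusions": exclusions,
            "bins": bins,
            "comparison": comparison,
            "manifest": manifest,
        }
    )
    return bundle
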