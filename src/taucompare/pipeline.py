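"""End-to-end orchestration: generate -> censor -> missingness -> impute ->
{correlate, concordance, ridge-compare, tree-vim}, seeded throughout.

A single :class:`RunConfig` drives the whole pipeline; :func:`run_full`
executes the stages in order, writes CSV/JSON artifacts and returns a
:class:`RunReport` with per-stage parameters, outputs, wall-clock and
warnings plus the verdict matrix (outcome x pairing x stratum -> decision).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from . import status as st
from .impute import ImputationConfig, ImputedSet, impute
from .ridge import make_specs, bootstrap_models, apply_criteria
from .trees import vim_across_imputations

logger = logging.getLogger(__name__)

STRATA = ("all", "cu", "impaired", "abeta_pos", "abeta_neg")

DEFAULT_OUTCOMES = [
    "age", "apoe4", "csf_ab4240", "amyloid_pet",
    "mmse", "mem_z", "lang_z", "exec_z", "visuo_z",
    "hippo_tiv", "ad_sig_thickness",
]

#: AD features used as tree predictors (amyloid PET is excluded: its
#: structurally missing cells are never imputed)
DEFAULT_VIM_PREDICTORS = [
    "age", "education", "apoe4", "csf_ab4240", "mmse",
    "mem_z", "lang_z", "exec_z", "visuo_z", "hippo_tiv", "ad_sig_thickness",
]

CORRELATION_VARIABLES = coh.FLUID_MARKERS + coh.PET_MARKERS + [
    "age", "csf_ab4240", "amyloid_pet", "mmse", "mem_z", "hippo_tiv", "ad_sig_thickness",
]


@dataclass
class RunConfig:
    generator: coh.GeneratorConfig = field(default_factory=coh.GeneratorConfig)
    imputation: ImputationConfig = field(default_factory=lambda: ImputationConfig(m=5))
    outcomes: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOMES))
    #: (fluid marker, PET marker) pairings for the ridge comparison
    pairings: list[tuple[str, str]] = field(
        default_factory=lambda: [("csf_ptau181", "taupet_meta")])
    strata: list[str] = field(default_factory=lambda: ["all"])
    vim_outcomes: list[str] = field(default_factory=lambda: ["csf_ptau181", "taupet_meta"])
    vim_strata: list[str] = field(default_factory=lambda: ["cu", "impaired"])
    vim_predictors: list[str] = field(default_factory=lambda: list(DEFAULT_VIM_PREDICTORS))
    bootstrap_B: int = 200
    tree_B: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [s for s in list(self.strata) + list(self.vim_strata) if s not in STRATA]
        if bad:
            raise ValueError(f"unknown strata {bad}; expected subset of {STRATA}")
        schema = set(coh.IMPUTABLE_COLUMNS + coh.PROTECTED_COLUMNS + coh.STRUCTURAL_COLUMNS)
        referenced = (set(self.outcomes) | set(self.vim_outcomes)
                      | set(self.vim_predictors) | {m for p in self.pairings for m in p})
        missing = referenced - schema
        if missing:
            raise ValueError(f"columns not in the cohort schema: {sorted(missing)}")
        # seeds propagate from the global seed to every stage
        self.generator = dataclasses.replace(self.generator, seed=self.seed)
        self.imputation = dataclasses.replace(self.imputation, seed=self.seed + 1)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = coh.GeneratorConfig(**d["generator"])
        if "imputation" in d:
            d["imputation"] = ImputationConfig(**d["imputation"])
        if "pairings" in d:
            d["pairings"] = [tuple(p) for p in d["pairings"]]
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass
class StageRecord:
    name: str
    wall_clock_s: float
    params: dict
    inputs_digest: str
    outputs: list[str]
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    config: dict
    stages: list[StageRecord]
    verdict_matrix: dict  # outcome -> pairing -> stratum -> decision
    vim_rankings: dict    # outcome -> stratum -> ordered predictor list

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config,
            "stages": [asdict(s) for s in self.stages],
            "verdict_matrix": self.verdict_matrix,
            "vim_rankings": self.vim_rankings,
        }, indent=2, default=str)

    def digest(self) -> str:
        """Content digest; wall-clock timings are excluded so identical
        (config, seed) runs produce identical digests."""
        d = json.loads(self.to_json())
        for s in d["stages"]:
            s.pop("wall_clock_s", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stratum_mask(table: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(table), dtype=bool)
    if stratum == "cu":
        return (table["group"] == coh.CU).to_numpy()
    if stratum == "impaired":
        return (table["group"] == coh.IMPAIRED).to_numpy()
    if stratum == "abeta_pos":
        return (table["abeta_status"] == "POS").to_numpy()
    if stratum == "abeta_neg":
        return (table["abeta_status"] == "NEG").to_numpy()
    raise ValueError(f"unknown stratum {stratum!r}")


def _subset_imputed(imputed: ImputedSet, mask: np.ndarray) -> ImputedSet:
    return ImputedSet(
        tables=[t[mask].reset_index(drop=True) for t in imputed.tables],
        missing_mask=imputed.missing_mask[mask].reset_index(drop=True),
        config=imputed.config,
    )


def derive_reference_cutoffs(table: pd.DataFrame, markers: list[str]) -> dict[str, st.Cutoff]:
    """Mean + 2 SD cut-offs from the amyloid-negative cognitively unimpaired subgroup."""
    ref = table[(table["group"] == coh.CU) & (table["abeta_status"] == "NEG")]
    return {m: st.derive_cutoff(ref[m].dropna(), marker=m) for m in markers}


def run_full(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute the full pipeline; artifacts land under ``outdir``.

    Any stage failure aborts with the stage name; the partial report written
    so far is saved as ``report_partial.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[StageRecord] = []
    verdicts: dict = {}
    vim_rankings: dict = {}
    report = RunReport(config=json.loads(config.to_json()), stages=stages,
                       verdict_matrix=verdicts, vim_rankings=vim_rankings)

    def record(name: str, t0: float, params: dict, digest: str,
               outputs: list[Path], warnings: list[str] | None = None) -> None:
        # outputs recorded relative to outdir so digests compare across runs
        stages.append(StageRecord(
            name=name, wall_clock_s=round(time.perf_counter() - t0, 3), params=params,
            inputs_digest=digest, outputs=[str(Path(p).name) for p in outputs],
            warnings=warnings or []))
        logger.info("stage %s finished in %.2fs (%d warnings)", name,
                    stages[-1].wall_clock_s, len(stages[-1].warnings))

    current = "generate"
    try:
        # --- generate + censor + missingness ---------------------------------
        t0 = time.perf_counter()
        table, truth = coh.generate_cohort(config.generator)
        table = coh.censor_plasma(table, config.generator)
        censored_n = table.attrs.get("plasma_censored_n", 0)
        table = coh.apply_missingness(table, config.generator)
        cohort_path = outdir / "cohort.csv"
        truth_path = outdir / "ground_truth.json"
        coh.write_cohort_csv(table, cohort_path)
        truth_path.write_text(truth.to_json())
        record("generate", t0, {"generator": json.loads(json.dumps(
            asdict(config.generator), default=str))}, "",
            [cohort_path, truth_path],
            [f"plasma values censored at detection limit: {censored_n}"])

        # --- cut-offs, quadrants, concordance --------------------------------
        current = "concordance"
        t0 = time.perf_counter()
        markers = sorted({m for p in config.pairings for m in p})
        cutoffs = derive_reference_cutoffs(table, markers)
        cutoffs_path = outdir / "cutoffs.json"
        cutoffs_path.write_text(json.dumps(
            {m: dataclasses.asdict(c) for m, c in cutoffs.items()}, indent=2))
        conc_rows = []
        quadrants = {}
        for fluid, pet in config.pairings:
            calls_f = st.binarize(table[fluid], cutoffs[fluid])
            calls_p = st.binarize(table[pet], cutoffs[pet])
            q = st.quadrant_table(calls_p, calls_f, marker_a=pet, marker_b=fluid)
            quadrants[f"{pet}_vs_{fluid}"] = dataclasses.asdict(q)
            conc_rows.append({"pet": pet, "fluid": fluid, **st.concordance_percent(q)})
        quad_path = outdir / "quadrants.json"
        quad_path.write_text(json.dumps(quadrants, indent=2))
        conc_path = outdir / "concordance.csv"
        pd.DataFrame(conc_rows).to_csv(conc_path, index=False)
        record("concordance", t0, {"markers": markers}, _sha(cohort_path),
               [cutoffs_path, quad_path, conc_path])

        # --- correlations -----------------------------------------------------
        current = "correlate"
        t0 = time.perf_counter()
        corr = st.correlation_matrix(table, CORRELATION_VARIABLES)
        corr_path = outdir / "correlations.csv"
        corr.to_frame().to_csv(corr_path)
        record("correlate", t0, {"variables": CORRELATION_VARIABLES},
               _sha(cohort_path), [corr_path])

        # --- imputation -------------------------------------------------------
        current = "impute"
        t0 = time.perf_counter()
        imputed = impute(table, config.imputation)
        imp_paths = imputed.save(outdir, prefix="imputed")
        record("impute", t0, {"m": config.imputation.m,
                              "n_iterations": config.imputation.n_iterations,
                              "pmm_donors": config.imputation.pmm_donors},
               _sha(cohort_path), imp_paths)

        # --- ridge comparison -------------------------------------------------
        current = "ridge-compare"
        t0 = time.perf_counter()
        summary_rows = []
        warn: list[str] = []
        for fluid, pet in config.pairings:
            pair_key = f"{pet}_vs_{fluid}"
            for stratum in config.strata:
                mask = stratum_mask(imputed.tables[0], stratum)
                sub = _subset_imputed(imputed, mask) if stratum != "all" else imputed
                for outcome in config.outcomes:
                    if outcome in (fluid, pet):
                        continue
                    specs = make_specs(outcome, fluid, pet)
                    summary = bootstrap_models(sub, specs, B=config.bootstrap_B,
                                               seed=config.seed + 10)
                    if summary.n_redrawn:
                        warn.append(f"{pair_key}/{stratum}/{outcome}: "
                                    f"{summary.n_redrawn} replicates redrawn")
                    v = apply_criteria(summary)
                    df = summary.to_frame()
                    df.insert(0, "stratum", stratum)
                    df.insert(0, "pairing", pair_key)
                    summary_rows.append(df)
                    verdicts.setdefault(outcome, {}).setdefault(pair_key, {})[stratum] = {
                        "decision": v.decision, "criterion": v.firing_criterion,
                        "percent_change_fluid": v.percent_change_fluid,
                        "percent_change_pet": v.percent_change_pet,
                    }
        ridge_path = outdir / "ridge_summary.csv"
        pd.concat(summary_rows, ignore_index=True).to_csv(ridge_path, index=False)
        verdict_path = outdir / "verdicts.json"
        verdict_path.write_text(json.dumps(verdicts, indent=2, default=str))
        record("ridge-compare", t0, {"B": config.bootstrap_B, "pairings": config.pairings,
                                     "strata": config.strata},
               _sha(imp_paths[0]), [ridge_path, verdict_path], warn)

        # --- bagged-tree variable importance ---------------------------------
        current = "tree-vim"
        t0 = time.perf_counter()
        vim_paths = []
        for outcome in config.vim_outcomes:
            for stratum in config.vim_strata:
                mask = stratum_mask(imputed.tables[0], stratum)
                preds = [p for p in config.vim_predictors if p != outcome]
                vim = vim_across_imputations(imputed, outcome, preds,
                                             B=config.tree_B, seed=config.seed + 20,
                                             rows=mask)
                p = outdir / f"vim_{outcome}_{stratum}.csv"
                vim.to_csv(p)
                vim_paths.append(p)
                vim_rankings.setdefault(outcome, {})[stratum] = list(vim.index)
        record("tree-vim", t0, {"B": config.tree_B, "outcomes": config.vim_outcomes,
                                "strata": config.vim_strata},
               _sha(imp_paths[0]), vim_paths)

        report_path = outdir / "report.json"
        report_path.write_text(report.to_json())
        return report
    except Exception:
        (outdir / "report_partial.json").write_text(report.to_json())
        logger.error("pipeline aborted during stage %r", current)
        raise
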