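"""End-to-end pipeline: one config, reproducible run directory.

Stages run in a fixed order::

    generate/load -> adapt -> footprint -> score -> preprocess -> mfa
                  -> cluster -> characterize -> scenario

Each stage draws its randomness (if any) from a seed derived from the
single run seed and the stage's position, so re-running a prefix of the
pipeline reproduces the same intermediate results.  The run directory
contains every stage's tables as CSV plus a JSON manifest (seed, config
hash, package version, per-stage row counts and warnings); identical
config + seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._weights import wmean
from .core_io import (IMPACT_COLS, FOODS_SCHEMA, INTAKE_SCHEMA, NUTRIENT_SCHEMA,
                      PERSON_SCHEMA, ValidationError, join_consistency_check,
                      read_impact_factors, read_table, write_report_tables,
                      write_table)
from .characterize import kruskal_dunn, variance_normality_diag, vtest_cat, vtest_quant
from .cluster import cut_and_consolidate, suggest_k, ward_tree
from .diet_quality import BsdsConfig, compute_mbsds
from .footprint import group_contributions, person_impacts
from .lci import AdaptationRules, apply_adaptation
from .mfa import MFAInput, fit_mfa
from .preprocess import energy_adjust_residual, scale_to_sd
from .scenario import scenario_report
from .synthetic import (default_spec, generate_impact_factors, generate_population,
                        generate_trade_records)

log = logging.getLogger("dietshift")

STAGES = ("generate", "adapt", "footprint", "score", "preprocess", "mfa",
          "cluster", "characterize", "scenario")


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``synthetic`` / ``inputs`` is set."""

    synthetic: dict | None = None          # overrides for the default population spec
    inputs: dict | None = None             # paths: intakes, nutrients, persons, factors, foods
    adaptation: dict | None = None         # AdaptationRules fields (optional stage)
    mfa_dims: int = 5
    k: int | str = "auto"
    target_cluster: int | str = "auto"     # 'auto' = highest mean diet-quality cluster
    population: float = 4.3e6
    national_baselines: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "runs/latest"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValidationError(
                "config must set exactly one of 'synthetic' and 'inputs'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(root_seed: int, stage: str) -> int:
    """Counter-based per-stage seed below 2**31."""
    return int(np.random.SeedSequence([root_seed, STAGES.index(stage)])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class RunResult:
    config: PipelineConfig
    tables: dict
    manifest: dict
    out_dir: Path


def _config_hash(config: PipelineConfig) -> str:
    payload = config.to_dict()
    payload.pop("out_dir", None)  # where results land is not part of the analysis
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> RunResult:
    """Execute the pipeline; ``stop_after`` truncates it after that stage."""
    if stop_after is not None and stop_after not in STAGES:
        raise ValidationError(f"unknown stage {stop_after!r}; stages: {STAGES}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": _config_hash(config),
                      "version": __version__, "stages": []}
    tables: dict = {}
    stage_warnings: list[str] = []

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"name": stage, **info,
                                   "warnings": list(stage_warnings)})
        stage_warnings.clear()
        log.info("stage %s done: %s", stage, info)

    def done(stage: str) -> bool:
        return stop_after == stage

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = _run_stages(config, tables, record, done, caught, stage_warnings)
        except ValidationError as exc:
            current = manifest["stages"][-1]["name"] if manifest["stages"] else "generate"
            raise ValidationError(f"pipeline aborted after stage '{current}': {exc}") from exc

    _write_outputs(tables, out_dir)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str) + "\n")
    return RunResult(config=config, tables=tables, manifest=manifest, out_dir=out_dir)


def _run_stages(config, tables, record, done, caught, stage_warnings):
    def flush_warnings():
        stage_warnings.extend(str(w.message) for w in caught)
        caught.clear()

    # --- generate / load -------------------------------------------------
    if config.synthetic is not None:
        overrides = dict(config.synthetic)
        n = int(overrides.pop("n_persons", 5125))
        spec = default_spec(n_persons=n, seed=stage_seed(config.seed, "generate"),
                            **overrides)
        intakes, nutrients, persons, truth = generate_population(spec)
        factors = generate_impact_factors(spec)
        trade = generate_trade_records(spec)
        foods = spec.foods
        tables["ground_truth"] = truth.to_frame()
    else:
        paths = config.inputs
        intakes = read_table(paths["intakes"], INTAKE_SCHEMA)
        nutrients = read_table(paths["nutrients"], NUTRIENT_SCHEMA)
        persons = read_table(paths["persons"], PERSON_SCHEMA)
        factors = read_impact_factors(paths["factors"],
                                      per=paths.get("factors_per", "g"))
        foods = read_table(paths["foods"], FOODS_SCHEMA)
        trade = None
    report = join_consistency_check(intakes, persons, factors, foods)
    tables.update(intakes=intakes, nutrients=nutrients, persons=persons,
                  factors=factors, foods=foods, trade=trade,
                  consistency=report)
    flush_warnings()
    record("generate", rows=len(intakes), consistent=report.ok)
    if done("generate"):
        return

    # --- adapt ------------------------------------------------------------
    if config.adaptation is not None:
        rules = AdaptationRules(
            intensity_source=config.adaptation.get("intensity_source", {}),
            intensity_europe=config.adaptation.get("intensity_europe", {}),
            intensity_domestic=config.adaptation.get("intensity_domestic", {}),
            electricity_share=pd.Series(config.adaptation.get("electricity_share", {}),
                                        dtype=float),
            livestock_foods=frozenset(config.adaptation.get("livestock_foods", ())),
            feed_factor=config.adaptation.get("feed_factor", {}),
        )
        if trade is None:
            raise ValidationError("adaptation requires trade records")
        factors = apply_adaptation(factors, trade, rules)
        tables["factors"] = factors
    flush_warnings()
    record("adapt", adapted=bool(config.adaptation))
    if done("adapt"):
        return

    # --- footprint ---------------------------------------------------------
    weights = persons.reindex(intakes.index)["survey_weight"].to_numpy()
    impacts = person_impacts(intakes, factors)
    tables["impacts"] = impacts
    flush_warnings()
    record("footprint", rows=len(impacts))
    if done("footprint"):
        return

    # --- score -------------------------------------------------------------
    food_groups = foods["food_group"]
    scores_bsds = compute_mbsds(intakes, nutrients, persons, food_groups, BsdsConfig())
    tables["mbsds"] = scores_bsds
    flush_warnings()
    record("score", mean_mbsds=float(wmean(scores_bsds["mbsds"].to_numpy(), weights)))
    if done("score"):
        return

    # --- preprocess ---------------------------------------------------------
    group_intakes = intakes.T.groupby(food_groups).sum().T
    energy = nutrients["energy_kj"]
    nutrient_vars = nutrients.drop(columns=["energy_kj"])
    adj_nutrients = energy_adjust_residual(nutrient_vars, energy, weights)
    adj_impacts = energy_adjust_residual(impacts, energy, weights)
    adj_groups = energy_adjust_residual(group_intakes, energy, weights)
    std_nutrients, _ = scale_to_sd(adj_nutrients, weights)
    std_impacts, _ = scale_to_sd(adj_impacts, weights)
    std_groups, _ = scale_to_sd(adj_groups, weights)
    tables.update(adjusted_nutrients=adj_nutrients.values,
                  adjusted_impacts=adj_impacts.values,
                  adjusted_group_intakes=adj_groups.values)
    flush_warnings()
    record("preprocess", variables=std_nutrients.shape[1] + std_impacts.shape[1])
    if done("preprocess"):
        return

    # --- mfa -----------------------------------------------------------------
    ratio = (nutrients["plant_protein_g"] /
             nutrients["animal_protein_g"].clip(lower=1e-9))
    sup_quant = pd.concat([
        std_groups,
        scores_bsds["mbsds"].rename("mbsds"),
        energy.rename("energy_kj"),
        ratio.rename("plant_animal_protein_ratio"),
        persons.reindex(intakes.index)[["age", "bmi", "waist"]],
    ], axis=1)
    sup_cat = persons.reindex(intakes.index)[
        ["sex", "education", "income", "municipality", "smoking",
         "physical_activity"]].astype(str)
    mfa_result = fit_mfa(MFAInput(
        groups={"nutrients": std_nutrients, "impacts": std_impacts},
        weights=weights, sup_quant=sup_quant, sup_cat=sup_cat,
        n_dims=config.mfa_dims))
    tables["mfa"] = mfa_result
    flush_warnings()
    record("mfa", dim1_pct=float(mfa_result.pct_variance[0]),
           dims=mfa_result.n_dims)
    if done("mfa"):
        return

    # --- cluster --------------------------------------------------------------
    tree = ward_tree(mfa_result.scores, weights)
    n = len(mfa_result.scores)
    suggestion = suggest_k(tree, range(2, min(9, n - 1)))
    k = suggestion.k if config.k == "auto" else int(config.k)
    solution = cut_and_consolidate(tree, k, mfa_result.scores, weights,
                                   suggestion=suggestion)
    tables["clusters"] = solution
    flush_warnings()
    record("cluster", k=k, suggested_k=suggestion.k,
           weak_elbow=suggestion.weak_elbow,
           within_inertia=solution.within_inertia)
    if done("cluster"):
        return

    # --- characterize -----------------------------------------------------------
    labels = solution.labels
    lab = labels.to_numpy()
    char_vars = pd.concat([impacts, scores_bsds["mbsds"].rename("mbsds")], axis=1)
    vtests = {var: vtest_quant(char_vars[var].to_numpy(), lab, weights)
              for var in char_vars.columns}
    vtest_table = pd.concat(vtests, names=["variable", "cluster"])
    posthoc = {var: kruskal_dunn(char_vars[var].to_numpy(), lab)
               for var in char_vars.columns}
    posthoc_table = pd.concat({v: r.pairwise for v, r in posthoc.items()},
                              names=["variable", "a", "b"])
    diag = pd.concat({var: variance_normality_diag(char_vars[var].to_numpy(), lab)
                      for var in char_vars.columns}, names=["variable", None])
    cat_v = pd.concat({c: vtest_cat(sup_cat[c], lab, weights)
                       for c in ("sex", "municipality")},
                      names=["variable", "cluster", "category"])
    contributions = group_contributions(intakes, factors, food_groups,
                                        labels=labels, weights=weights)
    tables.update(vtests=vtest_table, posthoc=posthoc_table, diagnostics=diag,
                  vtests_cat=cat_v, contributions=contributions)
    flush_warnings()
    record("characterize", variables=len(char_vars.columns))
    if done("characterize"):
        return

    # --- scenario ------------------------------------------------------------------
    if config.target_cluster == "auto":
        means = {int(c): wmean(scores_bsds.loc[lab == c, "mbsds"].to_numpy(),
                               weights[lab == c])
                 for c in np.unique(lab)}
        target = max(sorted(means), key=lambda c: means[c])
    else:
        target = int(config.target_cluster)
    adj_impact_vals = tables["adjusted_impacts"]
    report = scenario_report(
        adj_impact_vals, labels, target, weights,
        population=config.population,
        national_baselines=config.national_baselines or None,
        units={"gwp": "Mt_from_kg", "land_use": "same",
               "marine_eutroph": "t_from_g", "freshwater_eutroph": "t_from_g"},
        group_intakes=group_intakes)
    tables["scenario"] = report
    flush_warnings()
    record("scenario", target_cluster=target,
           gwp_pct_change=float(report.impacts.loc["gwp", "pct_change"]))
    return


def _write_outputs(tables: dict, out_dir: Path) -> None:
    for name in ("intakes", "nutrients", "persons", "factors", "foods",
                 "trade", "impacts", "mbsds", "ground_truth"):
        if tables.get(name) is not None:
            write_table(tables[name], out_dir / f"{name}.csv")
    if "consistency" in tables:
        (out_dir / "consistency.json").write_text(tables["consistency"].to_json() + "\n")
    if "mfa" in tables:
        m = tables["mfa"]
        write_table(m.scores, out_dir / "mfa_scores.csv")
        eig = pd.DataFrame({"eigenvalue": m.eigenvalues, "pct_variance": m.pct_variance})
        eig.index.name = "dim"
        write_table(eig, out_dir / "mfa_eigenvalues.csv")
        write_table(m.var_correlations, out_dir / "mfa_correlations.csv")
    if "clusters" in tables:
        sol = tables["clusters"]
        write_table(sol.labels.to_frame(), out_dir / "cluster_labels.csv")
        (out_dir / "cluster_tree.json").write_text(
            json.dumps(sol.tree.to_nested_lists()) + "\n")
    reports = {}
    if "vtests" in tables:
        reports["report_vtests"] = tables["vtests"].reset_index()
        reports["report_posthoc"] = tables["posthoc"].reset_index()
        reports["report_contributions"] = tables["contributions"]
    if "scenario" in tables:
        rep = tables["scenario"]
        reports["report_scenario_impacts"] = rep.impacts.reset_index()
        reports["report_food_changes"] = rep.food_changes.rename_axis(
            "food_group").reset_index()
    if reports:
        write_report_tables(reports, out_dir)
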