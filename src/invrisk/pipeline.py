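"""End-to-end orchestration: occurrences + climates -> priority table.

``run_species`` is the in-memory workhorse used by tests and
experiments; ``run_pipeline`` is the file-based driver behind the CLI's
``run`` subcommand.  One master seed fans out deterministically to
every stochastic stage (per-species splits and background samples), so
rerunning a configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (
    ThresholdPair,
    auc,
    auc_band,
    classify_map,
    thresholds_from_training,
)
from .grids import ClimateStack, GridMismatchError, Layer, cell_areas, read_stack, write_ascii_grid
from .habitat_change import HabitatChange, change_metrics
from .occurrences import OccurrenceSet, read_occurrences, list_species, split_train_test, thin_to_cells
from .prioritize import comparison_table, prioritize, priority_frame
from .risk_assessment import load_schema, load_scorecard, total_score
from .sdm_maxent import (
    MaxentModel,
    fit_maxent,
    predict_suitability,
    presence_features_matrix,
    sample_background,
)
from .varselect import SelectionReport, select_variables


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineParams:
    """Tunable parameters of a run; defaults are the study conditions."""

    train_fraction: float = 0.75
    pearson_threshold: float = 0.7
    vif_threshold: float = 10.0
    reg_multiplier: float = 1.0
    n_background: int = 10_000
    seed: int = 0
    thin: bool = True
    hinge: bool = False
    suitable_class: object = 2  # 2 = high-risk, "suitable" = classes 1+2

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise PipelineError("train_fraction must be in (0, 1)")
        if self.pearson_threshold <= 0 or self.vif_threshold <= 0:
            raise PipelineError("selection thresholds must be positive")
        if self.reg_multiplier < 0 or self.n_background < 1:
            raise PipelineError("reg_multiplier must be >= 0 and n_background >= 1")


@dataclass
class RunConfig:
    occurrences: Path
    baseline_dir: Path
    future_dir: Path
    out_dir: Path
    schema: Path | None = None
    scorecards_dir: Path | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        paths = raw.get("paths", {})
        base = Path(path).parent

        def resolve(key, required=True):
            if key not in paths or paths[key] is None:
                if required:
                    raise PipelineError(f"config missing required path {key!r}")
                return None
            p = Path(paths[key])
            return p if p.is_absolute() else base / p

        return cls(
            occurrences=resolve("occurrences"),
            baseline_dir=resolve("baseline_dir"),
            future_dir=resolve("future_dir"),
            out_dir=resolve("out_dir"),
            schema=resolve("schema", required=False),
            scorecards_dir=resolve("scorecards_dir", required=False),
            params=PipelineParams(**raw.get("params", {})),
        )

    def validate(self) -> None:
        for key in ("occurrences", "baseline_dir", "future_dir"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise PipelineError(f"input {key} does not exist: {p}")
        if self.schema is not None and not Path(self.schema).exists():
            raise PipelineError(f"schema file does not exist: {self.schema}")


@dataclass
class SpeciesResult:
    """Everything the pipeline learns about one species."""

    species: str
    occurrences: OccurrenceSet
    selection: SelectionReport
    model: MaxentModel
    thresholds: ThresholdPair
    auc_train: float
    auc_test: float
    suitability_baseline: Layer
    suitability_future: Layer
    classes_baseline: Layer
    classes_future: Layer
    change_high: HabitatChange
    change_suitable: HabitatChange

    def evaluation_row(self) -> dict:
        return {
            "species": self.species,
            "n_presences": len(self.occurrences),
            "n_variables": len(self.selection.kept),
            "variables": " ".join(self.selection.kept),
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
            "auc_band": auc_band(self.auc_test),
            "t_low_ltp": self.thresholds.t_low,
            "t_high_maxsss": self.thresholds.t_high,
            "thresholds_flagged": self.thresholds.flagged,
        }


def species_seed(master_seed: int, species: str) -> int:
    """Stable per-species seed below 2^31, derived from the master seed."""
    return (master_seed * 1_000_003 + zlib.crc32(species.encode())) % (2**31 - 1)


def run_species(
    occ: OccurrenceSet,
    baseline: ClimateStack,
    future: ClimateStack,
    params: PipelineParams | None = None,
) -> SpeciesResult:
    """Fit, evaluate and project one species; seeds derive from
    ``params.seed`` and the species name."""
    params = params or PipelineParams()
    if baseline.spec != future.spec:
        raise GridMismatchError("baseline and future stacks are on different grids")
    shared = [v for v in baseline.names if v in future.names]
    if not shared:
        raise PipelineError("baseline and future stacks share no variables")
    baseline_shared = baseline.subset(shared)
    seed = species_seed(params.seed, occ.species)

    occ_model = thin_to_cells(occ, baseline.spec, baseline_shared) if params.thin else occ
    if len(occ_model) < 2:
        raise PipelineError(
            f"species {occ.species!r}: fewer than 2 usable presences after cleaning/thinning"
        )
    train, test = split_train_test(occ_model, params.train_fraction, seed=seed)

    bg_rows, bg_cols = sample_background(baseline_shared, params.n_background, seed=seed)
    bg_matrix = baseline_shared.extract(bg_rows, bg_cols)
    selection = select_variables(
        pd.DataFrame(bg_matrix, columns=shared),
        pearson_threshold=params.pearson_threshold,
        vif_threshold=params.vif_threshold,
    )
    kept = selection.kept
    if not kept:
        raise PipelineError(f"species {occ.species!r}: no covariates survived selection")
    keep_idx = [shared.index(v) for v in kept]
    bg_kept = bg_matrix[:, keep_idx]

    X_train = presence_features_matrix(baseline, train, kept)
    X_test = presence_features_matrix(baseline, test, kept)

    from .sdm_maxent import FeatureExpansion

    expansion = FeatureExpansion.fit(bg_kept, kept, hinge=params.hinge)
    model = fit_maxent(
        X_train,
        bg_kept,
        expansion=expansion,
        reg_multiplier=params.reg_multiplier,
        seed=seed,
    )

    train_scores = model.logistic(X_train)
    bg_scores = model.logistic(bg_kept)
    thresholds = thresholds_from_training(train_scores, bg_scores)
    auc_train = auc(train_scores, bg_scores)

    # held-out AUC against a fresh background sample of the same size
    fresh_rows, fresh_cols = sample_background(
        baseline_shared, len(bg_rows), seed=seed + 1
    )
    fresh_scores = model.logistic(
        baseline_shared.extract(fresh_rows, fresh_cols)[:, keep_idx]
    )
    auc_test = auc(model.logistic(X_test), fresh_scores)

    suit_b = predict_suitability(model, baseline)
    suit_f = predict_suitability(model, future)
    cls_b = classify_map(suit_b, thresholds)
    cls_f = classify_map(suit_f, thresholds)
    areas = cell_areas(baseline.spec)
    return SpeciesResult(
        species=occ.species,
        occurrences=occ_model,
        selection=selection,
        model=model,
        thresholds=thresholds,
        auc_train=auc_train,
        auc_test=auc_test,
        suitability_baseline=suit_b,
        suitability_future=suit_f,
        classes_baseline=cls_b,
        classes_future=cls_f,
        change_high=change_metrics(cls_b, cls_f, areas, which_class=2),
        change_suitable=change_metrics(cls_b, cls_f, areas, which_class="suitable"),
    )


def _write_csv(df: pd.DataFrame, path: Path, params: PipelineParams) -> None:
    """CSV with the originating parameter values as header comments."""
    header = "".join(f"# {k} = {v}\n" for k, v in asdict(params).items())
    path.write_text(header + df.to_csv(index=False))


def run_pipeline(config: RunConfig) -> dict:
    """File-based end-to-end run; returns the manifest dict.

    Outputs under ``out_dir``: per-species subdirectories (cleaning
    report, selection report, model JSON, evaluation CSV, suitability
    and classified rasters for both scenarios), change_metrics.csv,
    risk_scores.csv, priority.csv, comparison.csv and manifest.json.
    """
    config.validate()
    params = config.params
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        baseline = read_stack(config.baseline_dir)
    except Exception as exc:
        raise PipelineError(f"stage load-baseline failed: {exc}") from exc
    try:
        future = read_stack(config.future_dir)
    except Exception as exc:
        raise PipelineError(f"stage load-future failed: {exc}") from exc

    species_names = list_species(config.occurrences)
    results: list[SpeciesResult] = []
    eval_rows, change_rows = [], []
    for sp in species_names:
        try:
            occ = read_occurrences(config.occurrences, sp)
            sp_dir = out / "species" / sp.replace(" ", "_")
            sp_dir.mkdir(parents=True, exist_ok=True)
            (sp_dir / "cleaning_report.txt").write_text(occ.report.as_text())
            res = run_species(occ, baseline, future, params)
        except Exception as exc:
            raise PipelineError(f"stage model-species [{sp}] failed: {exc}") from exc
        results.append(res)
        _write_csv(res.selection.to_frame(), sp_dir / "selection_report.csv", params)
        res.model.save(sp_dir / "model.json")
        _write_csv(pd.DataFrame([res.evaluation_row()]), sp_dir / "evaluation.csv", params)
        write_ascii_grid(res.suitability_baseline, sp_dir / "suitability_baseline.asc", precision=6)
        write_ascii_grid(res.suitability_future, sp_dir / "suitability_future.asc", precision=6)
        write_ascii_grid(res.classes_baseline, sp_dir / "classes_baseline.asc", precision=1)
        write_ascii_grid(res.classes_future, sp_dir / "classes_future.asc", precision=1)
        eval_rows.append(res.evaluation_row())
        for label, ch in (("high_risk", res.change_high), ("suitable", res.change_suitable)):
            change_rows.append({"species": sp, "class": label, **ch.as_dict()})

    _write_csv(pd.DataFrame(eval_rows), out / "evaluation.csv", params)
    _write_csv(pd.DataFrame(change_rows), out / "change_metrics.csv", params)

    manifest = {
        "invrisk_version": __version__,
        "seed": params.seed,
        "parameters": {k: str(v) for k, v in asdict(params).items()},
        "species": species_names,
        "n_species_modelled": len(results),
    }

    if config.scorecards_dir is not None:
        schema = load_schema(config.schema)
        risk_by_species = {}
        risk_rows = []
        for card_path in sorted(Path(config.scorecards_dir).glob("*.yml")):
            card = load_scorecard(card_path)
            risk = total_score(card, schema)
            risk_by_species[card.species] = risk
            row = {
                "species": risk.species,
                "score": risk.score,
                "category": risk.category,
                "answered_fraction": risk.answered_fraction,
                "insufficient_information": risk.insufficient_information,
            }
            for g, (earned, mx) in risk.group_subtotals.items():
                row[f"{g.replace(' ', '_')}_earned"] = earned
                row[f"{g.replace(' ', '_')}_max"] = mx
            risk_rows.append(row)
        _write_csv(pd.DataFrame(risk_rows), out / "risk_scores.csv", params)

        entries = []
        for res in results:
            if res.species not in risk_by_species:
                continue
            ch = res.change_high if params.suitable_class == 2 else res.change_suitable
            entries.append((res.species, risk_by_species[res.species], ch))
        if entries:
            records = prioritize(entries)
            _write_csv(priority_frame(records), out / "priority.csv", params)
            _write_csv(comparison_table(entries), out / "comparison.csv", params)
            manifest["n_prioritised"] = len(records)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
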