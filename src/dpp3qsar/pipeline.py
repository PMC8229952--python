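"""End-to-end orchestration of the coumarin hDPP III QSAR analysis.

``run_paper_pipeline`` executes: load dataset -> build structures -> embed
3D -> descriptors -> response transform -> inactive exclusion -> activity
split -> GA-MLR -> validation battery -> Williams applicability domain ->
criteria checklist -> frozen-model predictions for the proposed compounds.
Every artifact embeds the package version and the resolved seed set, and a
structured log line per stage records the dataset bookkeeping
(compounds in/out, descriptors in/out).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import log_response
from .compound_library import (
    CompoundRecord,
    build_structures,
    embed_coordinates,
    load_paper_dataset,
    write_structures,
)
from .descriptors import (
    MODEL_DESCRIPTORS,
    descriptor_table,
    wide_descriptor_table,
    write_descriptor_csv,
)
from .qsar_model import (
    GAConfig,
    MODEL2_PUBLISHED,
    SplitResult,
    activity_ranked_split,
    exclude_inactives,
    fit_ols,
    ga_select,
    predict,
    prune_descriptors,
)
from .validation import (
    ValidationReport,
    check_criteria,
    compute_validation_report,
    williams,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_paper_pipeline",
           "refit_model_descriptors"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (fully serializable)."""

    outdir: str = "qsar_run"
    embed_seed: int = 2021
    exclusion_seed: int = 1
    split_seed: int = 1
    yscramble_seed: int = 1
    n_yscramble: int = 500
    n_exclude_inactives: int = 8
    # The dataset records which inactives were actually excluded; by default the
    # pipeline honours that recorded draw instead of re-drawing.
    use_recorded_exclusions: bool = True
    eeig_weighting: str = "edge_degree"
    const_fraction: float = 0.85
    max_abs_corr: float = 0.95
    outlier_threshold: float = 2.0
    ga: GAConfig = field(default_factory=lambda: GAConfig(seed=1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    """Objects and artifact paths produced by one pipeline run."""

    config: PipelineConfig
    records: list[CompoundRecord]
    descriptors: pd.DataFrame
    split: SplitResult
    model: object
    report: ValidationReport
    criteria: dict[str, bool]
    predictions: pd.DataFrame
    artifacts: dict[str, Path]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "package": f"dpp3qsar {__version__}",
        "seeds": (
            f"embed={config.embed_seed} exclusion={config.exclusion_seed} "
            f"split={config.split_seed} ga={config.ga.seed} "
            f"yscramble={config.yscramble_seed}"
        ),
        "eeig_weighting": config.eeig_weighting,
    }


def refit_model_descriptors(
    records: list[CompoundRecord] | None = None,
    embed_seed: int = 2021,
    drop_outlier: bool = True,
    eeig_weighting: str = "edge_degree",
):
    """Refit the published three-descriptor model on own-computed inputs.

    Builds and embeds the modeling compounds, computes (EEig05x, Mor10u,
    nArOH), and fits OLS of the log-response on those columns.  With
    ``drop_outlier`` the recorded response outlier is excluded, mirroring
    the improved-model refit.  Numerical identity with the published
    coefficients is not expected (the original geometries and descriptor
    software conventions are not reproducible); the sign pattern is.
    """
    if records is None:
        records = load_paper_dataset()
    pool = [
        r
        for r in records
        if r.role == "modeling"
        or (r.role == "excluded_outlier" and not drop_outlier)
    ]
    graphs = build_structures(pool)
    structs = [embed_coordinates(graphs[r.compound_id], embed_seed) for r in pool]
    table = descriptor_table(
        structs, ids=[r.compound_id for r in pool], eeig_weighting=eeig_weighting
    )
    y = np.array([log_response(r.inhibition_pct) for r in pool])
    ids = [r.compound_id for r in pool]
    # descriptor_table sorts by id; align the response the same way
    order = np.argsort(ids)
    return fit_ols(table, y[order], training_ids=sorted(ids))


def run_paper_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on the packaged dataset; write all artifacts."""
    config = config or PipelineConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": log_path}
    try:
        # --- dataset ---------------------------------------------------
        records = load_paper_dataset()
        tested = [r for r in records if r.is_tested]
        proposed = [r for r in records if r.role == "proposed"]
        logger.info(
            "stage=load compounds_total=%d tested=%d proposed=%d",
            len(records), len(tested), len(proposed),
        )

        # --- structures and descriptors ---------------------------------
        graphs = build_structures(records)
        structs = {
            cid: embed_coordinates(g, config.embed_seed)
            for cid, g in graphs.items()
        }
        ordered_ids = sorted(structs)
        struct_list = [structs[cid] for cid in ordered_ids]
        trio = descriptor_table(
            struct_list, ids=ordered_ids, eeig_weighting=config.eeig_weighting
        )
        wide = wide_descriptor_table(
            struct_list, ids=ordered_ids, eeig_weighting=config.eeig_weighting
        )
        logger.info(
            "stage=descriptors compounds=%d pool_columns=%d",
            len(wide), wide.shape[1],
        )

        sdf_path = outdir / "structures.sdf"
        write_structures(struct_list, sdf_path, "sdf")
        artifacts["structures"] = sdf_path
        desc_path = outdir / "descriptors.csv"
        write_descriptor_csv(wide, desc_path, prov)
        artifacts["descriptors"] = desc_path

        # --- response and exclusions ------------------------------------
        responses = {
            r.compound_id: log_response(r.inhibition_pct)
            for r in tested
        }
        if config.use_recorded_exclusions:
            excluded = tuple(
                r.compound_id for r in tested if r.role == "excluded_inactive"
            )
            retained = [
                r.compound_id for r in tested if r.compound_id not in excluded
            ]
        else:
            part = exclude_inactives(
                records, config.n_exclude_inactives, config.exclusion_seed
            )
            excluded = part.excluded_inactive_ids
            retained = list(part.training_ids)
        logger.info(
            "stage=exclusion tested=%d excluded_inactive=%d retained=%d",
            len(tested), len(excluded), len(retained),
        )

        # --- split -------------------------------------------------------
        split0 = activity_ranked_split(
            retained,
            [responses[i] for i in retained],
            n_groups=5,
            seed=config.split_seed,
        )
        logger.info(
            "stage=split training=%d test=%d",
            len(split0.training_ids), len(split0.test_ids),
        )

        # --- GA-MLR model 1 ----------------------------------------------
        pool = prune_descriptors(
            wide.loc[ordered_ids].drop(index=[p.compound_id for p in proposed]),
            config.const_fraction,
            config.max_abs_corr,
        )
        logger.info(
            "stage=prune descriptors_in=%d descriptors_out=%d",
            wide.shape[1], pool.shape[1],
        )
        tr_ids = list(split0.training_ids)
        te_ids = list(split0.test_ids)
        y_tr = np.array([responses[i] for i in tr_ids])
        y_te = np.array([responses[i] for i in te_ids])
        ga1 = ga_select(pool.loc[tr_ids], y_tr, config.ga)
        model1 = dataclasses.replace(ga1.model, training_ids=tuple(tr_ids))
        logger.info(
            "stage=ga_model1 descriptors=%s fitness=%.3f",
            ",".join(model1.descriptor_names), ga1.best_fitness,
        )

        # --- applicability domain of model 1 -> outlier removal -----------
        X_tr1 = pool.loc[tr_ids, list(model1.descriptor_names)]
        wd1 = williams(
            model1, X_tr1, y_tr,
            X_query=pool.loc[te_ids, list(model1.descriptor_names)],
            y_query=y_te, ids_tr=tr_ids, ids_query=te_ids,
            outlier_threshold=config.outlier_threshold,
        )
        train_outliers = tuple(i for i in wd1.outlier_ids if i in tr_ids)
        logger.info(
            "stage=williams_model1 h_star=%.3f outliers=%s",
            wd1.h_star, list(train_outliers),
        )

        # --- refit without outliers (model 2 analogue) ---------------------
        tr2_ids = [i for i in tr_ids if i not in train_outliers]
        y_tr2 = np.array([responses[i] for i in tr2_ids])
        ga2 = ga_select(pool.loc[tr2_ids], y_tr2, config.ga)
        model = dataclasses.replace(ga2.model, training_ids=tuple(tr2_ids))
        logger.info(
            "stage=ga_model2 training=%d descriptors=%s fitness=%.3f",
            len(tr2_ids), ",".join(model.descriptor_names), ga2.best_fitness,
        )
        split = SplitResult(
            training_ids=tuple(tr2_ids),
            test_ids=tuple(te_ids),
            excluded_inactive_ids=tuple(excluded),
            outlier_ids=tuple(train_outliers),
        )

        # --- validation ----------------------------------------------------
        X_tr = pool.loc[tr2_ids, list(model.descriptor_names)]
        X_te = pool.loc[te_ids, list(model.descriptor_names)]
        report = compute_validation_report(
            model, X_tr, y_tr2, X_te, y_te,
            n_yscramble=config.n_yscramble,
            yscramble_seed=config.yscramble_seed,
        )
        criteria = check_criteria(report)
        logger.info(
            "stage=validation R2=%.3f Q2_LOO=%.3f criteria_passed=%d/%d",
            report.R2, report.Q2_LOO,
            sum(criteria.values()), len(criteria),
        )

        wd = williams(
            model, X_tr, y_tr2, X_query=X_te, y_query=y_te,
            ids_tr=tr2_ids, ids_query=te_ids,
            outlier_threshold=config.outlier_threshold,
        )

        # --- predictions for the proposed compounds with frozen model ------
        prop_ids = [p.compound_id for p in proposed]
        X_prop = trio.loc[prop_ids, list(MODEL_DESCRIPTORS)]
        pred_log = np.asarray(predict(MODEL2_PUBLISHED, X_prop))
        predictions = pd.DataFrame(
            {
                "id": prop_ids,
                **{d: X_prop[d].to_numpy() for d in MODEL_DESCRIPTORS},
                "pred_log_pct_inhibition": pred_log,
                "pred_pct_inhibition": 10**pred_log,
                "model": "published2",
            }
        )
        logger.info(
            "stage=predict proposed=%s pred_log=%s",
            prop_ids, [f"{v:.2f}" for v in pred_log],
        )

        # --- artifacts ------------------------------------------------------
        model_path = outdir / "model.json"
        model.to_json(model_path, provenance=prov)
        artifacts["model"] = model_path
        report_json = outdir / "report.json"
        report.to_json(report_json, provenance={**prov, "criteria": criteria})
        artifacts["report_json"] = report_json
        report_tsv = outdir / "report.tsv"
        report.to_tsv(report_tsv, provenance=prov)
        artifacts["report_tsv"] = report_tsv
        williams_path = outdir / "williams.tsv"
        wd.to_tsv(williams_path, provenance=prov)
        artifacts["williams"] = williams_path
        pred_path = outdir / "predictions.csv"
        with open(pred_path, "w") as fh:
            for key, val in prov.items():
                fh.write(f"# {key}: {val}\n")
            predictions.to_csv(fh, index=False)
        artifacts["predictions"] = pred_path
        config_path = outdir / "config.json"
        config_path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
        artifacts["config"] = config_path

        return PipelineResult(
            config=config,
            records=records,
            descriptors=wide,
            split=split,
            model=model,
            report=report,
            criteria=criteria,
            predictions=predictions,
            artifacts=artifacts,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
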