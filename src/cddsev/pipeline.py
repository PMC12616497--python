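"""End-to-end driver: filter -> harmonize -> fit -> score -> weights -> validate.

Every stage logs its n and decisions; all outputs carry a provenance
header (package version, seed, config hash) and are byte-identical under
an identical (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import OBSERVED_VARS, config_hash, read_cohort, write_cohort
from .fiml import factor_scores, filter_inclusion, fit_sem
from .model import SemModel, load_packaged_model, parse_model_config
from .scoring import WeightSet, apply_weights, derive_weights, harmonize, standardize
from .validate import reliability_table, validation_report, write_report

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_csv: str | Path | None = None
    model_config: str | Path | None = None       # None -> packaged default
    weights_file: str | Path | None = None       # None -> derive from cohort
    outdir: str | Path = "cddsev_out"
    seed: int = 0
    inclusion_level: str = "variable"            # or "instrument"
    min_scores: int = 2
    icc_form: str = "icc2"
    ttest_flavor: str = "welch"
    rmsea_denominator: str = "n-1"
    options: dict = field(default_factory=dict)

    def meta(self) -> dict:
        # the hash covers the analytic configuration only, so runs writing
        # to different directories remain byte-identical
        hashed = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return {
            "cddsev_version": __version__,
            "seed": self.seed,
            "config_hash": config_hash(hashed),
        }


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Run the full severity-scoring pipeline and write all artifacts.

    Returns a dict with the in-memory results (fit, weights, scores,
    validation report) and the paths written.  Raises on any stage failure;
    the CLI maps that to a nonzero exit.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.meta()

    if cohort is None:
        if config.cohort_csv is None:
            raise ValueError("no cohort: pass a frame or set cohort_csv")
        cohort = read_cohort(config.cohort_csv)

    model = (load_packaged_model() if config.model_config is None
             else parse_model_config(config.model_config))

    included = filter_inclusion(cohort, min_scores=config.min_scores,
                                level=config.inclusion_level)
    log.info("included %d baseline rows (excluded %d)", len(included),
             included.attrs.get("n_excluded", 0))
    harm = harmonize(included)

    fit = fit_sem(model, harm, rmsea_denominator=config.rmsea_denominator)
    scores = factor_scores(model, fit, harm)
    scores["global_std"] = standardize(scores["global"])

    if config.weights_file is not None:
        weights = WeightSet.from_json(config.weights_file)
    else:
        weights = derive_weights(harm, scores["global_std"],
                                 provenance=f"derived(seed={config.seed})")

    complete = ~harm[list(OBSERVED_VARS)].isna().any(axis=1)
    weighted = np.full(len(harm), np.nan)
    if complete.any():
        weighted[complete.to_numpy()] = apply_weights(
            harm[complete.to_numpy()], weights)

    scores_out = scores[["subject_id", "global_std",
                         "communication", "comorbidities",
                         "n_observed_vars"]].copy()
    scores_out = scores_out.rename(columns={"global_std": "global_severity"})
    scores_out["weighted_global"] = weighted

    report = validation_report(included, scores["global_std"].to_numpy(),
                               outdir=outdir / "figures",
                               ttest_flavor=config.ttest_flavor)

    reliability = None
    if (cohort["visit"] == "retest").any():
        try:
            reliability = reliability_table(cohort, weights, form=config.icc_form)
        except ValueError as exc:
            log.warning("reliability table skipped: %s", exc)

    # -- write artifacts ----------------------------------------------
    paths = {}
    fit_report = {"_provenance": meta, **fit.to_dict(),
                  "n_excluded": int(included.attrs.get("n_excluded", 0))}
    paths["fit_report"] = outdir / "fit_report.json"
    Path(paths["fit_report"]).write_text(
        json.dumps(fit_report, indent=2, default=float) + "\n")

    paths["weights"] = outdir / "weights.json"
    weights.to_json(paths["weights"], meta=meta)

    paths["scores"] = outdir / "scores.csv"
    write_cohort(scores_out, paths["scores"], meta=meta)

    paths["validation"] = outdir / "validation.json"
    write_report({"_provenance": meta, **report}, paths["validation"])

    if reliability is not None:
        paths["reliability"] = outdir / "reliability.csv"
        write_cohort(reliability, paths["reliability"], meta=meta)

    return {"fit": fit, "weights": weights, "scores": scores_out,
            "validation": report, "reliability": reliability,
            "paths": {k: str(v) for k, v in paths.items()}}
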