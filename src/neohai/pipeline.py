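"""End-to-end pipeline: classification -> scoring -> tool -> diagnostics -> LOT.

``run_pipeline`` ties every stage together and writes a reproducible
analysis bundle to an output directory:

* ``episodes_augmented.csv`` — the episode table plus reference-standard
  label, rationale, per-test positivity, tool recommendation, and
  theoretical LOT (every number in the other artifacts is recomputable from
  this file);
* ``metrics.csv`` / ``metrics.json`` — the diagnostic-accuracy table (tests
  as columns, counts and metrics as rows);
* ``tree.txt`` / ``tree.json`` — the exhaustive-CHAID tree over the NeoHoP
  score band and the t24 CRP band;
* ``lot_comparison.csv`` / ``lot_comparison.json`` — observed vs.
  theoretical LOT per stratum;
* ``tool_summary.json`` — tool branch counts and exclusions;
* ``manifest.json`` — seed, package version, sizes, exclusion counts.

Identical configuration and seed give a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chaid import CHAIDConfig, CHAIDNode, grow_tree
from .classification import HAIClass, classify_cohort
from .decision_tool import apply_tool
from .diagnostics import confusion_matrix, metrics_table
from .episodes import EpisodeRecord, read_episodes, record_to_row, validate_episode
from .scoring import (
    DEFAULT_CRP_CUTOFF,
    DEFAULT_NEOHOP_THRESHOLD,
    TEST_NAMES,
    TestSpec,
    compute_neohop,
    test_positivity,
)
from .stats import lot_comparison, plot_lot_comparison
from .synthetic import CohortConfig, cohort_report, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Pipeline settings; exactly one of ``input_path`` / ``synthetic`` is set."""

    input_path: str | None = None
    synthetic: CohortConfig | None = None
    output_dir: str = "neohai_output"
    crp_cutoff: float = DEFAULT_CRP_CUTOFF
    neohop_threshold: int = DEFAULT_NEOHOP_THRESHOLD
    chaid: CHAIDConfig = field(default_factory=CHAIDConfig)
    quartile_method: str = "tukey"
    lot_test: str = "mann_whitney"
    seed: int = 0
    log_level: str = "INFO"
    make_plot: bool = False

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_path and synthetic must be configured"
            )


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    synthetic = raw.pop("synthetic", None)
    chaid = raw.pop("chaid", None)
    cfg = PipelineConfig(
        synthetic=CohortConfig(**synthetic) if synthetic is not None else None,
        chaid=CHAIDConfig(**chaid) if chaid is not None else CHAIDConfig(),
        **raw,
    )
    return cfg


def _score_band(rec: EpisodeRecord, cutoff: float) -> str:
    score = compute_neohop(rec, crp_cutoff=cutoff)
    if score is None:
        return "missing"
    return "0" if score.total == 0 else ("1" if score.total == 1 else ">=2")


def _crp24_band(rec: EpisodeRecord, cutoff: float) -> str:
    if rec.crp_t24 is None:
        return "missing"
    return "ge_cutoff" if rec.crp_t24 >= cutoff else "lt_cutoff"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the analysis bundle; returns the manifest."""
    t_start = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name):
        t = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t, 4)
            logger.info("stage %s finished in %.3f s", name, timings[name])

        return done

    # --- load or simulate -------------------------------------------------
    done = _stage("input")
    if config.synthetic is not None:
        records, sampled_labels = generate_cohort(
            dataclasses.replace(config.synthetic, seed=config.seed)
        )
    else:
        records = read_episodes(config.input_path)
        sampled_labels = None
    if not records:
        raise PipelineError("input", "no episodes to analyse")
    invalid = [r.episode_id for r in records if not validate_episode(r).ok]
    if invalid:
        logger.warning("%d episodes fail validation: %s", len(invalid), invalid[:5])
    done()

    # --- classification ---------------------------------------------------
    done = _stage("classification")
    outcomes, n_unclassifiable = classify_cohort(records, cutoff=config.crp_cutoff)
    labels = [o.label if isinstance(o, HAIClass) else None for o in outcomes]
    truth = [o.any_hai for o in outcomes]
    done()

    # --- scoring: five candidate tests ------------------------------------
    done = _stage("scoring")
    specs = {
        name: TestSpec(
            name=name,
            crp_cutoff=config.crp_cutoff,
            neohop_threshold=config.neohop_threshold,
        )
        for name in TEST_NAMES
    }
    calls = {
        name: [test_positivity(rec, spec) for rec in records]
        for name, spec in specs.items()
    }
    done()

    # --- diagnostics (classifiable episodes only) --------------------------
    done = _stage("diagnostics")
    keep = [i for i, t in enumerate(truth) if t is not None]
    matrices = {
        name: confusion_matrix(
            [calls[name][i] for i in keep], [truth[i] for i in keep]
        )
        for name in TEST_NAMES
    }
    table = metrics_table(matrices)
    table.to_csv(out / "metrics.csv")
    (out / "metrics.json").write_text(table.to_json(indent=2) + "\n")
    done()

    # --- decision tool -----------------------------------------------------
    done = _stage("decision_tool")
    tool_outcomes, n_tool_excluded, branch_counts = apply_tool(
        records, cutoff=config.crp_cutoff
    )
    (out / "tool_summary.json").write_text(
        json.dumps(
            {
                "branch_counts": branch_counts,
                "n_not_evaluable": n_tool_excluded,
                "n_unclassifiable": n_unclassifiable,
            },
            indent=2,
        )
        + "\n"
    )
    done()

    # --- CHAID tree ---------------------------------------------------------
    done = _stage("chaid")
    features = pd.DataFrame(
        {
            "neohop_t0_band": [_score_band(r, config.crp_cutoff) for r in records],
            "crp_t24_band": [_crp24_band(r, config.crp_cutoff) for r in records],
        }
    )
    tree_keep = features.index[[t is not None for t in truth]]
    tree: CHAIDNode = grow_tree(
        features.loc[tree_keep],
        ["any_hai" if truth[i] else "no_hai" for i in tree_keep],
        config.chaid,
    )
    (out / "tree.txt").write_text(tree.to_text() + "\n")
    (out / "tree.json").write_text(tree.to_json(indent=2) + "\n")
    done()

    # --- LOT comparison -----------------------------------------------------
    done = _stage("lot")
    lot_table = lot_comparison(
        [r.observed_lot_days for r in records],
        [o.theoretical_lot_days if o is not None else None for o in tool_outcomes],
        labels,
        test=config.lot_test,
        quartile_method=config.quartile_method,
    )
    lot_table.to_csv(out / "lot_comparison.csv")
    (out / "lot_comparison.json").write_text(lot_table.to_json(indent=2) + "\n")
    if config.make_plot:
        plot_lot_comparison(lot_table, out / "lot_comparison.png")
    done()

    # --- augmented episode table -------------------------------------------
    done = _stage("augment")
    rows = []
    for i, rec in enumerate(records):
        row = record_to_row(rec)
        outcome = outcomes[i]
        if isinstance(outcome, HAIClass):
            row["hai_label"] = outcome.label
            row["any_hai"] = str(int(outcome.any_hai))
            row["rationale"] = "; ".join(outcome.rationale)
        else:
            row["hai_label"] = "unclassifiable"
            row["any_hai"] = ""
            row["rationale"] = "; ".join(outcome.conflicts)
        for name in TEST_NAMES:
            row[f"test_{name}"] = calls[name][i].value
        tool = tool_outcomes[i]
        row["recommendation"] = tool.recommendation.value if tool else "not_evaluable"
        row["theoretical_lot_days"] = (
            repr(tool.theoretical_lot_days) if tool else ""
        )
        if sampled_labels is not None:
            row["sampled_label"] = sampled_labels[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "episodes_augmented.csv", index=False)
    done()

    # --- report + manifest ---------------------------------------------------
    if sampled_labels is not None:
        report = cohort_report(records, sampled_labels)
        (out / "cohort_report.json").write_text(json.dumps(report, indent=2) + "\n")
    manifest = {
        "package": "neohai",
        "version": __version__,
        "seed": config.seed,
        "n_episodes": len(records),
        "n_unclassifiable": n_unclassifiable,
        "n_tool_not_evaluable": n_tool_excluded,
        "crp_cutoff": config.crp_cutoff,
        "neohop_threshold": config.neohop_threshold,
        "quartile_method": config.quartile_method,
        "lot_test": config.lot_test,
    }
    logger.info("pipeline finished in %.3f s", time.perf_counter() - t_start)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
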