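"""Config-driven end-to-end runs: simulate/read -> fractions -> call -> report."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .fractionation import (
    DensityCalibration,
    FractionThresholds,
    GradientFraction,
    designate_fractions,
    ri_to_density,
)
from .io import (
    read_abundance_table,
    read_fraction_metadata,
    read_sample_sheet,
    read_truth_table,
    write_abundance_table,
    write_experiment,
)
from .labelling import CallParameters, call_experiment
from .simulate import SimulationConfig, TruthTable, simulate_experiment

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "annotate_fractions"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SchemaError(ValueError):
    """Config validation failure naming the offending field."""


@dataclass
class RunConfig:
    """Validated run configuration.

    Either a ``simulate`` section (synthetic experiment) or an ``inputs``
    section (paths to abundance table + sample sheet) must be present; the
    ``caller`` section must state ``k`` and ``floor`` explicitly so a run is
    self-documenting.
    """

    params: CallParameters
    control_treatment: str | None = None
    test_treatment: str = "rhizosphere"
    simulate: SimulationConfig | None = None
    abundance_path: str | None = None
    samples_path: str | None = None
    truth_path: str | None = None
    fractions_path: str | None = None
    calibration: DensityCalibration = field(default_factory=DensityCalibration)
    thresholds: FractionThresholds = field(default_factory=FractionThresholds)
    output_dir: str = "results"
    seed: int | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        caller = raw.get("caller")
        if not isinstance(caller, dict):
            raise SchemaError("missing required section 'caller'")
        for key in ("k", "floor"):
            if key not in caller:
                raise SchemaError(f"caller section missing required field '{key}'")
        try:
            params = CallParameters(floor=float(caller["floor"]), k=float(caller["k"]))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"invalid caller parameters: {exc}") from exc

        sim_cfg = None
        if "simulate" in raw and raw["simulate"] is not None:
            sim_raw = dict(raw["simulate"])
            if "seed" not in sim_raw and raw.get("seed") is not None:
                sim_raw["seed"] = raw["seed"]
            try:
                sim_cfg = SimulationConfig(**sim_raw)
            except TypeError as exc:
                raise SchemaError(f"invalid simulate section: {exc}") from exc

        inputs = raw.get("inputs") or {}
        if sim_cfg is None and not ("abundances" in inputs and "samples" in inputs):
            raise SchemaError(
                "config needs either a 'simulate' section or inputs.abundances "
                "and inputs.samples"
            )

        fr = raw.get("fractionation") or {}
        try:
            calibration = DensityCalibration(**(fr.get("calibration") or {}))
            thresholds = FractionThresholds(**(fr.get("thresholds") or {}))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"invalid fractionation section: {exc}") from exc

        return cls(
            params=params,
            control_treatment=caller.get("control_treatment"),
            test_treatment=caller.get("test_treatment", "rhizosphere"),
            simulate=sim_cfg,
            abundance_path=inputs.get("abundances"),
            samples_path=inputs.get("samples"),
            truth_path=inputs.get("truth"),
            fractions_path=inputs.get("fractions"),
            calibration=calibration,
            thresholds=thresholds,
            output_dir=str(raw.get("output_dir", "results")),
            seed=raw.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def annotate_fractions(
    metadata: pd.DataFrame,
    calibration: DensityCalibration,
    thresholds: FractionThresholds,
) -> pd.DataFrame:
    """Add density and heavy/light/discard designation columns to a
    fraction-metadata table."""
    out = metadata.copy()
    out["density"] = [
        ri_to_density(ri, calibration) for ri in out["refractive_index"]
    ]
    designations = []
    for _, grad in out.groupby("gradient_id", sort=False):
        fracs = [
            GradientFraction(fraction_index=int(r.fraction_index), density=r.density)
            for r in grad.itertuples()
        ]
        labels = designate_fractions(fracs, thresholds)
        designations.extend(labels[int(r.fraction_index)] for r in grad.itertuples())
    out["designation"] = designations
    return out


def _status_counts(calls: pd.DataFrame) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {}
    for (treatment, timepoint), grp in calls.groupby(["treatment", "timepoint"]):
        counts[f"{treatment}/{timepoint}"] = (
            grp["final_status"].value_counts().sort_index().to_dict()
        )
    return counts


def _recovery_metrics(
    calls: pd.DataFrame, truth: TruthTable, test_treatment: str
) -> dict[str, float]:
    sub = calls[calls["treatment"] == test_treatment]
    predicted = set(sub.loc[sub["final_status"] == "labelled", "taxon_id"])
    positives = set(truth.taxa_with("labelled"))
    negatives = set(truth.status) - positives
    tp = len(predicted & positives)
    fp = len(predicted & negatives)
    return {
        "sensitivity": tp / len(positives) if positives else float("nan"),
        "specificity": (len(negatives) - fp) / len(negatives) if negatives else float("nan"),
        "n_true_labelled": len(positives),
        "n_called_labelled": len(predicted),
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured pipeline and write calls + summary to disk.

    Returns the summary dict.  On a stage failure all partial outputs written
    so far are removed and a PipelineError naming the stage is raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        stage = "inputs"
        truth = None
        if config.simulate is not None:
            experiment, truth = simulate_experiment(config.simulate)
            abundance, samples = experiment.abundance, experiment.samples
            paths = write_experiment(experiment, truth, outdir)
            written.extend(paths.values())
        else:
            abundance = read_abundance_table(config.abundance_path)
            samples = read_sample_sheet(config.samples_path)
            if config.truth_path:
                truth = read_truth_table(config.truth_path)

        stage = "fractionation"
        if config.fractions_path:
            metadata = read_fraction_metadata(config.fractions_path)
            annotated = annotate_fractions(metadata, config.calibration, config.thresholds)
            frac_out = outdir / "fractions.tsv"
            annotated.to_csv(frac_out, sep="\t", index=False)
            written.append(frac_out)

        stage = "calling"
        calls = call_experiment(
            abundance, samples, config.params, control_treatment=config.control_treatment
        )
        calls_out = outdir / "calls.tsv"
        calls.to_csv(calls_out, sep="\t", index=False)
        written.append(calls_out)

        stage = "summary"
        summary: dict[str, Any] = {
            "version": __version__,
            "parameters": {
                "floor": config.params.floor,
                "k": config.params.k,
                "control_treatment": config.control_treatment,
            },
            "seed": config.simulate.seed if config.simulate else config.seed,
            "status_counts": _status_counts(calls),
        }
        if truth is not None:
            summary.update(_recovery_metrics(calls, truth, config.test_treatment))
        summary_out = outdir / "summary.json"
        with open(summary_out, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        written.append(summary_out)
        return summary
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
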