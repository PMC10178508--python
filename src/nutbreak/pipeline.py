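"""End-to-end orchestration: configuration, seeding, manifests and stages.

A pipeline run is described by one YAML config with a mandatory global
seed.  The global seed expands to per-stage seeds through a fixed counter
scheme (stage name -> index below), so any stage can be re-run
independently and bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dataset import (
    ConfigError,
    FactorialDataset,
    ProcessCondition,
    ResponseVector,
    SplitSpec,
    read_dataset,
    write_dataset,
    RESPONSE_COLUMNS,
)
from .fixtures import (
    PRINTED_PARETO_CHANGES,
    PRINTED_RMSE_REDUCTION,
    PRINTED_VALIDATION_ERROR,
    load_table4,
    load_table5_pareto,
    load_table6,
)
from .ga import GAConfig, train_ga_ann
from .metrics import percent_change, relative_error_percent, rmse_reduction_percent
from .moo import MOOConfig, ParetoSet, run_nsga2, summarize_pareto, validate_optimum
from .network import (
    NetworkParameters,
    NetworkTopology,
    TrainingConfig,
    forward,
    topology_search,
)
from .surface import NoiseSpec, SurfaceParams, generate_dataset, generate_validation_point

#: fixed stage indices of the seed counter scheme
STAGE_INDEX = {
    "simulate": 0,
    "split": 1,
    "topology": 2,
    "ga": 3,
    "train": 4,
    "moo": 5,
    "validate": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive the per-stage seed: SeedSequence(global, stage index)."""
    ss = np.random.SeedSequence([int(global_seed), STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; exactly one data source."""

    seed: int
    output_dir: Path
    dataset_path: Path | None = None
    synthetic: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    topology: dict = field(default_factory=dict)
    ga: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    moo: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw or raw["seed"] is None:
            raise ConfigError("config must set an explicit global seed")
        data = raw.get("data", {})
        path = data.get("path")
        synthetic = data.get("synthetic")
        if (path is None) == (synthetic is None):
            raise ConfigError(
                "config must name exactly one data source: "
                "data.path or data.synthetic"
            )
        return cls(
            seed=int(raw["seed"]),
            output_dir=Path(raw.get("output_dir", "runs")),
            dataset_path=Path(path) if path else None,
            synthetic=synthetic or {},
            split=raw.get("split", {}),
            topology=raw.get("topology", {}),
            ga=raw.get("ga", {}),
            training=raw.get("training", {}),
            moo=raw.get("moo", {}),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(raw)

    def resolved(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "data": (
                {"path": str(self.dataset_path)}
                if self.dataset_path
                else {"synthetic": self.synthetic}
            ),
            "split": self.split,
            "topology": self.topology,
            "ga": self.ga,
            "training": self.training,
            "moo": self.moo,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(
    config: PipelineConfig, stage: str, outputs: dict[str, str], t0: float
) -> Path:
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "global_seed": config.seed,
        "stage_seed": stage_seed(config.seed, stage) if stage in STAGE_INDEX else None,
        "version": __version__,
        "outputs": outputs,
        "elapsed_s": round(time.perf_counter() - t0, 3),
        "resolved_config": config.resolved(),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _load_dataset(config: PipelineConfig) -> FactorialDataset:
    if config.dataset_path is not None:
        return read_dataset(config.dataset_path)
    params = SurfaceParams(**config.synthetic.get("surface", {}))
    sigma = config.synthetic.get("noise_sigma")
    noise = NoiseSpec(
        sigma=tuple(sigma) if sigma else NoiseSpec().sigma,
        seed=stage_seed(config.seed, "simulate"),
    )
    return generate_dataset(params, noise)


def cmd_simulate(config: PipelineConfig) -> Path:
    """Generate the seeded synthetic factorial dataset and write it."""
    t0 = time.perf_counter()
    if config.dataset_path is not None:
        raise ConfigError("simulate requires a synthetic data block")
    dataset = _load_dataset(config)
    out = config.output_dir / "dataset.csv"
    write_dataset(dataset, out)
    _write_manifest(config, "simulate", {"dataset": str(out)}, t0)
    return out


def cmd_train(config: PipelineConfig) -> tuple[Path, Path]:
    """Split, optionally search the topology, then train BP and GA-ANN.

    Writes the serialized GA-ANN model and an evaluation report holding
    both models' per-response scores and the RMSE reductions.
    """
    t0 = time.perf_counter()
    dataset = _load_dataset(config)
    split = SplitSpec(
        fraction=float(config.split.get("fraction", 0.8)),
        seed=stage_seed(config.seed, "split"),
    )
    topo_block = dict(config.topology)
    do_search = topo_block.pop("search", False)
    train_cfg = TrainingConfig(
        **{k: v for k, v in config.training.items()},
    )
    if do_search:
        result = topology_search(
            dataset,
            seed=stage_seed(config.seed, "topology"),
            split=split,
            config=train_cfg,
            replicates=int(topo_block.pop("replicates", 10)),
        )
        transfer, j = result.selected
        search_table = result.table
    else:
        transfer = topo_block.get("hidden_transfer", "logsig")
        j = int(topo_block.get("n_hidden", 12))
        search_table = None
    topology = NetworkTopology(n_hidden=j, hidden_transfer=transfer)

    ga_cfg = GAConfig(
        **{**config.ga, "seed": stage_seed(config.seed, "ga")},
    )
    report = train_ga_ann(dataset, topology, ga_cfg, train_cfg, split)

    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    model_path = out_dir / "model.json"
    report.ga_params.to_json(
        model_path,
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "init": "ga",
        },
    )
    eval_payload = {
        "topology": {"hidden_transfer": transfer, "n_hidden": j},
        "bp": {"r2": dict(report.bp_scores.r2), "rmse": dict(report.bp_scores.rmse)},
        "ga_ann": {"r2": dict(report.ga_scores.r2), "rmse": dict(report.ga_scores.rmse)},
        "rmse_reduction_percent": report.rmse_reduction,
    }
    eval_path = out_dir / "evaluation.json"
    eval_path.write_text(json.dumps(eval_payload, indent=2))
    if search_table is not None:
        search_table.to_csv(out_dir / "topology_search.csv", index=False)
    _write_manifest(
        config, "train", {"model": str(model_path), "evaluation": str(eval_path)}, t0
    )
    return model_path, eval_path


def cmd_optimize(
    config: PipelineConfig, model_path: str | Path, reference: int = 1
) -> tuple[Path, Path]:
    """Run the five-objective optimizer on a trained surrogate.

    Writes the Pareto set CSV (report column order, report precision) and
    a comparison report against the reference group.
    """
    t0 = time.perf_counter()
    model = NetworkParameters.from_json(model_path)
    moo_cfg = MOOConfig(**{**config.moo, "seed": stage_seed(config.seed, "moo")})
    pareto = run_nsga2(model, moo_cfg)

    frame = pareto.to_frame()
    # report precision: T one decimal, V two, MC one, responses one/two
    frame["T"] = frame["T"].round(1)
    frame["V"] = frame["V"].round(2)
    frame["MC"] = frame["MC"].round(1)
    frame["DT"] = frame["DT"].round(1)
    frame["SEC"] = frame["SEC"].round(2)
    for c in ("HR", "WR", "SR"):
        frame[c] = frame[c].round(1)
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    pareto_path = out_dir / "pareto.csv"
    frame.to_csv(pareto_path, index=False)

    report = {}
    if len(pareto) >= 1:
        reference = min(max(reference, 1), len(pareto))
        report = {
            f"group_{g}_vs_{reference}": summarize_pareto(pareto, reference, g)
            for g in range(1, len(pareto) + 1)
            if g != reference
        }
    report_path = out_dir / "pareto_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    _write_manifest(
        config, "moo", {"pareto": str(pareto_path), "report": str(report_path)}, t0
    )
    return pareto_path, report_path


def cmd_validate(
    config: PipelineConfig,
    model_path: str | Path,
    condition: ProcessCondition,
    experimental: ResponseVector | None = None,
) -> Path:
    """Predict at a condition and report relative errors against a
    validation observation (given, or drawn from the synthetic surface)."""
    t0 = time.perf_counter()
    model = NetworkParameters.from_json(model_path)
    predicted = forward(model, condition)
    if experimental is None:
        if config.dataset_path is not None:
            raise ConfigError(
                "no experimental responses given and no synthetic surface "
                "to draw a validation run from"
            )
        params = SurfaceParams(**config.synthetic.get("surface", {}))
        sigma = config.synthetic.get("noise_sigma")
        noise = NoiseSpec(
            sigma=tuple(sigma) if sigma else NoiseSpec().sigma,
            seed=stage_seed(config.seed, "validate"),
        )
        _, experimental = generate_validation_point(params, noise, condition)
    errors = validate_optimum(predicted, experimental)
    payload = {
        "condition": {"T": condition.T, "V": condition.V,
                      "MC": condition.MC, "D": condition.D},
        "predicted": dict(zip(RESPONSE_COLUMNS, predicted.as_array().tolist())),
        "experimental": dict(zip(RESPONSE_COLUMNS, experimental.as_array().tolist())),
        "relative_error_percent": errors,
    }
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "validation.json"
    path.write_text(json.dumps(payload, indent=2))
    _write_manifest(config, "validate", {"validation": str(path)}, t0)
    return path


def reproduce_tables() -> dict:
    """Recompute every derived percentage of the shipped report tables
    from their raw fixture values and compare with what was printed.

    Returns a report dict; ``report["ok"]`` is True iff every recomputed
    value equals the printed one after rounding to the printed precision.
    """
    mismatches: list[str] = []
    recomputed: dict[str, dict] = {"rmse_reduction": {}, "validation_error": {},
                                   "pareto_changes": {}}

    table4 = load_table4()
    for resp, (printed, digits) in PRINTED_RMSE_REDUCTION.items():
        value = round(
            rmse_reduction_percent(
                float(table4.loc["BP", f"{resp}_RMSE"]),
                float(table4.loc["GA-ANN", f"{resp}_RMSE"]),
            ),
            digits,
        )
        recomputed["rmse_reduction"][resp] = value
        if value != printed:
            mismatches.append(
                f"RMSE reduction {resp}: recomputed {value}, printed {printed}"
            )

    _, pred, val = load_table6()
    for k, resp in enumerate(RESPONSE_COLUMNS):
        value = round(
            relative_error_percent(pred.as_array()[k], val.as_array()[k]), 2
        )
        recomputed["validation_error"][resp] = value
        if value != PRINTED_VALIDATION_ERROR[resp]:
            mismatches.append(
                f"validation error {resp}: recomputed {value}, "
                f"printed {PRINTED_VALIDATION_ERROR[resp]}"
            )

    pareto = load_table5_pareto()
    for (cand, ref), printed_map in PRINTED_PARETO_CHANGES.items():
        summary = summarize_pareto(pareto, ref, cand)
        got = summary["percent_change"]
        recomputed["pareto_changes"][f"{cand}_vs_{ref}"] = got
        for resp, printed in printed_map.items():
            if got[resp] != printed:
                mismatches.append(
                    f"group {cand} vs {ref} {resp}: recomputed {got[resp]}, "
                    f"printed {printed}"
                )

    return {"ok": not mismatches, "mismatches": mismatches, "recomputed": recomputed}
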