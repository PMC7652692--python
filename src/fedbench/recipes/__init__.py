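"""Experiment recipes: declarative configs for full benchmark runs.

A recipe names a synthetic dataset, a partition scenario, a model family,
the training schedule and the bootstrap budget, with a mandatory top-level
seed. Bundled recipes encode each benchmark experiment (image10
CML/basic/imbalanced/skewed/combined, ICU CML/basic/imbalanced, ECG
CML/basic/imbalanced) at full benchmark scale, each with a ``mini`` override block
for desk-scale runs.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..datasets import GeneratorConfig, LabeledDataset, generate_split_pair, save_dataset_container
from ..evaluation import bootstrap_report, evaluate, write_report
from ..federation import ExperimentResult, run_experiment
from ..models import ModelSpec, TrainingConfig, WeightSet, encode_payload, predict
from ..partitioning import (
    PartitionPlan,
    partition_basic,
    partition_imbalanced_fraction,
    partition_imbalanced_random,
    partition_imbalanced_skewed,
    partition_skewed,
    save_plan,
)

__all__ = [
    "ExperimentRecipe",
    "load_recipe",
    "bundled_recipe_names",
    "build_partition",
    "run_recipe",
]


@dataclass
class ExperimentRecipe:
    name: str
    generator: GeneratorConfig
    partition: dict
    model: ModelSpec
    training: TrainingConfig
    bootstrap_K: int
    seed: int
    weighting: str = "samples"

    @classmethod
    def from_dict(cls, doc: dict, mini: bool = False) -> "ExperimentRecipe":
        doc = dict(doc)
        if "seed" not in doc:
            raise ValueError("recipe must declare a seed")
        if mini:
            overrides = doc.pop("mini", {})
            for section, values in overrides.items():
                if isinstance(values, dict):
                    doc[section] = {**doc.get(section, {}), **values}
                else:
                    doc[section] = values
        else:
            doc.pop("mini", None)
        seed = int(doc["seed"])
        gen = dict(doc["generator"])
        gen.setdefault("seed", seed)
        if "length_range" in gen and gen["length_range"] is not None:
            gen["length_range"] = tuple(gen["length_range"])
        if "class_proportions" in gen and gen["class_proportions"] is not None:
            gen["class_proportions"] = tuple(gen["class_proportions"])
        part = dict(doc["partition"])
        if part.get("scenario") not in (
            "cml",
            "basic",
            "imbalanced_random",
            "imbalanced_fraction",
            "skewed",
            "imbalanced_skewed",
        ):
            raise ValueError(f"unknown partition scenario {part.get('scenario')!r}")
        training = dict(doc.get("training", {}))
        training.setdefault("seed", seed)
        ev = dict(doc.get("evaluation", {}))
        return cls(
            name=doc["name"],
            generator=GeneratorConfig(**gen),
            partition=part,
            model=ModelSpec(**doc["model"]),
            training=TrainingConfig(**training),
            bootstrap_K=int(ev.get("K", 100)),
            seed=seed,
            weighting=doc.get("weighting", "samples"),
        )


def bundled_recipe_names() -> list[str]:
    root = resources.files("fedbench.recipes")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_recipe(name_or_path: str | Path, mini: bool = False) -> ExperimentRecipe:
    """Load a recipe from a YAML path, or by bundled name (e.g. image10_basic)."""
    path = Path(name_or_path)
    if path.exists():
        text = path.read_text()
    else:
        res = resources.files("fedbench.recipes") / f"{name_or_path}.yaml"
        if not res.is_file():
            raise FileNotFoundError(
                f"no recipe file {name_or_path!r}; bundled: {bundled_recipe_names()}"
            )
        text = res.read_text()
    return ExperimentRecipe.from_dict(yaml.safe_load(text), mini=mini)


def build_partition(recipe: ExperimentRecipe, train: LabeledDataset) -> PartitionPlan:
    p = dict(recipe.partition)
    scenario = p.pop("scenario")
    seed = p.pop("seed", recipe.seed)
    if scenario == "cml":  # centralized baseline: one client holding everything
        return partition_basic(train, 1, len(train), seed=seed)
    if scenario == "basic":
        return partition_basic(train, p["n_clients"], p["per_client"], seed=seed)
    if scenario == "imbalanced_random":
        return partition_imbalanced_random(
            train, p["n_clients"], p.get("size_min", 1), p.get("size_max", 600), seed=seed
        )
    if scenario == "imbalanced_fraction":
        return partition_imbalanced_fraction(train, p["fractions"], seed=seed)
    if scenario == "skewed":
        return partition_skewed(train, p.get("per_client"), seed=seed)
    return partition_imbalanced_skewed(
        train, p.get("size_min", 1), p.get("size_max", 600), seed=seed
    )


def run_recipe(
    recipe: ExperimentRecipe, out_dir: str | Path, recipe_source: str | Path | None = None
) -> ExperimentResult:
    """Full pipeline: generate -> partition -> federate -> evaluate.

    Writes a self-describing run directory: the recipe, the partition plan,
    per-round history CSV, final/best weights, per-client accuracies, and
    the metric report with bootstrap CIs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, test = generate_split_pair(recipe.generator)
    plan = build_partition(recipe, train)
    save_plan(plan, out / "partition.json")
    result = run_experiment(
        train,
        test,
        plan,
        recipe.model,
        recipe.training,
        weighting=recipe.weighting,
    )
    result.history.to_csv(out / "history.csv", index=False)
    result.per_client.to_csv(out / "per_client.csv", index=False)
    (out / "best_weights.json").write_bytes(encode_payload(result.best_weights.to_payload()))
    scores = predict(recipe.model, result.best_weights, test.records)
    report = evaluate(scores, test.labels, n_classes=test.n_classes)
    boots = bootstrap_report(
        scores, test.labels, recipe.bootstrap_K, seed=recipe.seed, n_classes=test.n_classes
    )
    write_report(out, report, boots)
    manifest = {
        "recipe_name": recipe.name,
        "seed": recipe.seed,
        "scenario": recipe.partition.get("scenario"),
        "model_family": recipe.model.family,
        "rounds_run": int(len(result.history)),
        "best_round": int(result.best_round),
    }
    (out / "run.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if recipe_source is not None and Path(recipe_source).exists():
        shutil.copy(recipe_source, out / "recipe.yaml")
    else:
        (out / "recipe.yaml").write_text(yaml.safe_dump(_recipe_doc(recipe)))
    return result


def _recipe_doc(recipe: ExperimentRecipe) -> dict:
    g = recipe.generator
    return {
        "name": recipe.name,
        "seed": recipe.seed,
        "generator": {
            "archetype": g.archetype,
            "n_train": g.n_train,
            "n_test": g.n_test,
            "class_proportions": list(g.proportions),
            "noise_scale": g.noise_scale,
            "label_mode": g.label_mode,
            "seed": g.seed,
        },
        "partition": recipe.partition,
        "model": {"family": recipe.model.family, "n_blocks": recipe.model.n_blocks},
        "training": {
            "local_epochs": recipe.training.local_epochs,
            "batch_size": recipe.training.batch_size,
            "max_rounds": recipe.training.max_rounds,
            "patience": recipe.training.patience,
            "seed": recipe.training.seed,
        },
        "evaluation": {"K": recipe.bootstrap_K},
        "weighting": recipe.weighting,
    }
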