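"""Reusable end-to-end experiment recipes on synthetic selection data.

These functions wire the whole pipeline together -- simulate selections,
filter records, pretrain the single-helix module, fine-tune the pair model,
and score designs against the ground-truth recognition code -- at sizes that
run on one CPU in minutes.  They back both the ``zfhelix demo`` subcommand
and the reproducibility script.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from zfhelix import b1h_io
from zfhelix.analysis import fit_pwm_mixture, selection_qc
from zfhelix.design import AStarParams, astar_design, concatenated_pwm
from zfhelix.model import ModelConfig, TrainedModel
from zfhelix.synthetic import (
    RecognitionCode,
    SimulationParams,
    default_anchor,
    ground_truth_pair_pwm,
    make_library_contexts,
    sample_code,
    sample_pair_targets,
    simulate_pair_campaign,
    simulate_single_campaign,
    simulate_single_selection,
)
from zfhelix.training import (
    TrainConfig,
    build_validation_split,
    predicted_pwm,
    pwm_mse,
    pretrain_single_module,
    reconstruction_accuracy,
    train_full_model,
)
from zfhelix.types import SelectionDataset

#: Simulation scale of the desk-size experiments: three library contexts
#: x 64 triplets for single selections, 200 random 7-mers for pair
#: selections, ~50 recovered survivors per selection.
SINGLE_PARAMS = dict(n_candidates=20_000_000, max_survivors=60)
PAIR_PARAMS = dict(n_candidates=1_500_000, max_survivors=60)
N_PAIR_TARGETS = 200
N_CONTEXTS = 3


def _filtered(datasets: list[SelectionDataset]) -> list[SelectionDataset]:
    return [
        SelectionDataset(
            target=d.target,
            records=b1h_io.basic_filter(d.records),
            context=d.context,
            library_id=d.library_id,
            metadata=d.metadata,
        )
        for d in datasets
    ]


def simulate_corpus(
    code: RecognitionCode,
    seed: int,
    n_pair_targets: int = N_PAIR_TARGETS,
    n_contexts: int = N_CONTEXTS,
) -> tuple[list[SelectionDataset], list[SelectionDataset], list[str]]:
    """Simulate and filter a full single + pair selection campaign."""
    contexts = make_library_contexts(code, n_contexts)
    singles = simulate_single_campaign(
        code, contexts, SimulationParams(seed=seed, **SINGLE_PARAMS)
    )
    targets = sample_pair_targets(seed, n_pair_targets)
    pairs = simulate_pair_campaign(
        code, targets, SimulationParams(seed=seed, **PAIR_PARAMS)
    )
    return _filtered(singles), _filtered(pairs), targets


def toy_train_configs(seed: int, fast: bool = False) -> tuple[ModelConfig, TrainConfig, TrainConfig]:
    """(model config, pretrain config, pair config) for desk-size training."""
    model_cfg = ModelConfig.toy(dropout=0.1)
    pre_cfg = TrainConfig(
        learning_rate=3e-3, batch_size=512, max_epochs=15 if fast else 30,
        patience=8, seed=seed,
    )
    pair_cfg = TrainConfig(
        learning_rate=3e-3, batch_size=512, max_epochs=18 if fast else 35,
        patience=8, seed=seed, init_mode="transfer",
    )
    return model_cfg, pre_cfg, pair_cfg


def hierarchy_experiment(
    seed: int,
    context_strength: float,
    n_eval_targets: int = 5,
    pair_seed: int | None = None,
    pretrained: TrainedModel | None = None,
    fast: bool = False,
) -> dict:
    """Train the full hierarchical model and the concatenated single-module
    baseline on one synthetic code and compare predicted-PWM error on
    held-out pair targets.

    Returns per-target mean squared errors of both predictors against the
    exact ground-truth pair PWMs, and the trained models' metadata.
    ``pair_seed`` varies only the pair-campaign simulation and fine-tuning
    (for seed-to-seed noise estimates without re-pretraining).
    """
    code = sample_code(seed, context_strength)
    model_cfg, pre_cfg, pair_cfg = toy_train_configs(seed, fast=fast)
    contexts = make_library_contexts(code, N_CONTEXTS)
    if pretrained is None:
        singles = _filtered(
            simulate_single_campaign(
                code, contexts, SimulationParams(seed=seed, **SINGLE_PARAMS)
            )
        )
        pretrained = pretrain_single_module(singles, model_cfg, pre_cfg)
    pseed = seed if pair_seed is None else pair_seed
    targets = sample_pair_targets(pseed, N_PAIR_TARGETS)
    pairs = _filtered(
        simulate_pair_campaign(
            code, targets, SimulationParams(seed=pseed, **PAIR_PARAMS)
        )
    )
    pair_cfg = replace(pair_cfg, seed=pseed)
    full = train_full_model(pairs, model_cfg, pair_cfg, pretrained=(pretrained, pretrained))

    split = build_validation_split(targets)
    eval_targets = list(split.validation)[:n_eval_targets]
    anchor = default_anchor(code)
    rows = []
    for target in eval_targets:
        truth = ground_truth_pair_pwm(code, target, anchor)
        full_pwm = predicted_pwm(full, target, n_samples=300, seed=seed + 101)
        base_pwm = concatenated_pwm(
            (pretrained, pretrained), target, n_samples=300, seed=seed + 101
        )
        rows.append(
            {
                "target": target,
                "full_mse": pwm_mse(full_pwm, truth),
                "baseline_mse": pwm_mse(base_pwm, truth),
            }
        )
    gaps = [r["full_mse"] - r["baseline_mse"] for r in rows]
    return {
        "context_strength": context_strength,
        "seed": seed,
        "pair_seed": pseed,
        "targets": rows,
        "wins": int(sum(g < 0 for g in gaps)),
        "n_targets": len(rows),
        "median_gap": float(np.median(gaps)),
        "gap_std": float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0,
        "single_val_loss": pretrained.metadata["best_val_loss"],
        "pair_val_loss": full.metadata["best_val_loss"],
        "models": (pretrained, full),
    }


def deterministic_pretrain_experiment(seed: int, max_epochs: int = 400) -> dict:
    """Pretrain on a deterministic recognition code (very high stringency,
    no escapees): held-out reconstruction accuracy should approach 1."""
    from zfhelix.synthetic import sample_deterministic_code

    code = sample_deterministic_code(seed)
    contexts = make_library_contexts(code, 2)
    params = SimulationParams(
        seed=seed, n_candidates=500_000_000, escapee_rate=0.0, max_survivors=30
    )
    singles = _filtered(simulate_single_campaign(code, contexts, params))
    model_cfg = ModelConfig.toy()
    cfg = TrainConfig(
        learning_rate=3e-3, batch_size=128, max_epochs=max_epochs, patience=40,
        seed=seed,
    )
    module = pretrain_single_module(singles, model_cfg, cfg)
    # held-out masked positions: the by-helix validation split used in training
    from zfhelix.training import evaluate_masked, examples_from_datasets, split_examples

    examples = examples_from_datasets(singles)
    _, val = split_examples(examples, axis="by_helix", seed=seed)
    _, val_acc = evaluate_masked(module.network, val, 0.5, seed)
    return {
        "n_examples": len(examples),
        "n_validation": len(val),
        "validation_accuracy": float(val_acc),
        "module": module,
    }


def untrained_accuracy_experiment(seed: int, n_positions: int = 10_000) -> dict:
    """Reconstruction accuracy of an untrained model on uniform random
    helices: chance level 1/20 within binomial error."""
    rng = np.random.default_rng(seed)
    model_cfg = ModelConfig.toy()
    from zfhelix.model import SingleHelixModule
    from zfhelix.types import AMINO_ACIDS, BASES

    network = SingleHelixModule(model_cfg, np.random.default_rng(seed))
    untrained = TrainedModel(network=network, config=model_cfg)
    n_examples = int(np.ceil(n_positions / 3))  # 3 masked positions each
    examples = [
        (
            "".join(rng.choice(list(BASES), 4)),
            "".join(rng.choice(list(AMINO_ACIDS), 6)),
        )
        for _ in range(n_examples)
    ]
    acc = reconstruction_accuracy(untrained, examples, mask_fraction=0.5, seed=seed)
    return {
        "accuracy": float(acc),
        "n_masked_positions": n_examples * 3,
        "chance": 0.05,
    }


def run_end_to_end_demo(seed: int, outdir: str | Path, scale: str = "tiny") -> dict:
    """Simulate -> filter -> cluster/QC -> pretrain -> fine-tune -> design ->
    specificity, on toy scale; writes a metrics report.

    ``tiny`` runs in roughly a minute with reduced sizes; ``small`` uses the
    full desk-size conditions of :func:`hierarchy_experiment`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "scale": scale}

    code = sample_code(seed, 2.0)
    contexts = make_library_contexts(code, 2)
    params = SimulationParams(seed=seed, n_candidates=20_000_000, max_survivors=40)
    dataset = _filtered(
        [
            simulate_single_selection(
                code, contexts[0], contexts[0].overlap_base + "GCT", params
            )
        ]
    )[0]
    b1h_io.write_dataset(dataset, outdir / "selection.tsv")
    report["selection_records"] = len(dataset)

    cluster_model = fit_pwm_mixture(
        dataset.sequences(), read_weights=dataset.read_weights(),
        k=min(2, len(set(dataset.sequences()))), seed=seed, n_restarts=5,
    )
    qc = selection_qc(cluster_model)
    report["qc_passed"] = qc.passed
    report["max_information_content_bits"] = round(qc.max_information_content, 3)

    if scale == "tiny":
        exp = hierarchy_experiment(seed, 2.0, n_eval_targets=3, fast=True)
    else:
        exp = hierarchy_experiment(seed, 2.0)
    report["hierarchy_strength2"] = {
        "wins": exp["wins"],
        "n_targets": exp["n_targets"],
        "median_gap": exp["median_gap"],
    }
    single_mod, full = exp.pop("models")

    target = exp["targets"][0]["target"]
    design_result = astar_design(full, target, AStarParams(n_complete=3))
    report["astar_designs"] = [
        {"pair": str(p), "log_prob": round(c.log_prob, 4)}
        for p, c in zip(design_result.helix_pairs(), design_result.sequences)
    ]

    from zfhelix.design import specificity_profile

    if design_result.sequences:
        profile = specificity_profile(full, design_result.helix_pairs()[0])
        report["specificity_argmax"] = profile.argmax_target
        report["specificity_sum"] = float(profile.probabilities.sum())
        report["designed_for"] = target

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
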