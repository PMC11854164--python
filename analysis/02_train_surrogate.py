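#!/usr/bin/env python
"""Train the 3-10-1 backpropagation surrogate on the 17-run dataset.

Trains across a small pool of initialization seeds, keeps the net with the
lowest validation MSE, and reports the per-subset regression statistics and
error histogram.  Writes results/bp_net.json and results/bp_training.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from yieldsurf.neural import (
    TrainConfig,
    error_histogram,
    forward,
    regression_report,
    save_params,
    split_dataset,
    train,
)
from yieldsurf.synthdata import load_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seeds", type=int, default=10, help="initialization pool size")
    args = parser.parse_args()

    OUT.mkdir(exist_ok=True)
    data = load_fixture("bbd17").dataset
    obs = data.observed()
    # select the restart by pooled train+validation MSE (raw units); the
    # 3-point validation MSE alone is too noisy to rank restarts reliably
    best = None
    for seed in range(1, args.seeds + 1):
        cfg = TrainConfig(seed=seed)
        params, hist = train(data, cfg)
        tr, va, _ = split_dataset(len(obs), cfg.split_fractions, cfg.seed)
        sel = np.concatenate([tr, va])
        preds = np.asarray(forward(params, obs.actual_matrix[sel]))
        fit_mse = float(np.mean((preds - obs.yields[sel]) ** 2))
        if best is None or fit_mse < best[2]:
            best = (params, cfg, fit_mse, hist, seed)
    params, cfg, fit_mse, hist, seed = best
    print(f"Best of {args.seeds} restarts: seed {seed}, best epoch {hist.best_epoch}, "
          f"train+validation MSE {fit_mse:.2f} (%-yield units), "
          f"stop: {hist.stop_reason.value}")

    splits = split_dataset(len(data.observed()), cfg.split_fractions, cfg.seed)
    report = regression_report(params, data, splits)
    for subset, entry in report.items():
        r = "n/a" if entry["r"] is None else f"{entry['r']:.4f}"
        print(f"  {subset:>10}: R = {r} (n = {entry['n']})")

    preds = np.asarray(forward(params, obs.actual_matrix))
    edges, counts = error_histogram(params, data)
    print(f"Prediction errors span [{(obs.yields - preds).min():.2f}, "
          f"{(obs.yields - preds).max():.2f}] % yield over {counts.sum()} runs")

    save_params(params, OUT / "bp_net.json", cfg)
    (OUT / "bp_training.json").write_text(json.dumps({
        "seed": seed,
        "best_epoch": hist.best_epoch,
        "stop_reason": hist.stop_reason.value,
        "train_val_mse": fit_mse,
        "regression": report,
        "error_hist_edges": edges.tolist(),
        "error_hist_counts": counts.tolist(),
    }, indent=1) + "\n")


if __name__ == "__main__":
    main()
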