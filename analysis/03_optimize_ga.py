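#!/usr/bin/env python
"""Genetic-algorithm search for the yield-maximizing extraction conditions.

Runs the GA twice: over the trained neural surrogate (the GA-BP pipeline)
and over the fitted quadratic, where a dense-grid oracle verifies the GA.
Writes results/ga_optimum.json and results/ga_trace.csv.
"""

import argparse
import json
from pathlib import Path

from yieldsurf.design import code
from yieldsurf.ga import GAConfig, ga_bp_pipeline, run_ga, write_trace
from yieldsurf.neural import TrainConfig
from yieldsurf.rsm import fit_quadratic, optimize_surface, predict
from yieldsurf.synthdata import load_fixture

OUT = Path(__file__).resolve().parents[1] / "results"
BOX = ((4.0, 6.0), (1.5, 4.5), (40.0, 80.0))


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    data = load_fixture("bbd17").dataset
    ga_cfg = GAConfig(bounds=BOX, generations=600, seed=args.seed)

    # pick the surrogate restart by pooled train+validation MSE, as in the
    # training stage, so the GA searches the best available surrogate
    import numpy as np

    from yieldsurf.neural import forward, split_dataset, train

    obs = data.observed()
    best_seed, best_mse = None, None
    for seed in range(1, 11):
        p, _ = train(data, TrainConfig(seed=seed))
        tr, va, _ = split_dataset(len(obs), seed=seed)
        sel = np.concatenate([tr, va])
        mse = float(np.mean((np.asarray(forward(p, obs.actual_matrix[sel])) - obs.yields[sel]) ** 2))
        if best_mse is None or mse < best_mse:
            best_seed, best_mse = seed, mse

    params, hist, result = ga_bp_pipeline(data, TrainConfig(seed=best_seed), ga_cfg)
    pH, enz, t = result.best_point
    print(f"GA over BP surrogate (600 generations): pH {pH:.3f}, enzyme {enz:.3f} %, "
          f"time {t:.2f} min -> predicted yield {result.best_fitness:.2f} %")
    write_trace(result, OUT / "ga_trace.csv")

    model = fit_quadratic(data)
    fitness = lambda x: float(predict(model, code(x, data.factors)))
    quad_result = run_ga(fitness, ga_cfg)
    oracle = optimize_surface(model)
    gap = abs(quad_result.best_fitness - oracle.value)
    print(f"GA over fitted quadratic: best {quad_result.best_fitness:.3f} % vs "
          f"analytic/grid optimum {oracle.value:.3f} % (gap {gap:.4f})")

    (OUT / "ga_optimum.json").write_text(json.dumps({
        "ga_bp": {
            "point": [round(v, 4) for v in result.best_point],
            "predicted_yield": round(result.best_fitness, 3),
            "generations": len(result.trace),
        },
        "ga_on_quadratic": {
            "point": [round(v, 4) for v in quad_result.best_point],
            "predicted_yield": round(quad_result.best_fitness, 4),
            "oracle_value": round(oracle.value, 4),
            "gap": round(gap, 5),
        },
    }, indent=1) + "\n")


if __name__ == "__main__":
    main()
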