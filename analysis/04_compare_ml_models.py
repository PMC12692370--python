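"""Benchmark tree-ensemble regressors against the statistical models.

Trains whichever of RandomForest / LightGBM / XGBoost / CatBoost is
installed on the same development design and raw-dollar outcome, scores with
the identical metric panel, and optionally sweeps numeric hyperparameters by
+/-10%.  Writes results/ml_panel.tsv.
"""

import pathlib
import sys

import casemix as cm

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0, n: int = 20_000, perturb: float | None = 0.1) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = cm.RunConfig(cohort_spec=cm.CohortSpec(n_patients=n, seed=seed),
                       split_seed=seed,
                       ml_params={"iterations": 1000, "learning_rate": 0.1,
                                  "depth": 6, "seed": seed})
    rep = cm.run_ml_comparison(cfg, perturb=perturb)
    rep.panel.write(OUT / "ml_panel.tsv")
    print(rep.panel.table.round(4).to_string(index=False))
    print("\nchosen hyperparameter variants:")
    for model, info in rep.extras["hyperparameters"].items():
        print(f"  {model}: scale {info['variant_scale']}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
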