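#!/usr/bin/env python
"""5-fold cross-validation of the fitted spatial model.

Each fold refits the full model on the remaining folds and predicts the
held-out clusters' prevalence; metrics are Pearson correlation, RMSE, MAE
and percentage bias against the held-out empirical proportions y/m.

Writes results/cv.json.
"""

import json
from pathlib import Path

from atlas import InferenceConfig, cross_validate, default_priors, read_clusters

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cl = read_clusters(ROOT / "study" / "clusters.csv")
    selected = (ROOT / "selection" / "selected.txt").read_text().split()
    cfg = InferenceConfig(seed=42, n_iter=2000, burn_in=600, thin=2)
    res = cross_validate(cl, selected, default_priors(200.0), k=5, config=cfg)
    with open(ROOT / "cv.json", "w") as fh:
        json.dump(res.to_dict(), fh, indent=2, sort_keys=True)

    print("per-fold metrics:")
    for f in res.per_fold:
        print(f"  fold {f['fold']}: n={f['n_test']}, rho={f['rho']:.3f}, "
              f"rmse={f['rmse']:.4f}, mae={f['mae']:.4f}, bias={f['pct_bias']:.2f}%")
    p = res.pooled
    print(f"pooled: rho={p['rho']:.3f}, rmse={p['rmse']:.4f}, mae={p['mae']:.4f}, "
          f"pct_bias={p['pct_bias']:.2f}%")


if __name__ == "__main__":
    main()
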