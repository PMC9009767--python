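"""Generate the synthetic stimulus suites and summarise their statistics.

Builds the parametric-difficulty discrimination suite (real vs k-image
averages) and the category set used for backbone pre-training, then
writes a per-level summary table: class balance, mean pixel contrast of
each class, and centroid separation. The contrast column makes the
difficulty manipulation visible before any model is involved: the
average class drifts away from the real-image contrast distribution as
k grows.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gainsweep.pipeline import desk_profile, stage_seed
from gainsweep.images import build_difficulty_suite, generate_category_dataset

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 0) -> None:
    cfg = desk_profile(seed=seed)
    suite = build_difficulty_suite(
        cfg.levels, cfg.n_per_split, seed=stage_seed(cfg.seed, "suite"),
        style_params=cfg.style(),
    )
    rows = []
    for level, splits in suite.items():
        for split, ds in splits.items():
            real = ds.images[ds.labels == 1]
            avg = ds.images[ds.labels == 0]
            rows.append(
                {
                    "level": level,
                    "split": split,
                    "n": len(ds),
                    "balance": float(ds.labels.mean()),
                    "real_contrast": float(real.reshape(len(real), -1).std(axis=1).mean()),
                    "avg_contrast": float(avg.reshape(len(avg), -1).std(axis=1).mean()),
                    "centroid_distance": float(
                        np.linalg.norm(real.mean(axis=0) - avg.mean(axis=0))
                    ),
                }
            )
    df = pd.DataFrame(rows).sort_values(["level", "split"])
    df.to_csv(OUT / "stimulus_summary.csv", index=False)
    print(df.to_string(index=False))

    cats = generate_category_dataset(
        cfg.pretrain_categories, cfg.pretrain_per_category,
        seed=stage_seed(cfg.seed, "categories"), style_params=cfg.style(),
    )
    print(f"\ncategory set: {len(cats)} images, "
          f"{cfg.pretrain_categories} balanced categories")
    print(f"wrote {OUT / 'stimulus_summary.csv'}")


if __name__ == "__main__":
    import sys

    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
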