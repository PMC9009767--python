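"""Gain profiles for a response-complexity difficulty manipulation.

Difficulty here is the number of answer options (2 / 4 / 8 categories)
rather than perceptual degradation. Heads are fine-tuned per option
subset (resampled subsets for sizes below the full set) and scored by
one-vs-rest AUC across the gain grid. The contrast with the perceptual
manipulation is the point: response complexity changes overall AUC but
is not expected to shift the peak gain state systematically.
"""

from pathlib import Path

from gainsweep.pipeline import desk_profile, run_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "answer_options"


def main(seed: int = 0) -> None:
    cfg = desk_profile(seed=seed)
    tables = run_experiment("answer_options", cfg, OUT)
    print(tables["peaks"].to_string(index=False))
    prof = tables["profile"]
    at_one = prof[prof.delta == 1.0].groupby("condition")["value"].mean()
    print("\nAUC at neutral gain by option count:")
    print(at_one.round(3).to_string())
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    import sys

    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
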