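"""Block-wise decodable information and activation across gain states.

For every difficulty level and gain state, logistic probes read the
real-vs-average label from each block's tap activations; mean
activation is recorded alongside. Summaries: the gain state of best
decoding per (block, difficulty) with ceiling conditions excluded, the
per-block average peak across difficulties, and the most informative
block per (difficulty, gain) with first/last tie reporting.
"""

from pathlib import Path

from gainsweep.pipeline import desk_profile, run_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "decoding"


def main(seed: int = 0) -> None:
    tables = run_experiment("decoding", desk_profile(seed=seed), OUT)
    print("peak decoding gain per block (averaged over difficulties):")
    print(tables["peaks_per_block"].to_string(index=False))
    print("\nmost informative block per (level, gain):")
    print(tables["informative_blocks"].to_string(index=False))
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    import sys

    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
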