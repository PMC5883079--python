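"""Full-scale input-noise point (long-running; hours on one CPU).

Reproduces the headline pixel-noise measurement at production scale:
a 101x101 torus (N = 10,201) with m = 21 (M = 440), movies of Q = 250
frames recorded by discrete gradient descent, and start frames corrupted by
exactly 500 flipped pixels (f = 500/10201 ~ 0.049).  At this operating
point roughly 20% of retrieval attempts fail to heal the input noise and
corrupt the movie; the rest converge back to the recorded loop within a few
frames.

Usage:
    python scripts/full_scale_pixel_noise.py --seed 1 --movies 10 \
        --trials-per-movie 100 --out results/full_scale_pixel_noise.json

Reduce --movies / --trials-per-movie for a shorter (noisier) run.
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

from crossnet_astm import RecorderParams, build_grid
from crossnet_astm.experiments import pixel_noise_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, required=True)
    ap.add_argument("--movies", type=int, default=10)
    ap.add_argument("--trials-per-movie", type=int, default=100)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()

    grid = build_grid(101, 101, 21)  # N = 10,201, M = 440
    f = 500 / grid.N
    t0 = time.time()
    sweep = pixel_noise_experiment(
        grid,
        RecorderParams(rule="dgd"),
        Q=250,
        f_values=[f],
        movies=args.movies,
        trials_per_movie=args.trials_per_movie,
        seed=args.seed,
    )
    _, res = sweep[0]
    payload = {
        "corruption_probability": res.p,
        "stderr": res.standard_error,
        "trials": res.trials,
        "f": f,
        "flipped_pixels": 500,
        "N": grid.N,
        "M": grid.M,
        "Q": 250,
        "runtime_s": round(time.time() - t0, 1),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2) + "\n")
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
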