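#!/usr/bin/env python
"""Echo-lag recovery check.

For each of ten independently generated sync pairs, builds the artificial
condition (person B = exact 50-frame-lagged echo of person A's isolated
series), runs the best WCLC configuration and records the lag of the
longest identified synchronization interval.  Writes
results/lag_recovery.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from dyadsync import (
    AnalysisConfig,
    GeneratorParams,
    SmoothingSpec,
    TransformSpec,
    generate_base_pair,
    identify_msi,
    make_artificial,
    make_isolated,
)
from dyadsync._seeds import derive_seed

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-pairs", type=int, default=10)
    args = parser.parse_args()

    params = GeneratorParams()
    config = AnalysisConfig(
        method="WCLC",
        transform=TransformSpec("log1p"),
        smoothing=SmoothingSpec("none"),
        bandwidth=125,
        r2_cutoff=0.25,
    )
    rows = []
    for k in range(args.n_pairs):
        seed = derive_seed(args.seed, "pair", k)
        embedded, ref = generate_base_pair(params, sync=True, seed=seed)
        artificial = make_artificial(make_isolated(embedded), lag=params.echo_lag)
        intervals = identify_msi(artificial, config, master_seed=seed)
        longest = max(intervals, key=lambda iv: iv.duration) if intervals else None
        rows.append(
            {
                "pair": k,
                "n_frames": artificial.n_frames,
                "ref_start": ref.start,
                "ref_end": ref.end,
                "n_intervals": len(intervals),
                "recovered_lag": longest.lag if longest else float("nan"),
                "mean_r2": longest.mean_r2 if longest else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "lag_recovery.csv", index=False)

    hits = (table["recovered_lag"] - params.echo_lag).abs() <= config.step
    print(table.to_string(index=False))
    print(
        f"\nconstruction lag {params.echo_lag} recovered within one lag-grid "
        f"step for {int(hits.sum())}/{len(table)} pairs"
    )


if __name__ == "__main__":
    main()
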