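"""Run the whole pipeline (simulate -> QC -> BIP -> HBM -> stats) in one go.

Thin wrapper over :func:`presaccsf.pipeline.run_pipeline`; the numbered
scripts run the same stages individually from persisted artifacts.

Usage: python analysis/00_run_all.py [--seed 1] [--outdir results/run] [--scale 1.0]
"""

import argparse
import time
from pathlib import Path

from presaccsf.pipeline import PipelineOptions, run_pipeline
from presaccsf.synth import ExperimentConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    ap.add_argument("--scale", type=float, default=1.0)
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()

    cfg = ExperimentConfig(
        n_participants=max(2, int(round(12 * args.scale))),
        trials_per_individual=max(20, int(round(300 * args.scale))),
    )
    opts = PipelineOptions(experiment=cfg, n_perm=args.n_perm)
    t0 = time.time()
    manifest = run_pipeline(args.outdir, seed=args.seed, opts=opts)
    print(f"pipeline finished in {time.time() - t0:.0f}s -> {args.outdir}")
    print("HBM:", manifest["hbm"])


if __name__ == "__main__":
    main()
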