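"""Summarise eye-movement quality control and saccade parameters.

Reads ``trials.csv`` from a run directory, reports the trial-inclusion
accounting (how many trials each exclusion rule caught) and the
per-direction saccade parameters (latency, amplitude, landing precision)
over included saccade trials; writes ``saccade_summary.csv``.

Usage: python analysis/02_saccade_qc.py [--outdir results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from presaccsf.pipeline import stage_saccades


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    trials = pd.read_csv(args.outdir / "trials.csv")
    n_inc = int((trials["qc_status"] == "included").sum())
    print(f"{n_inc} of {len(trials)} presented trials included")
    print(trials["qc_status"].value_counts().to_string())
    path = stage_saccades(args.outdir)
    print(f"\nper-direction saccade parameters -> {path}")
    print(pd.read_csv(path).to_string(index=False))


if __name__ == "__main__":
    main()
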