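"""First fitting stage: independent grid-Bayes (BIP) fit per individual.

Each of the 72 individual units is fit independently on the CSF parameter
grid with a uniform prior; the across-individual averages of the posterior
means and SDs, the between-individual covariance of the means, and the mean
within-individual covariance are saved — they become the hierarchical
model's prior. Writes ``bip_fits.csv`` and ``bip_summary.json``.

Usage: python analysis/03_fit_bip.py [--outdir results/run]
"""

import argparse
import time
from pathlib import Path

import numpy as np

from presaccsf.bip import BIPSummary
from presaccsf.pipeline import PipelineOptions, stage_bip


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    t0 = time.time()
    path = stage_bip(args.outdir, PipelineOptions())
    summary = BIPSummary.from_json(path)
    print(f"fit {summary.n_individuals} individuals in {time.time() - t0:.0f}s -> {path}")
    with np.printoptions(precision=3, suppress=True):
        print("population mean of BIP posterior means (mu0):", summary.mu0)
        print("population mean of BIP posterior SDs (sigma0):", summary.sigma0)
        print("between-individual covariance Sigma_BIP:\n", summary.sigma_bip)
        print("mean within-individual covariance phi_BIP:\n", summary.phi_bip)


if __name__ == "__main__":
    main()
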