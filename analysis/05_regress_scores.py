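#!/usr/bin/env python
"""Relate shape modes to canal geometry.

Simple OLS of each specimen-level geometric feature on each retained PC
score; writes the full regression table and prints the R² matrix, showing
which anatomical quantity each mode encodes.
"""

import argparse
from pathlib import Path

import pandas as pd

from canalshape.cli_app import regress


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run-dir", type=Path, default=Path("results/cohort_run"))
    args = ap.parse_args()
    regress(args.run_dir)
    table = pd.read_csv(args.run_dir / "regression.csv")
    r2 = table.pivot(index="feature", columns="pc", values="r2")
    print("\nR² of feature-on-score regressions:")
    print(r2.round(3).to_string())
    best = table.loc[table["r2"].idxmax()]
    print(f"\nStrongest association: {best['feature']} ~ {best['pc']} "
          f"(R² = {best['r2']:.2f}, slope CI [{best['ci_lo']:.3g}, "
          f"{best['ci_hi']:.3g}])")


if __name__ == "__main__":
    main()
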