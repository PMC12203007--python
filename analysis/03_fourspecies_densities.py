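#!/usr/bin/env python
"""Pairwise coalescence-time densities on the four-species phylogeny.

Writes the exact between-species coalescence densities (t_ab, t_ac, t_bc)
for the pulse models A/B and migration models C/D including directional
variants, plus the mis-assignment demonstration: fitting the sister-lineage
migration model (D) to the nonsister model's (C) densities forces t_ab and
t_ac to coincide even though they differ sharply in the truth.
"""

import argparse
import json
import warnings
from pathlib import Path

from mscflow import ExperimentDesign, report, run_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/03_densities"))
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    dens = ExperimentDesign(name="fourspecies_density",
                            outdir=args.out / "densities", seed=args.seed)
    run_experiment(dens)
    report(dens, plot=args.plot)
    print(f"density tables under {dens.outdir}")

    demo = ExperimentDesign(name="misassignment_demo",
                            outdir=args.out / "misassignment",
                            seed=args.seed)
    run_experiment(demo)
    doc = json.loads((demo.outdir / "cells" /
                      "modelC_fit_by_modelD.json").read_text())
    print("mis-assignment demo (model C truth, model D fit):")
    print(f"  fitted tauS = {doc['tauS']:.5f} (true 0.006), "
          f"tauT = {doc['tauT']:.5f} (true 0.002)")
    print(f"  L1 distance between t_ab and t_ac densities: "
          f"true {doc['true_ab_ac_l1']:.3f} vs fitted "
          f"{doc['fitted_ab_ac_l1']:.3f} (the sister-lineage model cannot "
          f"separate them)")


if __name__ == "__main__":
    main()
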