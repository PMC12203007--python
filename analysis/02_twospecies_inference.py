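#!/usr/bin/env python
"""Bayesian inference on pulse-introgression data under migration models.

Simulates two-species difference-count data from the base pulse model
(phi = 0.2) and fits IM, IIM and SC by MCMC, summarizing posterior means
and 95% HPD intervals.  The expected signature: the IIM fit recovers the
most gene flow, the IM and SC fits much less.
"""

import argparse
import warnings
from pathlib import Path

from mscflow import ExperimentDesign, report, run_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/02_inference"))
    ap.add_argument("--loci", type=int, default=2000)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    design = ExperimentDesign(
        name="twospecies_sim", outdir=args.out, seed=args.seed,
        options=dict(phi=0.2, loci=args.loci, sites=1000))
    run_experiment(design)
    tab = report(design)

    m_rows = tab[tab.param == "M"].set_index("family")
    print("posterior mean migration rate M (true pulse phi = 0.2):")
    for fam, r in m_rows.iterrows():
        print(f"  {fam:>4}: {r['mean']:.3f}  (95% HPD {r.hpd_lo:.3f}-"
              f"{r.hpd_hi:.3f})")
    best = m_rows["mean"].idxmax()
    print(f"largest recovered gene flow: {best} "
          f"(pulse data favor a migration window that ends before the "
          f"present)")
    print(f"wrote {args.out / 'report.tsv'}")


if __name__ == "__main__":
    main()
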