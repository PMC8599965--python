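#!/usr/bin/env python
"""Group statistics on the state metrics.

PCA of fractional occupancy (Kaiser retention), permutation GLM of the
component scores on group with age/sex/motion as nuisance (max-statistic
FWE correction), orientation of the discriminating component so the case
group is more negative, and its covariate-adjusted correlation with the
severity score among cases.
"""

import json
from pathlib import Path

import pandas as pd

from pspdyn.pipeline import RunConfig, run_pipeline

CONFIG = Path(__file__).parent / "cohort_config.json"


def main() -> None:
    cfg = RunConfig.from_json(CONFIG)
    man = run_pipeline(cfg)
    out = Path(cfg.outdir)
    summary = json.loads((out / "stats_summary.json").read_text())
    stats = pd.read_csv(out / "group_stats.tsv", sep="\t")
    print(stats.to_string(index=False))
    ev = summary["eigenvalues"]
    kept = summary["n_retained"]
    var_pct = 100 * sum(summary["variance_explained"])
    print(f"\n{kept} components with eigenvalue > 1 explain {var_pct:.0f}% of FO variance "
          f"(eigenvalues: {', '.join(f'{e:.2f}' for e in ev)})")
    print(f"discriminating component: {summary['discriminating_component']} "
          f"(group FWE p = {summary['group_p_fwe']:.4f})")
    print(f"within-case severity correlation: r = {summary['severity_r']:.2f} "
          f"(t = {summary['severity_t']:.2f}, p = {summary['severity_p']:.4f})")
    if man.warnings:
        print("warnings:", "; ".join(man.warnings))


if __name__ == "__main__":
    main()
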