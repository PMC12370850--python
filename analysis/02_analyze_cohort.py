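"""Run the full paired-condition analysis on the simulated cohort.

Reads ``scratch/cohort/`` (written by 01_simulate_cohort.py) and writes the
report tables to ``results/report/``: the paired-comparison table of global
endpoints, BH-FDR-corrected sensor topographies, permutation-corrected ROI
band-power and connectivity contrasts, and index-vs-map correlation tables.
Prints the headline endpoint comparisons.
"""

from pathlib import Path

import pandas as pd

from eegecg.pipeline import RunConfig, run

ROOT = Path(__file__).resolve().parents[1]
IN, OUT = ROOT / "scratch" / "cohort", ROOT / "results" / "report"

if __name__ == "__main__":
    cfg = RunConfig(mode="files", in_dir=str(IN), out_dir=str(OUT), seed=7, n_perm=1000)
    bundle = run(cfg)
    pd.set_option("display.width", 160)
    cols = ["measure", "method", "statistic", "p", "effect", "effect_label", "tier"]
    print(bundle.table1[cols].round(4).to_string(index=False))
    sig = bundle.table1[bundle.table1.tier != "ns"]
    print(f"\n{len(sig)} of {len(bundle.table1)} endpoints significant or trend-level.")
    print(
        "note: this driver runs a scaled cohort; effects sized near d = 0.4-0.5 "
        "need n = 32-34 for 80% power (see scripts/acceptance.py for the full "
        "design point)."
    )
    print(f"report tables written to {OUT}")
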