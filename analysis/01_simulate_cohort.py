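"""Simulate the study cohort: 32 active-caries and 13 caries-free subjects.

Each subject contributes 5 substrates x 4 inhibitor groups of saliva wells
(1:20 dilution); a subset of caries subjects adds matched biopsy wells
(1:750). Per-subject activities are lognormal around the group means, with
the caries group elevated on PepE and carrying an MMP-enriched class
profile. Writes the plate time series, layout and generative truth table.
"""

import runpy
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = runpy.run_path(Path(__file__).parent / "00_common.py")

import pandas as pd  # noqa: E402

from pepfinger.pipeline import run  # noqa: E402

manifest = run(common["CONFIG"], stages=["simulate"])
truth = pd.read_csv(common["RESULTS"] / "truth.csv")
sal = truth[truth["specimen"] == "saliva"]

print(f"simulated {manifest['stages']['simulate']['wells']} wells "
      f"for {manifest['stages']['simulate']['subjects']} subjects "
      f"(seed {common['SEED']})")
for label, grp in sal.groupby("label"):
    print(f"  {label:8s} n={len(grp):2d}  mean generative PepE Vmax "
          f"{grp['PepE_vmax_target'].mean():7.1f} a.u./min")
n_biopsy = (truth["specimen"] == "biopsy").sum()
print(f"  matched biopsies: {n_biopsy}")
print(f"artifacts -> {common['RESULTS']}")
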