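"""Deconvolve effective MMP activities from per-substrate cleavage rates.

Class-constrained inference: metallo activity is fitted to the
(uninhibited - MMPi) rate differentials against the bundled MMP-2/-8/-9
specificity matrix; the BOTHi-surviving rate per substrate is the
unattributed residual (proteases outside both inhibitor spectra).
"""

import runpy
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = runpy.run_path(Path(__file__).parent / "00_common.py")

import pandas as pd  # noqa: E402

from pepfinger.pipeline import run  # noqa: E402
from pepfinger.plate_io import SUBSTRATES  # noqa: E402

manifest = run(common["CONFIG"], stages=["deconvolve"])
acts = pd.read_csv(common["RESULTS"] / "activities.csv")
truth = pd.read_csv(common["RESULTS"] / "truth.csv")

print(f"deconvolved {manifest['stages']['deconvolve']['specimens']} specimens")
sal = acts[acts["sample_type"] == "saliva"].merge(
    truth.loc[truth["specimen"] == "saliva", ["sample_id", "label"]], on="sample_id"
)
mmp_cols = [c for c in acts.columns if c.startswith("metallo_MMP")]
print("mean effective metallo activity (nM) by caries status:")
print(sal.groupby("label")[mmp_cols].mean().round(3).to_string())
un_cols = [f"{s}_unattributed_kobs_per_s" for s in SUBSTRATES]
print("mean unattributed (BOTHi-surviving) rate, 1e-4 s^-1:")
print((sal.groupby("label")[un_cols].mean() * 1e4).round(2).to_string())
n_dis = (sal["disinhibition_evidence"].fillna("") != "").sum()
print(f"saliva specimens with disinhibition evidence: {n_dis}/{len(sal)}")
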