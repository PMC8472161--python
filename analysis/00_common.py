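"""Shared settings for the analysis drivers: one run directory, one seed.

Every numbered script stages its artifacts in results/analysis/ via the
pipeline module, so the whole sequence is reproducible with:

    for s in analysis/0*.py; do python "$s"; done
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20210866 % (2**31)

CONFIG = {
    "outdir": str(RESULTS),
    "seed": SEED,
    "simulate": {"n_caries": 32, "n_healthy": 13, "noise_sd_au": 50.0},
    "classify": {"condensed": True},
}
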