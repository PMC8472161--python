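"""Compare fingerprint features between caries and healthy saliva; cluster.

Runs the per-feature Student/Welch comparisons with Cohen's d, the Pearson
biclustering of the feature matrix, and the shrinkage partial-correlation
network; writes the comparison table, cluster assignments and edge list.
"""

import runpy
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = runpy.run_path(Path(__file__).parent / "00_common.py")

import pandas as pd  # noqa: E402
from scipy.cluster import hierarchy  # noqa: E402

from pepfinger.pipeline import run  # noqa: E402
from pepfinger.stats import bicluster  # noqa: E402

manifest = run(common["CONFIG"], stages=["stats"])
cmp = pd.read_csv(common["RESULTS"] / "group_comparisons.csv")

sig = cmp[cmp["label"] != "ns"].sort_values("p_value")
print(f"compared {len(cmp)} features; {len(sig)} significant at p <= 0.05")
print("top discriminating features (caries vs healthy):")
cols = ["feature", "test", "p_value", "cohens_d", "label", "effect_label"]
print(sig[cols].head(10).to_string(index=False))

# sample-level biclustering of the saliva fingerprints
fps = pd.read_csv(common["RESULTS"] / "fingerprints.csv")
sal = fps[fps["sample_type"] == "saliva"].set_index("sample_id")
numeric = sal.drop(columns=["sample_type"])
numeric = numeric.loc[:, numeric.notna().all() & (numeric.std() > 0)]
res = bicluster(numeric)
clusters = hierarchy.fcluster(res.row_linkage, 2, criterion="maxclust")
assign = pd.DataFrame({"sample_id": numeric.index, "cluster": clusters})
assign.to_csv(common["RESULTS"] / "bicluster_assignments.csv", index=False)
truth = pd.read_csv(common["RESULTS"] / "truth.csv")
merged = assign.merge(
    truth.loc[truth["specimen"] == "saliva", ["sample_id", "label"]], on="sample_id"
)
print("\ntop-level bicluster vs caries status:")
print(pd.crosstab(merged["cluster"], merged["label"]).to_string())
print(f"\npartial-correlation network: "
      f"{manifest['stages']['stats']['network_edges']} edges above |r| = 0.2")
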