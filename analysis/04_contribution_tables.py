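"""Format the group-contribution tables from a finished pipeline run.

Produces the two summary tables of the analysis: per-group absolute variance
with pvaf over -200..1000 ms (eye / neck / brain vs the total backprojection)
and the per-brain-cluster decomposition of the P3 window (400..800 ms), both
as CSV and as printed text.
"""

import argparse
from pathlib import Path

import pandas as pd

parser = argparse.ArgumentParser()
parser.add_argument("--pipeline-out", default="results/pipeline")
parser.add_argument("--out", default="results")
args = parser.parse_args()

vr = pd.read_csv(Path(args.pipeline_out) / "variance_report.csv")
out = Path(args.out)

env = vr.query("window == 'envelope'").copy()
env["cell"] = env["stimulus"] + "/" + env["condition"]
t2 = env.pivot_table(index="cell", columns="group",
                     values=["absolute_variance", "pvaf"])
t2.to_csv(out / "table_group_contributions.csv")
print("Group contributions, -200..1000 ms (variance uV^2, pvaf %):")
print(t2.round(2))

p3 = vr.query("window == 'p3'").copy()
p3["cell"] = p3["stimulus"] + "/" + p3["condition"]
t3 = p3.pivot_table(index="cell", columns="group",
                    values=["absolute_variance", "pvaf"])
t3.to_csv(out / "table_brain_cluster_p3.csv")
print("\nBrain-cluster decomposition, 400..800 ms:")
print(t3.round(3))
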