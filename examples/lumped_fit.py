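"""Recover per-type lumped parameters S from synthetic stretch trajectories.

Generates the default synthetic campaign — three circulating cell types,
sixteen cells per condition, nine electrode conditions, 5% cell-to-cell
scatter — reduces each tip trajectory to its steady-state elongation,
and fits L* = S V^2 gamma(R, d, w) per cell type.
"""

import tempfile
from pathlib import Path

from depstretch import estimate_S, load_default_gamma, load_trajectories, synth_trajectories

S_TRUE = {"erythrocyte": 0.004, "pbmc": 0.002, "t47d": 0.001}  # 1/V^2

table = load_default_gamma()
path = Path(tempfile.mkdtemp()) / "trajectories.csv"
synth_trajectories(S_TRUE, table, n_cells=16, noise_cv=0.05, seed=1, path=path)

fits = estimate_S(load_trajectories(path), table)
print(fits[["type", "S", "stderr", "n_cells", "S_cell_mean", "S_cell_se"]].to_string(index=False))
for _, row in fits.iterrows():
    err = 100 * abs(row["S"] - S_TRUE[row["type"]]) / S_TRUE[row["type"]]
    print(f"{row['type']}: recovered S within {err:.1f}% of the planted value")
# S merges the cell's compliance and dielectric contrast into one number;
# distinct cell types separate by many standard errors at this noise level.
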