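"""Generate a synthetic IMC-style tissue and inspect its ground truth.

Builds one ~5,000-cell ROI with a tumor core, an interface ring, normal
tissue, and planted T/DC + myeloid hubs, then prints the cell counts per
region and per planted community. These labels are what the community
detection downstream is expected to recover.
"""

import pandas as pd

import spatialcomm as sc

table, truth = sc.generate_tissue(sc.default_tissue_spec(seed=1))

print(f"{table.n_cells} cells, markers: {', '.join(table.markers)}")
print("\nCells per tissue region:")
print(truth.df["region"].value_counts().to_string())
print("\nCells per planted community:")
print(truth.df["planted_community"].value_counts().to_string())
print("\nCell-type mix of the planted T/DC hub community:")
hub = table.df.loc[truth.planted == "hub_TDC", "cell_type"]
print(hub.value_counts(normalize=True).round(3).to_string())
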