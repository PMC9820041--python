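"""Classify grid cells into functional land-use categories from POIs.

Builds a tiny 3-cell POI table by hand, bins the points to the grid,
and applies the normalized-frequency dominance rule: per-cell counts
are divided by national category totals (so that rare categories such
as residential POIs are not swamped), converted to percentage shares,
and a cell is labelled with the class whose share uniquely reaches 50%
— otherwise it is mixed-use.
"""

import pandas as pd

from activitygrid import GridDefinition, bin_points_to_cells, classify_table

grid = GridDefinition(origin=(0, 0), cell_size=5.0, n_rows=1, n_cols=3)

# cell 0: residential-dominated; cell 1: office cluster; cell 2 has a
# few POIs of several kinds — its two residential POIs still dominate
# after normalization because residential POIs are nationally rare
pois = pd.DataFrame({
    "x": [1.0] * 6 + [6.0] * 7 + [11.0] * 6,
    "y": [1.0] * 19,
    "category": (["Residential community"] * 5 + ["Catering site"]
                 + ["Office building"] * 5 + ["Private company"] * 2
                 + ["Residential community"] * 2 + ["Hotel"] * 2
                 + ["Office building"] * 2),
})

# national totals from a (pretend) country-wide snapshot: residential
# POIs are scarcer nationally, which the normalization corrects for
national = pd.Series({
    "Residential community": 2_000, "Community service": 800,
    "Private company": 9_000, "Office building": 7_000,
    "Financial sector": 2_500, "Legal sector": 900,
    "Government institution": 2_800, "Education institution": 4_000,
    "Commercial site": 6_000, "Hotel": 3_500, "Tourism": 2_000,
    "Sport/gym": 2_200, "Catering site": 7_500,
})

counts, n_out = bin_points_to_cells(pois, grid)
result = classify_table(counts, national_totals=national)

print(result[["C_res", "C_work", "C_ent", "label", "sector_label"]].round(1))
print()
print("C_* are percentage shares of normalized frequency; a unique share")
print(">= 50% fixes the label, and working/entertainment cells are further")
print("assigned the dominant sector (empty when the cell is not sectorable).")
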