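"""Derive analysis covariates from raw inputs.

Shows the data-preparation rules on tiny hand-made inputs: range-polygon
rasterization (presence on any overlap with a cell), richness counting
under the IUCN status filter, insularity (area of the containing land
mass), Shannon land-cover diversity, and paleo-climate stability.
"""

import numpy as np
import pandas as pd
from shapely.geometry import box

import threatgrid as tg

# a 4x4 all-land grid; cells are unit squares in polygon coordinates
mask = np.ones((4, 4), dtype=bool)
lab = np.zeros((4, 4), dtype=int)
grid = tg.WorldGrid(is_land=mask, landmass_id=lab, ecoregion_id=lab,
                    region_id=lab, cell_area_km2=3091.0)

ranges = pd.DataFrame({
    "species_id": ["frog_a", "frog_b", "snake_a"],
    "status": ["VU", "LC", "DD"],
    "taxon": ["amphibians", "amphibians", "reptiles"],
    # frog_a covers a sliver of one cell: still present in the whole cell
    "geometry": [box(0.1, 0.1, 0.2, 0.2), box(0, 0, 4, 4), box(1.5, 1.5, 2.5, 2.5)],
})
presence = tg.rasterize_ranges(ranges, grid)
counts = tg.richness(presence)
print("presence records:", len(presence))
print(counts[counts["taxon"] == "combined"].head(3).to_string(index=False))

# insularity: a 3-cell island vs an isolated cell
island = np.zeros((3, 4), dtype=bool)
island[0, :3] = True
island[2, 3] = True
world2 = tg.WorldGrid(is_land=island, landmass_id=np.where(island, 0, -1),
                      ecoregion_id=np.where(island, 0, -1),
                      region_id=np.where(island, 0, -1), cell_area_km2=3091.0)
ins = tg.insularity(world2)
print("insularity (km^2):", sorted(ins.unique()),
      "# small values = more insular cells")

print(f"Shannon diversity, 4 equal land-cover classes: "
      f"{tg.shannon_diversity([0.25] * 4):.4f} (= ln 4)")

# climate stability: mean step-to-step displacement in z-scored (T, P) space
stack = pd.DataFrame({
    "cell_id": [0] * 3 + [1] * 3,
    "time_step": [0, 1, 2] * 2,
    "temperature": [10.0, 10.0, 10.0, 4.0, 9.0, 2.0],
    "precipitation": [500.0, 500.0, 500.0, 300.0, 800.0, 250.0],
})
stability = tg.climate_stability(stack)
print("climate stability (0 = perfectly stable):")
print(stability.round(3).to_string())
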