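# activitygrid

Grid-cell analysis of how human activity intensity changed across
pandemic restriction and recovery stages, for spatial epidemiologists
and urban analysts working with aggregated location-based-services
(LBS) counts.

The pipeline operates on a regular grid of 5 km × 5 km analysis cells
and combines three ingredients:

**1. POI-based land-use classification.** Each cell's function is
inferred from its mix of categorized points of interest.  With $n_i$
the count of class-$i$ POIs in a cell and $N_i$ the national total of
that class,

$$F_i = \frac{n_i}{N_i}, \qquad C_i = \frac{F_i}{\sum_j F_j} \times 100\%,$$

and the cell is labelled residential, working or entertainment when its
share $C_i$ is the unique maximum and reaches 50%, mixed-use when no
share does.  The normalization by $N_i$ keeps nationally rare classes
(residential POIs are far scarcer than working or entertainment ones)
from being swamped.  Working and entertainment cells are further
resolved into 6 and 5 sectors by the same rule over sub-category
totals.

**2. Window-based change rates.** Activity intensity arrives as 48
half-hourly counts per cell for four observation days: a baseline day
and three stage days (lockdown, first-stage work resuming, total work
resuming).  Intensity is summed only inside the clock window
characteristic of the cell's class (residential 22:00–24:00, working
9:00–17:00, entertainment 17:00–22:00, mixed 9:00–24:00), and each
period's change rate is

$$\text{period}_k = \frac{S_{k+1} - S_1}{S_1} \times 100\%,$$

where $S_d$ is the day-$d$ window sum.

**3. Attribute importance.** Eight per-cell attributes (GDP, population
density, urban/rural, administrative level, built-up area, bus-stop
density, road-junction density, cumulative infection cases) are ranked
by mean-decrease-Gini (MDG) importance in a bagged CART regression
forest written from first principles: node impurity is the sum of
squared deviations from the node mean, every split maximizes the
impurity decrease, and an attribute's MDG is its summed impurity
decrease over all splits divided by the number of trees, reported as a
normalized share.  A geographically weighted regression (Gaussian
kernel, optional leave-one-out bandwidth selection) provides the
spatial-statistics baseline, compared on identical 55/30/15
train/test/validation splits by MSE and adjusted $R^2$:

$$R^2_{adj} = 1 - (1 - R^2)\frac{n-1}{n-k-1}.$$

Because the original LBS, POI and raster snapshots are proprietary, the
package ships a synthetic-data module that generates grids, POIs,
diurnal intensity curves and attribute fields with *known planted
truth*, so every stage is testable end to end without any download.

## Worked example

```bash
python examples/attribute_importance.py
```

prints, for a 225-cell synthetic scenario with the default planted
effects:

```
Importance shares (lockdown-period change):
gdp                   80.2
junction_density      13.5
population_density     2.5
bus_stop_density       1.9
built_up_area          1.5
cumulative_cases       0.4
urban_rural            0.0
admin_level            0.0

forest: train MSE 12.22, adj R2 0.940
GWR:    train MSE 19.68, adj R2 0.904
```

GDP dominates the importance ranking and junction density comes
second, mirroring the planted effect sizes; the forest fits the
training data more closely than the GWR baseline.  The other examples
(`classify_cells.py`, `change_rates.py`) walk through the classifier
arithmetic on a hand-built POI table and the per-class / per-sector /
east–west change summaries.

The full pipeline, with cached stages and a run manifest, is one call
(or `activitygrid run` from the shell):

```python
from activitygrid import ScenarioConfig, run_pipeline
run_pipeline(ScenarioConfig(seed=1), out_dir="run")
```

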