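# ldrank

Partial-order ranking of land-degradation drivers at the county scale.

Land degradation (LD) in agro-pastoral regions is driven by many interacting
factors — climate, grazing pressure, economic activity, urban expansion —
whose relative strength varies from county to county. Weighted composite
indices force these factors onto a single axis and hide exactly that
heterogeneity. `ldrank` instead ranks counties with **partial order theory**
and the **Hasse diagram technique (HDT)**: counties are compared
componentwise on a block of indicators, pairs that disagree across
indicators stay *incomparable*, and the resulting order is read off a
layered diagram rather than an aggregate score.

The package is aimed at landscape ecologists and land-management analysts
who have (a) land-cover rasters for two or more epochs and (b) county-level
driver indicators, and who want a transparent, weight-free answer to "which
driver group dominates degradation in each county?"

## What it computes

**Land-cover change accounting.** For two epochs, the class-to-class
transition matrix S, where S_ij is the area (km²) converted from class i to
class j. Degradation is the conversion of grassland, forest or water bodies
into cropland, bare areas or impervious surfaces; restoration is the
conversion of cropland or bare areas into grassland, forest or water bodies.
The annual change rate is 100 · (changed area / jointly valid area) /
period length, in % yr⁻¹.

**Driver preprocessing.** County means of each indicator (zonal statistics,
or inverse-distance-weighted interpolation of station data), min–max
normalization fnᵢ(x) = (fᵢ(x) − fᵢmin)/(fᵢmax − fᵢmin), and orientation:
indicators whose raw reading works against degradation (precipitation,
distances to built-up features) are flipped with v ↦ 1 − v so that larger
always means "stronger LD influence".

**Partial-order ranking.** For counties x, y and an indicator set F,

    x ≥ y  ⇔  fᵢ(x) ≥ fᵢ(y)  for every fᵢ ∈ F,

otherwise x ∥ y (incomparable). Counties with identical vectors are merged
into equivalence classes, the cover relations (transitive reduction) form
the Hasse diagram, levels are counted so that undominated counties occupy
the top level, and maximal chains / isolated counties are enumerated.
Average ranks use the LPOM0 closed form

    Rav(x) = (S(x) + 1)(N + 1) / (N + 1 − U(x)),

with S the number of counties strictly below x and U the number
incomparable with x.

**Dominant-driver attribution.** One Hasse diagram per driver group
(natural, human activities, economic, urbanisation); each county's height in
each diagram is scored to [0, 1] ((level − 1)/(L − 1) by default, or a
normalized LPOM0 rank); the county's dominant group(s) are the argmax set,
with an optional tie tolerance. Per-region counts of dominated counties
summarize the ranking.

**Synthetic scenarios.** A generator plants a known dominant group per
county (effect size δ, noise σ) and known land-cover transition
probabilities, so the whole pipeline can be validated against ground truth
without any external data.

## Worked example

Six counties compared on the natural driver group (temperature and oriented
precipitation; values are a built-in synthetic table):

```python
import ldrank as lr
from ldrank.examples import six_county_example

table = six_county_example()          # oriented, normalized
p = lr.build_poset(table)
h = lr.hasse(p)
print("levels:", h.n_levels)
print(lr.lpom_average_rank(p, h).to_string())
print("chains:", lr.maximal_chains(h))
print("isolated:", sorted(h.isolated))
```

prints

```
levels: 3
        members  level  S  P  U       Rav
element
KYZ         KYZ      3  4  0  1  5.833333
TQ           TQ      2  1  1  3  3.500000
KYQ         KYQ      2  0  1  4  2.333333
WL           WL      2  0  1  4  2.333333
AES         AES      1  0  2  3  1.750000
ZLT         ZLT      3  0  0  5  3.500000
chains: [('AES', 'TQ', 'KYZ'), ('KYQ', 'KYZ'), ('WL', 'KYZ')]
isolated: ['ZLT']
```

Reading: KYZ sits at the top level — it is dominated by no other county, so
natural drivers influence it most strongly; AES sits at the bottom; TQ, KYQ
and WL occupy the middle level. ZLT pairs an extreme high on one indicator
with an extreme low on the other, so it is incomparable with every other
county (an *isolated* element, drawn dashed in the DOT export) and is best
managed as its own case. The three maximal chains are the diagram's
unbroken dominance paths; along each, the natural-driver influence
increases monotonically. Rav is the LPOM0 average-rank estimate (1 =
bottom, 6 = top).

## Command line

The same workflow is scriptable:

```bash
ldrank simulate --seed 7 --out bundle/          # synthetic inputs + truth
ldrank change --grid-a bundle/landcover_1990.asc \
              --grid-b bundle/landcover_2000.asc --out change/
ldrank rank --table bundle/drivers.csv --meta bundle/drivers_meta.json \
            --out rank/
ldrank report --rank-dir rank/ --change-dir change/ --out report.json
```

`rank/` then holds per-group rank tables (`rank_<group>.csv`), Hasse
diagrams as Graphviz DOT (`hasse_<group>.dot`), cover-edge lists, group
height scores, the per-county dominance table and (with `--regions`) a
region × group summary of dominated-county counts.

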