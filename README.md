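# routewalk

Pedestrian route-choice analysis on street networks.

`routewalk` is for urban-analytics and active-travel researchers who want
to know which street-environment factors pull pedestrians away from the
"obvious" walking routes.  Given a street network with per-edge
walkability-audit attributes and a cohort of chosen routes (one per
pedestrian, origin to first destination), it:

1. generates two **labeled alternative routes** per origin–destination
   pair — the shortest-distance route and the least-directional-change
   route (space-syntax angular cost, θ/90 per turn);
2. computes **overlap** between each chosen route and each alternative,
   classifies 100%-overlap trips, and decomposes partial overlaps into
   deviated part-routes bounded by divergence/reconvergence
   intersections;
3. aggregates fifteen audited street-environment attributes to route
   level (length-weighted means for conditions/widths/proportions, sums
   for street-furniture counts);
4. estimates **conditional-logit** models of route choice.  Under
   random-utility maximisation with i.i.d. Gumbel errors,

   P(route j) = exp(β′x_j) / Σ_k exp(β′x_k),

   fitted from scratch by Newton iteration with analytic gradient and
   Hessian, standard errors from the observed information, and z / p
   values in the usual choice-model table layout.

A seeded synthetic module generates grid street networks, audit
attributes, short-trip OD pairs (~350 m scale) and utility-maximising
choices with known coefficients, so the entire pipeline is testable end
to end with a known data-generating process.

## Worked example

```python
import routewalk as rw
from routewalk.clogit import model_table

cfg = rw.SyntheticConfig(seed=1)            # 219 trips, 8x8 grid, ~350 m scale
net = rw.generate_network(cfg)
od = rw.sample_od_pairs(net, cfg)
chosen = {f"od{i:04d}": r
          for i, r in enumerate(rw.simulate_choices(net, od, cfg.beta_true, seed=1))}
report = rw.run_pipeline(net, chosen)

print(f"trips: {report.n_trips}")
print(f"mean trip length: {report.length_summary['mean_length']:.1f} m")
for lab, (n_full, n, pct) in report.full_overlap.items():
    print(f"full overlap vs {lab}: {n_full}/{n} = {pct}%")
m = report.models["entire_shortest"]
print(f"entire-route model vs shortest ({m.n_obs} trips):")
print(model_table(m.fit).to_string(index=False))
```

prints

```
trips: 219
mean trip length: 363.4 m
full overlap vs shortest: 163/219 = 74%
full overlap vs least_angular: 158/219 = 72%
full overlap vs both: 102/219 = 47%
entire-route model vs shortest (56 trips):
                 category      attribute      coef       se         z        p
         Roadway features driveway_width -0.054150 0.356954 -0.151701 0.879423
              Streetscape   green_spaces  2.737926 0.883120  3.100286 0.001933
              Streetscape   street_walls -1.615465 0.833565 -1.938019 0.052621
Pedestrian infrastructure   garbage_bins -0.309177 0.130199 -2.374644 0.017566
               Facilities          shops -3.268306 4.090841 -0.798933 0.424330
```

Reading the output: most simulated pedestrians walk one of the two
baseline routes exactly (74% match the shortest route edge-for-edge);
the models are fitted only on the trips that deviate.  Coefficients are
utilities per attribute unit on the Gumbel scale — here, greener routes
(condition code 1–3, length-weighted) strongly raise the odds that the
deviating route was the one chosen over the shortest alternative, which
is the signal planted by the generator's β(green_spaces) = +1.

The same analysis is scriptable from a shell:

```sh
routewalk simulate --seed 1 --out-dir data/
routewalk run --network data/network.geojson --attrs data/environment.csv \
              --chosen data/chosen.geojson --out report/
```

which writes `overlap.csv`, four `model_*.csv` tables and `report.json`.
`routewalk routes`, `routewalk env` and `routewalk overlap` expose the
intermediate stages for externally supplied networks and routes
(GeoJSON LineStrings plus a CSV attribute table; see
`docs/methods.md` for formats and modelling details).

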