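# emocaccess

Geographic access modelling for emergency obstetric care (EmOC) that
accounts for **patient bypassing** — the well-documented behaviour of
women travelling past a nearby facility to reach one they perceive as
higher quality.

The package is aimed at health-system planners and researchers who
want travel-time-based access estimates that go beyond
"nearest-facility" assumptions: it scores facility readiness, builds a
cost-distance surface from land cover, roads and terrain, delineates
priority-ranked catchments, routes emergency referrals along the road
network, and evaluates improvement scenarios with population-weighted
travel-time statistics. Because census-scale national inputs are
rarely redistributable, a seeded synthetic-landscape generator
provides fully reproducible inputs with the same statistical
structure, so the entire pipeline is testable end to end.

## The model

**Facility readiness and levels.** Each facility gets a readiness
score out of 14: one point for each of five general items (open 24/7,
electricity, water, motorised transport, communication) and one point
for each of the nine EmOC signal functions (parenteral antibiotics,
uterotonics and anticonvulsants, manual removal of the placenta,
removal of retained products, assisted vaginal delivery, newborn
resuscitation, blood transfusion, caesarean delivery) for which it is
both *staffed* and *equipped*. Facilities are then classified into
levels 1–5: level 5 (score 10–14 + recent caesarean), level 4 (score
10–14), level 3 (score 0–9 + transport), level 2 (score 6–9), level 1
(score 0–5).

**Journey segment 1 (home → first preferred facility).** A single
cost raster holds the minutes needed to cross each cell: walking speed
by land-cover class, attenuated by slope with a normalised
Tobler-style factor `exp(−k·|∇z|)`, replaced by motorised speeds where
roads overlap; water is impassable except at bridges. Each facility
projects a *primary* and *secondary* time-bound catchment (2 h / 5 h
for levels 5–4, 1 h / 3 h for levels 3–2, a 1 h secondary only for
level 1), and the nine (level, zone) classes carry priority ranks 1–9.
Where catchments overlap, a cell keeps only its best-ranked option —
so a woman within 2 h of a level 5 bypasses a closer level 3. Cells
beyond every bound are *outside the models*.

**Journey segment 2 (referral).** Cells whose first preferred facility
is below level 5 need onward transfer to the closest level 5 along the
road network. The direct shortest-path time `T` is adjusted by the
sender's infrastructure: no vehicle → `2T` (the receiving facility
must send one), no communication → `+30` min to locate a phone.

**Scenarios.** Model 0 is the status quo; Model 1 upgrades *k*
strategically located level-4 facilities to level 5 (greedy
population-coverage selection); Model 2 gives every facility a vehicle
and phone; Model 3 combines both. Reports give population counts by
destination level and hourly band, and population-weighted mean, SD,
95th percentile and maximum of segment-2 times (over the
transfer-needing subpopulation) and total journey times (over the
modelled population).

## Worked example

```bash
emocaccess report --seed 0 --upgrades 2 --out outputs/
```

runs the four models on the default synthetic landscape (a 75 km ×
75 km window, 50 000 people, 28 facilities) and prints:

```json
{
 "0": {"outside_pct": 0.61, "segment2_mean_h": 1.44,  "total_mean_h": 1.587},
 "1": {"outside_pct": 0.61, "segment2_mean_h": 0.796, "total_mean_h": 1.141},
 "2": {"outside_pct": 0.61, "segment2_mean_h": 1.365, "total_mean_h": 1.576},
 "3": {"outside_pct": 0.61, "segment2_mean_h": 0.428, "total_mean_h": 1.13}
}
```

Reading: 0.61 % of this landscape's population lives beyond every
catchment bound and stays outside the models. Under the status quo a
woman needing transfer to surgical care faces a population-weighted
mean referral of 1.44 h; upgrading two strategic level-4 facilities
(Model 1) cuts it to 0.80 h, universal vehicles and phones (Model 2)
to 1.37 h, and both together (Model 3) to 0.43 h — mirroring the
qualitative pattern that upgrades shorten referrals most while
infrastructure roll-out trims the adjustment penalties. Per-model CSV
reports in `outputs/` add the full level × hourly-band population
table and the SD/95th-percentile/maximum statistics.

The same stages are available piecewise (`simulate`, `score`,
`cost-surface`, `travel-time`, `catchments`, `referral`, `scenario`)
and as a library API (`emocaccess.run_pipeline`, see docstrings).

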