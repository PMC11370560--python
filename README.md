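# sipflow

Analysis pipeline for **group-housed home-cage polysubstance drinking
experiments**: cohorts of mice living together with continuous, voluntary
access to several drinking stations (water plus multiple doses of ethanol
and fentanyl), monitored by RFID antennas at each station (~100 Hz while an
animal is present) and 1 Hz volumetric drinking monitors (VDM).

The package takes the two raw acquisition streams and produces, per animal:

* **visit bouts and attributed drink events** — RFID reads are collapsed
  into station visits (maximal runs of one tag at one antenna with gaps
  ≤ 1 s), and each VDM drink row is attributed to the animal whose bout
  contains — or is nearest within 2 s of — the drink timestamp;
* **intake and occupancy tables** on the zeitgeber clock (ZT0 = lights-on,
  light = ZT0–12, dark = ZT12–24), normalised to body weight (ml/kg), at
  total / per-day / light-dark / day×ZT granularity, with dense day×ZT
  heat-map matrices;
* **two-bottle-choice preference indices**
  `pref = V_substance / (V_substance + V_water)` and dose preference
  `V_high / (V_high + V_low)` (0.5 = indifference, undefined when the
  denominator is zero);
* **polysubstance windows** — each animal × clock-aligned 60-minute bin is
  classified by the set of substances consumed; sets of size ≥ 2 are
  polysubstance use.  Combination distributions ("outer ring" = set size,
  "inner ring" = specific combination; 7 combinations for 3 substance
  types, 31 dose-resolved) are compared across groups by Pearson χ²;
* **behavioural phenotyping** — 12 open-field / elevated-zero-maze
  parameters are z-scored, reduced by PCA (components covering > 75%
  variance), and clustered by k-means; the number of clusters is chosen by
  bootstrap stability (homogeneity, completeness, V-measure, adjusted Rand,
  adjusted mutual information against the full-data fit);
* **statistics** — pooled-variance t, one-way ANOVA, two-way mixed-design
  repeated-measures ANOVA with the classical univariate error partition
  (group error = subjects within groups; within/interaction error =
  residual; df = (g−1, N−g), (a−1, (a−1)(N−g)), ((a−1)(g−1), (a−1)(N−g))),
  Bonferroni post hoc contrasts, Benjamini–Hochberg FDR, and Pearson χ².

Because raw cage data of this kind are rarely public, `sipflow` ships a
seeded **synthetic-cohort generator** that emulates all five inputs (roster,
station map, RFID stream, VDM stream, behaviour table) with planted
structure: nocturnal visit rates, a doubled female fentanyl choice weight,
escalating fentanyl preference across days, and three latent behavioural
phenotypes with serialized ground truth.  Every analysis in the package is
exercised end-to-end against those planted effects.

## Worked example

```python
from sipflow import synthetic_data as sd, stream_io, intake_metrics as im
from sipflow import preference as pf, polysubstance as ps, stats_engine as se

cfg = sd.SimConfig(n_males=8, n_females=8, n_days=2, rfid_hz=20.0, seed=11)
fx = sd.simulate_cohort(cfg)

bouts = stream_io.collapse_visits(fx.rfid, max_gap=1.0)
res = stream_io.assign_drinks(fx.vdm, bouts, fx.animals, fx.stations, tolerance=2.0)
print("bouts:", len(bouts), "events:", len(res.events), "unassigned:", res.n_unassigned)

total = im.aggregate_intake(res.events, fx.animals, "total", fx.stations, cfg.n_days)
pref = pf.substance_preference(total, "fentanyl").merge(fx.animals, on="tag")
print("fentanyl preference:", pref.groupby("sex")["value"].mean().round(3).to_dict())

t = se.t_test(pref.query("sex=='F'")["value"], pref.query("sex=='M'")["value"])
print(f"t[{t.df}] = {t.statistic:.2f}, p = {t.p:.4f}")

w = ps.classify_windows(res.events, "collapsed")
print("windows:", len(w), "polysubstance fraction:", round((w['count'] >= 2).mean(), 3))
```

prints

```
bouts: 782 events: 3681 unassigned: 0
fentanyl preference: {'F': 0.54, 'M': 0.381}
t[14] = 1.83, p = 0.0892
windows: 343 polysubstance fraction: 0.216
```

Every drink row was attributed to an animal (`unassigned: 0`); the planted
female fentanyl bias shows as a higher mean preference (0.54 vs 0.38 —
with only 16 animals over 2 days the t test is suggestive, not significant);
about 22% of the hourly windows with any intake involved more than one
substance.

The full battery — intake ANOVAs by sex and by behavioural cluster,
preference tests, polysubstance χ² contrasts, clustering with stability
table — runs from one config:

```bash
sipflow run --config run.yaml     # writes CSVs + report.json
```

or stage by stage (`sipflow simulate | ingest | intake | preference | poly |
cluster`) on intermediate files.

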