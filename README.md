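# pelagics

A size-structured pelagic food-web simulator for radiocesium (¹³⁷Cs)
bioaccumulation. It models the transfer of dissolved ¹³⁷Cs from
seawater through plankton into an age-structured community of 14
commercially important pelagic fish species of the north-western
Pacific coast, from Japanese anchovy up to Pacific bluefin tuna, and
extracts the radioecological metrics of an accidental release: peak
activity and its delay, ecological half-lives, concentration factors
and time-to-baseline.

## How the model works

* **Growth and bioenergetics** — every cohort (all fish of one species
  spawned in one year) follows a Von-Bertalanffy length curve and a
  length-weight power law. A daily energy budget closes the food
  ration: consumption covers respiration (standard metabolism × a
  swimming-activity multiplier × a Q10 temperature response), somatic
  growth, and the specific-dynamic-action/egestion/excretion losses.
* **Opportunistic size-based predation** — the probability a predator
  takes a prey depends only on their length ratio through a double
  sigmoid window (roughly 2–30× the prey length). Row-normalised
  selectivities give the diet matrix; trophic levels follow from the
  fixed point `TL = 1 + Σ α·TL_prey`, anchored by phytoplankton (TL 1)
  and zooplankton (TL 2) size bins.
* **Biokinetics** — each organism's activity concentration obeys a
  linear balance between uptake from water (`μ = 7×10⁻⁴ l g⁻¹ d⁻¹`),
  dietary uptake (assimilation efficiency 0.75 times the specific
  ration times the diet-weighted prey activity), and three first-order
  losses: allometric temperature-dependent biological elimination,
  physical decay (30.07 yr half-life), and growth dilution. Plankton
  track the water instantaneously through fixed concentration ratios.
  The system is integrated with a daily explicit Euler step using
  previous-day prey concentrations.
* **Synthetic forcing** — a seeded scenario generator supplies per-site
  water activity (uniform 1–3×10⁻³ Bq l⁻¹ baseline, then an accident
  pulse with linear rise, quasi-exponential decline and an optional
  delayed second peak at northern sites) and a 10–25 °C seasonal
  temperature cycle over a 30-site coastal grid (36–38.5 °N).
  User-supplied forcing CSVs are accepted as a drop-in replacement.

## Quick start (CLI)

```bash
# write the default synthetic forcing (30 sites, 2002-2013)
pelagics forcing --out out/

# run the full pipeline: forcing -> cohorts -> simulation -> metrics
pelagics simulate --out out/run --seed 1

# recompute metrics from an existing series file
pelagics metrics --in out/run/series.csv --accident-date 2011-03-11 --out out/metrics.csv

# dump the diet matrix and trophic levels on one date
pelagics diet --date 2010-08-02
```

`pelagics simulate` writes `series.csv` (site × species × cohort ×
date activity concentrations in Bq kg⁻¹ wet weight), `metrics.csv`,
`species_summary.csv`, `forcing.csv`, the resolved `config.yaml` and a
`manifest.json` with the seed and a configuration digest. Runs are
byte-identical under a fixed seed.

Custom runs use a YAML config (any subset of keys; unknown keys are
rejected):

```yaml
seed: 42
scenario:
  start: "2009-01-01"
  end: "2011-12-31"
grid:
  n_sites: 2
```

## Quick start (Python)

```python
import pelagics as pg
from pelagics.config import RunConfig
from pelagics.pipeline import run_simulation

result, manifest = run_simulation(RunConfig(seed=1), "out/run")
curve = result.series("S15", "jack_mackerel", 2008).to_series()
print(curve.max())          # peak activity, Bq/kg wet
```

With the default scenario and seed 1, species-mean peak delays grow
from ~87 d (anchovy) to ~420 d (bluefin tuna), ecological half-lives
from ~125 d (anchovy) to ~2100 d (bluefin), and both increase
monotonically with asymptotic length (Spearman ρ ≈ 0.96–0.98). Every
organism peaks after the water peak at its site.

## Testing

```bash
python -m pytest tests -q
```

The suite contains function-level oracles (analytic steady state,
exact exponential recovery, trophic-level residuals), engine
properties (linearity in the water forcing, determinism, unit
round-trips) and an acceptance suite (`tests/test_acceptance.py`).
One acceptance test is a **known red**:
`test_criterion_3_steady_state_and_small_pelagic_cf` asserts that a
nine-year constant-forcing run matches the naive chain equilibrium to
0.1% and that small-pelagic concentration factors average ≈ 93 l kg⁻¹.
Both targets are structurally unreachable in this model — the living
community always contains young, un-equilibrated cohorts, large tuna
never converge within a lifespan (loss time constant ~800 d), and the
dietary pathway roughly doubles the water-only concentration factor —
so the measured values (18–54% deviation; CF ≈ 180–310 l kg⁻¹) are
reported by the test rather than tuned away. See
`docs/methods.md` for the full analysis.

## Layout

```
src/pelagics/
  species.py     species parameter table (CSV-backed, validated)
  growth.py      Von-Bertalanffy growth + bioenergetic rations
  trophic.py     size-ratio selectivity, diets, trophic levels
  scenarios.py   seeded synthetic forcing generators
  dynamics.py    biokinetic balance and the multi-site engine
  metrics.py     peaks, half-lives, CFs, recovery, trend fits
  config.py      strict YAML configuration schema
  pipeline.py    orchestration and file I/O
  cli.py         click command-line interface
  data/species_default.csv   the 14-species default community
```

The shipped species table is assembled from literature-typical values
and deliberately easy to replace: point `species_table:` in the config
at any CSV with the same header.
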