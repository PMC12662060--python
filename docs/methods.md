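# Methods

`reefbleach` analyses repeated colony-level coral bleaching surveys: the
same reef stations visited during and after a marine heatwave, each
colony scored into one of six ordered health categories. This note
records the model, the parameter choices, and the limits of what the
test suite demonstrates.

## Health categories and severity indices

Each colony is assigned one category:

| code | weight | label   | extent of bleaching/death |
|------|--------|---------|---------------------------|
| C1   | 0      | Healthy | <1%                       |
| C2   | 1      | Low     | 1–10%                     |
| C3   | 2      | Medium  | 10–50%                    |
| C4   | 3      | High    | 50–90%                    |
| C5   | 4      | Extreme | >90%                      |
| C6   | 5      | Dead    | recent or long dead       |

**Bleaching Response Index (BRI).** With P1..P6 the category
percentages of a stratum (a genus, a site, or any pooled selection),

    BRI = (0·P1 + 1·P2 + 2·P3 + 3·P4 + 4·P5 + 5·P6) / 5

which maps 0 (all healthy) to 100 (all dead). The site-level BRI pools
all colonies of all genera at the site-period before applying the
formula; because the formula is linear in the category percentages, the
site BRI equals the colony-count-weighted mean of its genus BRIs — a
property the tests verify on random datasets.

**Prevalence** is 100 × (C2+C3+C4+C5)/(all colonies): live bleaching
only. Dead colonies stay in the denominator, so healthy share +
prevalence + dead share = 100 for any non-empty stratum. The package
reports mortality change as the signed difference in dead share between
the two periods, in percentage points.

**Bleaching Susceptibility Index (BSI).** Per site and period,

    BSI = Σ_i BRI_i · D_i / N

where D_i is genus i's relative abundance and N the number of genera in
the sum. Genera with fewer than `min_n = 5` colonies are excluded from
the sum — a few colonies can swing a genus BRI across its whole range —
but still count in every D_i denominator. D_i is expressed in percent
(0–100), not as a fraction: this is the only reading that produces the
tens-to-hundreds magnitudes this index is reported at in the reef
monitoring literature, and it is exposed as the `min_n`/selector
parameters rather than hard-coded, since conventions vary. With a
single genus at 100% abundance and no exclusion, BSI reduces to
BRI × 100.

**Density** is the mean over quadrats of colonies m⁻², with SE =
sd/√n over quadrats. Designed quadrats in which no colony was recorded
enter as zeros (an empty quadrat is an observation, not missing data);
the denominator is the designed quadrat count (default 20 of 1 m² per
station) unless an explicit design says otherwise.

**Degenerate strata** (no colonies) return flagged empty results or
raise `UndefinedIndexError` rather than silently reporting 0, so tables
distinguish "not surveyed" from "all healthy". In the genus summary
table a taxon absent in one period carries N = 0 and a missing BRI.

## Thermal stress (DHW)

Daily SST is reduced to a monthly climatology (per-calendar-month mean
over all years supplied); the maximum monthly mean (MMM) is the warmest
of the twelve. The daily HotSpot is SST − MMM. Degree heating weeks
accumulate HotSpots of at least `hotspot_floor = 1.0 °C` over a
trailing `window_days = 84` (12-week) window, divided by 7 to give
°C-weeks. Alert levels: ≥4 °C-weeks widespread-bleaching risk,
≥8 °C-weeks widespread-mortality risk, both inclusive at the lower
bound. The 1 °C floor matches the convention that 4 °C-weeks
corresponds to ≥1 °C excess sustained for four weeks.

Numerical choices: days earlier than one full window into the record
get a partial-window value and are flagged `supported = False` —
computed, but an underestimate of what a longer record would show;
series with calendar gaps are rejected rather than silently interpolated;
rolling sums are clamped at zero to keep float dust out of the
non-negativity invariant. The climatology is computed from whatever SST
history is supplied — reproducing a satellite product's re-centred
baseline (e.g. 1985–2012) is out of scope, and an external MMM can be
injected via `Climatology.from_mmm`.

Verified closed forms: a constant anomaly a with the floor disabled
gives steady-state DHW = 84a/7 exactly (24.0 °C-weeks at a = 2 °C); a
sub-floor anomaly accumulates nothing; DHW is translation-equivariant
(shifting SST and MMM together changes nothing) and monotone in any
single day's SST.

## Period comparison

Taxa are partitioned into dominant genera plus "Others": ranked by
total abundance, genera are named until their cumulative share strictly
exceeds `coverage = 0.80`; an explicit list can override. Relative
abundance of a status (bleached = C2–C5, dead = C6) is computed per
genus group within each pairing unit and period, with 0/0 flagged
missing rather than zero.

The test is Student's t for matched samples on per-unit values,
d = after − during, t = mean(d)/(sd(d)/√n), df = n − 1, two-sided p
from the t distribution — so negative t for bleached abundance means
less bleaching after the event. The pairing unit defaults to station:
stations persist across survey campaigns, while quadrats are
re-deployed haphazardly each time and cannot be matched; site-level
pairing is available as an option. Incomplete pairs are dropped
listwise and counted. Degenerate inputs are explicit: identical samples
give t = 0, p = 1; a constant nonzero difference has no within-pair
variance and is returned as a flagged infinite-t result rather than a
division error. The statistic is implemented directly (the degenerate
cases above are not expressible through `scipy.stats.ttest_rel`) and is
cross-checked against scipy in the tests. No multiple-testing
correction is applied, matching standard practice for these
per-taxon monitoring tables.

## Synthetic survey generator

The generator emulates the monitoring design so the pipeline is
testable without field data: 6 sites × 1–2 stations (11 stations) × 20
quadrats of 1 m², two periods. Per quadrat, the colony count is
negative binomial with mean `quadrat_mean = 18` and size
`quadrat_dispersion = 8` (var = μ + μ²/k ≈ 58.5, i.e. clearly
overdispersed relative to Poisson, as quadrat counts on patchy reefs
are); each colony draws a genus from the community relative abundances
and a during-period category from its genus's category distribution.

Between periods, each bleached colony (C2–C5) recovers to C1 with
probability `recovery_prob`, dies with `death_prob`, and otherwise
keeps its category; C1 and C6 persist. Because these are independent
per-colony Bernoulli moves and the after-period survey re-draws quadrat
membership anyway (new haphazard quadrats), the implementation evolves
each genus's category distribution analytically and draws the after
survey fresh from it — distributionally identical, simpler, and
deterministic per seed. Consequences: the after-period total is an
independent negative-binomial draw (the two periods' totals are not
coupled), and expected dead share after = dead share during +
bleached share × death_prob, which the tests check to Monte-Carlo
tolerance.

The default community is 9 dominant genera plus pooled rarer taxa,
Acropora-led, with branching thermally sensitive taxa (Acropora,
Pocillopora, Seriatopora, Stylophora, plus Lobophyllia/Pavona among the
rarer ones) given heavier bleaching mass and mortality than massive and
encrusting taxa (Galaxea, Favites, Echinopora, massive Porites,
Montipora). Millepora, a calcareous hydrocoral surveyed alongside the
stony corals, is included and can be excluded from hard-coral summaries
by flag. These profiles are illustrative of such an assemblage — they
are not fitted to any dataset, and the tests therefore validate
machinery (index algebra, conservation, calibration of the generator to
its own parameters), not any field estimate.

The SST generator is a seasonal sinusoid (default peak in mid-February,
a southern-hemisphere summer) plus flat heat-event plateaus and Gaussian
noise; the plateau shape is chosen because its DHW response has an
exact closed form.

What the synthetic data does **not** emulate: spatial correlation
within or between quadrats, taxon-specific detectability, coupling
between thermal stress and bleaching probabilities (DHW does not drive
the category distributions), and between-site heterogeneity beyond
sampling noise (all sites share one community profile by default —
per-site profiles require building a custom config). Passing tests
demonstrate the arithmetic and its invariants, not ecological realism.

## Problem sizes

Defaults were chosen so every check is cheap: the full default survey
is ~8,000 colonies and simulates in under two seconds; generator
calibration checks use ~10,000 colonies of one genus (binomial SE on
any category percentage ≤ 0.5 points, hence BRI within 1 unit with
high probability); the matched-test null calibration uses 2,000
replicates of 11 paired units (Monte-Carlo SE on the rejection rate
≈ 0.005 at α = 0.05).

## Known limitations

- Reported field densities of this survey type are often computed over
  an unstated surveyed-quadrat denominator; this package always uses
  the declared design, so densities are reproducible but may not match
  published values derived from undocumented denominators.
- The BSI relative-abundance convention (percent vs fraction; all taxa
  vs qualifying taxa in the denominator) is not standardised in the
  literature; the package documents and exposes its choice.
- The wide-dialect reader expects one header row naming site, station,
  season/period, quadrat and genus columns; multi-sheet workbooks must
  be exported to CSV first.
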