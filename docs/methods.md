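# Methods

`planktodiv` computes functional-diversity diagnostics of gridded,
depth-integrated plankton biomass fields: thresholded functional richness,
Shannon index and evenness, presence-based community turnover and its change
in rate, per-group appearance/disappearance counts, the phytoplankton
size-spectrum slope, and area-weighted regional summaries.  A synthetic-data
module generates fields with known diversity structure so that every stage
of the pipeline is testable without large model-output downloads.

## Data model

A **biomass field** is `time x lat x lon x type`, annual calendar-year
means, in mass carbon per unit area (default mgC m⁻²), already integrated
over depth; land cells are missing (NaN), never zero.  The **type
registry** carries, per type: a biogeochemical functional group
(prokaryote, picoeukaryote, coccolithophore, diazotroph, diatom,
mixotrophic dinoflagellate, zooplankton), an equivalent spherical diameter
(ESD, µm), a 1-based size class, and a trophic role.  The default
community has 35 phytoplankton types with group counts (2, 2, 5, 5, 11, 10)
plus 16 zooplankton size classes, spanning 0.6–2425 µm ESD.  The 16
phytoplankton size classes are bins equally spaced in log(ESD) over that
full community range; no published convention pins the boundaries down, so
they are an explicit, configurable choice (`size_class_edges`).

The **grid** is regular latitude–longitude with cos(latitude) × angular
extent area weights (only area *fractions* are reported, so the spherical
constant cancels) and longitudes normalized to [−180, 180).  Period means
use inclusive calendar-year bounds: the 2005–2024 baseline is the
arithmetic mean of exactly 20 annual slices.

Files are classic netCDF written through xarray's scipy backend; group
labels are integer codes with an attribute table.  Readers accept a layout
mapping for externally produced files whose variable names differ, clamp
negligible negative values (≤ 10⁻⁹ × field maximum) to zero, treat
all-missing columns as land, and reject NaN in ocean cells.

## Diversity metrics

A phytoplankton type is **present** at a cell/timestep when its share of
the total *phytoplankton* biomass there is ≥ 0.1% (configurable).  Three
conventions matter and are applied uniformly:

* the 0.1% denominator excludes zooplankton — the analysis is restricted to
  phytoplankton diversity, and zooplankton size classes are not
  functionally differentiated;
* a share exactly at the threshold counts as present;
* shares entering the Shannon index are renormalized over the included
  types, so `Σ p_i = 1`, `H = −Σ p_i ln p_i ≤ ln s` holds exactly for the
  thresholded richness `s`, and evenness `J = H / ln s ∈ [0, 1]`.

Evenness is undefined (missing) where `s ≤ 1` (ln 1 = 0) and such cells are
excluded from area fractions.  Natural logarithms are used throughout;
richness is the presence count, 0–35.

**Appearance/disappearance** of a group between two period means counts the
group members whose share crosses the presence threshold upward
(appearance) or downward (disappearance); appearances + disappearances +
persisting + never-present equals the group size at every cell.

## Turnover

Turnover between two presence sets A and B is `(N_G + N_L) / N_T` with
gains `N_G = |B \ A|`, losses `N_L = |A \ B|`, and `N_T = |A ∪ B|` — the
number of types observed across both timepoints read as the *union*, the
only reading under which the stated [0, 1] range holds (it is the Jaccard
distance).  Presence is computed from *period-mean* biomass: the metric
compares two multi-year mean communities, not an average of per-year
turnovers.  Cells where both sets are empty are missing, not 0.

The **change in turnover rate** is the turnover between a late period pair
minus that between an early pair; defaults are (2061–2080 vs 2081–2100) −
(2011–2030 vs 2031–2040), configurable.  The early-pair phrasing in the
source material is grammatically ambiguous (turnover of two means vs mean
of two turnovers); it is implemented as the turnover between the two early
period means, mirroring the late pair.

## Size-spectrum slope

Per cell: period-mean biomass is summed into the 16 phytoplankton size
classes; empty classes are dropped (a floor value for log 0 would distort
the fit); the slope of log(class biomass) against log(class ESD) is
estimated with the Theil–Sen estimator — the median of all pairwise slopes,
with the even-count median defined as the mean of the two middle values —
and the reported value is the slope **plus 3**, converting the biomass
spectrum of spherical cells to an abundance spectrum.  Negative reported
values indicate dominance by small cells.

The representative ESD of a class defaults to the geometric mean of its
member types' ESDs (natural on a log axis); the geometric midpoint of the
bin edges is available as an alternative since neither convention is
canonical.  The 0.1% presence threshold is *not* applied before binning by
default (all biomass is binned); a flag enables it.  The fit needs at least
two populated classes, is invariant to the logarithm base and to point
permutations, and equals OLS on exactly collinear data.  Theil–Sen is
implemented in-package (the estimator's tie conventions are part of the
contract); `scipy.stats.theilslopes` serves as an independent cross-check
in the tests only.

## Regional analysis

Area fractions are cos-latitude-weighted over *valid* cells: cells with an
undefined metric are excluded from numerator and denominator, and
`n_cells_valid` records the denominator's support.  "Decline"/"increase"
are strict inequalities; exact zeros belong to neither, so complementary
fractions (decline, increase, zero) sum to one.  Latitude bands use the
half-open convention [south, north) on cell centres, so touching bands
never double-count.  Built-in regions: global ocean, tropics (|lat| < 23°),
northern mid-latitudes (23–55°N), the union "poleward of 55° or within 23°
of the equator", subtropics (23–40°, both hemispheres), and the Southern
Ocean (south of 45°S).  The subtropical and Southern Ocean edges are not
universally defined, so they are explicit configuration values; reported
fractions can shift by a few points with these choices, which is why the
summary table serializes the region definitions it used.

## Synthetic data

### Parametric generator

For exact pipeline testing, `generate_parametric` constructs per-cell
communities whose measured diagnostics equal prescribed targets:

* **richness** — exactly `r` types hold positive biomass, all with shares
  at or above the presence threshold, the rest at zero;
* **evenness** — shares follow a one-parameter geometric family
  `p_i ∝ q^i`; `q` is solved numerically (Brent) so that `H / ln r` equals
  the target to better than 10⁻⁹.  The family cannot reach arbitrarily low
  evenness while keeping every share ≥ 0.1% (at richness 10 the floor is
  ≈ 0.60, at 16 ≈ 0.70); infeasible combinations raise a parameter error
  rather than silently breaking the richness guarantee;
* **turnover** — each year an expected fraction `f` of the present set is
  replaced by random absent types.  The count is the stochastic rounding of
  `f × r` (floor plus a Bernoulli remainder), which makes the *expected*
  replaced fraction exactly `f`; deterministic ceiling rounding would bias
  it upward for any `f > 0`;
* **size bias** — shares are assigned to present types by a persistent
  random priority plus `bias ×` standardized log-smallness; a positive,
  growing bias moves biomass into small types (declining spectrum slope)
  without touching richness or evenness.

All targets accept scalars, (start, end) linear ramps, or per-year arrays.
Cells evolve independently with random streams derived from (seed, cell
index), so runs are reproducible and cell order is irrelevant.

### Toy mechanistic simulator

`simulate_cell` integrates a 0-D
nutrient–phytoplankton–zooplankton community:

    dP_i/dt = µ_i P_i − Σ_j G_ij Z_j − m_P P_i
    µ_i     = µ_max,i · exp(E_a (T − T_ref)) · N / (N + k_N,i)
    G_ij    = g_max φ_ij P_i Π_j / (k_g² + Π_j²),   Π_j = Σ_i φ_ij P_i
    dZ_j/dt = λ Σ_i G_ij Z_j − m_Z Z_j²
    dN/dt   = S(t) − Σ_i µ_i P_i + r·[(1−λ) Σ G Z + m_P ΣP + m_Z ΣZ²]

with Monod uptake of a single generic nutrient, Arrhenius temperature
scaling, Holling type III grazing on the preference-weighted prey field,
and quadratic zooplankton mortality.  The feeding kernel φ is triangular in
log(predator:prey ESD ratio), zero outside ratios 5–15 and peaking at 10 —
the minimal shape consistent with the grazing range and preference.
Maximum growth is log-normal-shaped in size, peaking at 3 µm; the
half-saturation k_N rises as size^0.4, so the smallest cells have the
highest nutrient affinity and win under oligotrophic conditions.  (The
published model description contains contradictory statements about the
smallest group's affinity; the implementation follows the competitive
logic that picoplankton are the low-nutrient specialists.)

Numerics: fixed-step RK4 (default dt = 0.05 d), positivity clipping, and a
local-extinction floor (default 10⁻¹⁰ µM) below which a population is set
to zero — without it, outcompeted types linger at astronomically small
densities and corrupt log-biomass diagnostics.  Halving dt changes the
final state by far less than 1% (`dt_stability_check`).  A closed system
(no supply, full recycling, no mortality, assimilation 1) conserves
N + ΣP + ΣZ to integrator precision; a single type without grazers reaches
the Monod chemostat steady state N* = k_N m_P / (µ_max a(T) − m_P), which
the tests verify to 0.1%.

Each run is preceded by a spin-up (default 30 years) under the initial
forcing, so the recorded trajectory starts from an equilibrated community
rather than the arbitrary uniform initial condition — without it, the first
recorded decade is dominated by the relaxation transient and comparisons of
"early vs late" periods measure the transient, not the forcing response.
The default forcing then declines the nutrient supply linearly from 0.05 to
0.015 µM d⁻¹ and warms by 3 °C over 96 years.  Under this forcing, biomass
share shifts toward the small, high-affinity types and the size-spectrum
slope of the final decade falls below that of the first recorded decade,
reproducing the shift toward small-cell dominance that declining nutrient
supply causes in trait-based models.

The simulator carries group labels as metadata only: mixotrophy,
multi-nutrient colimitation (N/P/Si/Fe), nitrogen fixation, sinking and
transport are not represented.  It exists to produce fields with a
realistic, mechanistically generated diversity structure for the analysis
pipeline — it is not an ocean ecosystem model, and passing tests on its
output says nothing about skill against observations.

### World assembly and presets

`generate_world` maps per-latitude-band (or arbitrary-region) scenarios
onto a grid, runs parametric cells independently (one stream per cell) or a
mechanistic scenario once per band, and multiplies mean-one lognormal noise
(default σ = 0.1) onto all biomass.  Every ocean cell must be covered by a
scenario; the first matching region wins.

Presets: `tiny` (4×4 all-ocean grid, 8 types, 10 years, parametric) for
fast fixtures, and `paperlike` — a 10×16 global grid (18° × 22.5° cells, a
small land patch), the default 51-type registry, annual fields 2005–2100,
and six parametric band scenarios emulating the canonical high-emissions
response: biomass declining at low latitudes and rising poleward of 55°,
richness declining in the northern mid-latitudes and rising at the poles
and equator, evenness declining everywhere, per-year turnover accelerating
from 0 to 0.02–0.03 (flat in the mid-latitude bands), and a size bias
tilting small everywhere except a North-Atlantic-like sector where larger
types move in.  These trend magnitudes (e.g. tropical biomass −30%,
evenness −0.1 to −0.13, richness ±2–5 types) are fixed design choices of
the emulation, picked once as plausible magnitudes for a century of
high-emissions forcing; the per-year replacement fractions are kept at the
few-percent level because a community exchanging most of its membership
every decade would smear the 20-year period means into near-uniform
presence sets.

## Problem sizes

The shipped configurations are sized for a laptop: the `paperlike` world is
160 cells × 96 years × 51 types (generated in about a second), the
mechanistic acceptance runs integrate a single cell for 95 years at
dt = 0.05 d (~2 minutes), and the estimator cross-checks use hundreds of
random 16-point sets and all 4096 presence-set pairs of a 6-type universe.
Full-resolution model output (2° × 2.5°, 51 types, 96 years) is read
through the same `read_biomass` interface with a layout mapping but is not
required by any test.

## Known limitations

* The parametric generator's evenness family is geometric; it cannot
  express bimodal share structures, and its evenness floor rises with
  richness (see above).
* The toy simulator has one nutrient and no transport; coexistence is
  entirely grazing-mediated, so its equilibrium richness is lower than in
  transport-coupled models, and tuning it to a target richness is out of
  scope.
* Area fractions depend on band-edge conventions at the few-percent level
  on coarse grids; the summary table records the definitions used.
* Turnover is presence-based (Jaccard); abundance-weighted turnover
  (Bray–Curtis and relatives) is deliberately out of scope.
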