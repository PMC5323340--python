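# Methods

## Series model

`homolseries` treats a picked LC-HRMS peak list as a point set in
(m/z, RT, intensity) and defines a homologue-series candidate as an
m/z-ordered peak tuple whose adjacent differences are jointly
consistent with repeated addition of one chemical unit:

1. **Mass window.** Δm/z of adjacent members lies in
   [`dmz_min`, `dmz_max`] (Th), the a-priori mass range of candidate
   units at the charges considered. `dmz_min` must be positive, so
   m/z is strictly increasing within a tuple.
2. **Mass-defect envelope.** For a unit built from a given element
   set, the change of mass defect per Th of Δm/z is bounded by the
   extreme ratios defect/mass of the lightest isotopes of those
   elements (`gamma_bounds`). The adjacent defect difference must lie
   in [γ_min·Δm/z − 2ε, γ_max·Δm/z + 2ε]. Defects are reduced to
   [−0.5, 0.5) (ties at exactly ±0.5 round away from zero); a
   difference crossing ±0.5 wraps by ∓1 u, so validation tests the
   raw difference at shifts {0, ±1}.
3. **Retention window.** Adjacent ΔRT lies in [`drt_min`, `drt_max`];
   negative `drt_min` admits series formed by unit subtractions in
   meshed families.
4. **Local regularity.** Between consecutive pairs, |change of Δm/z|
   ≤ 4ε and |change of ΔRT| ≤ `ddrt_max` (absolute value — no sign
   is privileged).
5. **Global smoothness.** For tuples of length ≥ 4, a cubic smoothing
   spline RT ~ m/z with roughness penalty λ must reach R² ≥ `r2_min`.

ε is the maximum ± m/z measurement error, either absolute (Th) or
proportional (ppm). The pairwise 2ε margin is evaluated at the
lower-m/z peak of each pair and the 4ε margin at the middle peak of
each consecutive pair-of-pairs; this single convention is used by
every stage, so stage-1 output, merged tuples and the independent
validator agree exactly. An intensity-dependent ε is not modelled.

## Two-stage detection

**Stage 1 (k-d tree).** Each peak is embedded as
a = (m/z, Δm − γ_min·m/z, Δm − γ_max·m/z, RT); dimensions 2 and 3
rectify the γ envelope so that the feasible-successor region of a
peak is an axis-aligned closed box (H; the predecessor box L is its
mirror). A static 4-d k-d tree (median split cycling dimensions from
the root; median ties broken by lower peak index, even partitions
taking the lower middle element) answers the box queries with subtree
pruning. Where a center's defect plus the maximal γ-bounded change
can cross ±0.5, the box is additionally queried shifted by ±1 u on
the defect dimensions, and all candidates are re-validated in
unwrapped arithmetic — queries are a superset of the true acceptance
region (exactly so in absolute-ε mode; in ppm mode the
center-anchored box is wider than the lower-peak-anchored margin), so
nothing is lost. Valid adjacent pairs are then joined on the shared
middle peak under rule 4 to give the triplet set S₃; this equals
enumerating L×H per center and is tested against an O(n³) exhaustive
oracle.

**Stage 2 (recombination).** Two n-tuples overlapping in all but
their first/last member merge into an (n+1)-tuple; all pairwise
constraints of the merged tuple are inherited from its two parents,
so only the spline check (rule 5) is evaluated on merge. Tuples that
extended at least once are removed from their length class; the rest
are retained. The recursion terminates because tuple length strictly
grows within a finite peak set. Finally, retained tuples whose peaks
form an arithmetic index subsequence (step k ≥ 2, any offset, length
≥ 3) of a retained tuple of length ≥ 5 are removed as
regular-omission redundancies; irregular subsets are kept, since they
carry genuinely different spacing patterns. Remaining tuples of
length ≥ `n_min` become the reported series, sorted by first peak id
then length, ids assigned 1..K — identical input always yields
byte-identical output.

A peak may sit in many series. This is intrinsic: n isobaric twin
pairs along one series generate exactly 2ⁿ rival full-length series,
and a single missing member lets a double-spacing series bridge the
gap whenever 2·Δm/z ≤ `dmz_max`. These artefacts are surfaced, not
suppressed, and the pairing layer quantifies them.

## Smoothing spline

The spline minimizes Σ(RTᵢ − g(m/zᵢ))² + λ∫g″(t)²dt over natural
cubic splines with knots at the tuple's m/z values; fitted values are
obtained in closed form as (I + λK)⁻¹RT with K = QR⁻¹Qᵀ assembled
from the knot spacings. This closed form is used for all n ≥ 4
(penalized spline routines in common libraries refuse n < 5) and its
fitted values are unit-tested against
`scipy.interpolate.make_smoothing_spline`, which solves the same
objective, for n ≥ 5. λ = 0 interpolates (R² = 1, check effectively
off — the default, since a portable λ cannot be stated: its scale
depends on the RT and m/z units); larger λ is strictly smoother. R²
= 1 − SS_res/SS_tot; an all-equal-RT tuple has SS_tot = 0 and passes
by convention. The check starts at n = 4 because a cubic smoothing
spline on three points is degenerate and rule 4 already constrains
triplets.

## Series pairing

All unordered series pairs sharing ≥ 1 peak id are extracted. Each
series is summarized by u = (mean ΔRT / c_ΔRT, mean Δm/z / c_Δm/z)
with c the ranges of those means over all series of the sample
(degenerate zero ranges fall back to 1 so θ stays defined); the
intersection angle is θ = arccos of the clamped normalized dot
product. Pairs with θ below a threshold (default 0.08π, a
histogram-derived working value) are superjacent — near-coincident in
the RT–m/z plane, typically isobaric or gap artefacts — and the rest
are meshed. Means are signed, so subtraction-formed series with
negative mean ΔRT are handled. For external SOM clustering each pair
also yields v = (mean ΔRT_x/ĉ_ΔRT, mean Δm/z_x/ĉ_Δm/z, mean
ΔRT_y/ĉ_ΔRT, mean Δm/z_y/ĉ_Δm/z), ordered so mean Δm/z_x ≥ mean
Δm/z_y; the scale constants ĉ are user-supplied expected
uncertainties of the means (no universal default exists). SOM
training itself is out of scope; vectors are exported as delimited
text. Cross-sample prevalence of unit masses is summarized by
counting, for every observed series mean Δm/z, the samples containing
at least one series within a moving ±window (default ±0.005 Th, i.e.
±5 μu).

## Blank and monoisotopic voting

Blank voting screens picked blank-measurement peaks (not raw
profiles, which are upstream of a peak-list tool): a sample peak
fails if any blank peak lies within ±`mz_tol` and ±`rt_tol` and
exceeds `intensity_factor` (default 0.1) times the sample peak's
intensity; a series is blank when the failing fraction reaches
`majority` (default 0.5). The window tolerances have no canonical
values and are required arguments. Monoisotopic voting consumes an
external isotopologue-annotation table (grouping algorithms are a
separate concern): a series is monoisotopic when the modal m/z rank
over its annotated peaks is 1; modal ties including rank 1 resolve to
monoisotopic but are reported as "tie", and series without annotated
peaks are "undetermined". Both votes are order-invariant, and the
failing-peak count is non-increasing in `intensity_factor`.

## Synthetic data and the permutation false-series rate

The generator plants series with configurable unit (formula or raw
Δm/z at charge z), start m/z, length, RT start/increment with
optional geometric decay (emulating the flattening retention trend of
long homologue chains), Gaussian m/z and RT noise, gap positions and
isobaric twin positions (twin offset 0.0005 Th in m/z, 4 RT units),
on a background of peaks uniform in m/z and RT with log-uniform
intensity — a deliberately structureless null. Default study
conditions used by the test suite and the acceptance script: series
lengths spanning 5–30 members over the CH₂ / C₂H₄O / CH₂O / C₃H₆O
units, 1000 background peaks over m/z 100–1000 and RT 60–1200 s,
ε = 0.002 Th absolute, m/z noise ε/4 for the noisy condition,
detection bounds Δm/z ∈ [10, 60] Th, ΔRT ∈ [5, 120] s, ΔΔRT ≤ 20 s,
n_min = 5. What the generator does not emulate: isotope envelopes,
chromatographic peak shapes, intensity-dependent mass error,
correlated (drifting) RT noise and matrix-dependent peak-picking
dropout — so passing tests demonstrate the combinatorial and
geometric correctness of the detector under the stated error model,
not picker robustness on real data.

The false-series rate is estimated by permutation: the pairing of
(m/z, and hence mass defect) against (RT, intensity) is shuffled
across peaks, destroying genuine series structure while preserving
both marginal distributions exactly, and the detector is re-run; the
mean ± sd of the assigned-peak fraction over permutations estimates
the chance-detection level. On an unstructured cloud the permuted
rate matches the original (null self-consistency); on structured
input it falls far below the observed assigned fraction.

## Numerical and design choices

* Closed boxes everywhere: an ε-wide tolerance includes its boundary.
* cos θ clamped to [−1, 1] before arccos.
* Peak ids are positional after a stable m/z sort; all outputs are
  deterministic functions of the input bytes and the seed.
* Sub-tuple filtering runs once on the final retained sets; because
  removal is keyed to retained supertuples, this equals per-recursion
  filtering for the final result.
* Problem sizes in the test suite and acceptance script (50 oracle
  instances of ≤ 200 peaks, 1000 query boxes, 1000-background
  recovery samples, 3 permutations) were chosen as the smallest sizes
  at which the checked properties are non-trivial while the whole
  suite stays interactive-fast.

## Known limitations

* No gap tolerance: a missing member splits a series into flanks
  (each must reach n_min) and may induce a double-spacing bridge.
* Combinatorial output: heavily isobaric samples produce
  exponentially many rival series by design; downstream clustering
  (superjacency, SOM) is the intended remedy, not suppression.
* ε independent of intensity; RT units are the caller's
  responsibility (all RT parameters share them).
* Peak picking, centroiding, isotopologue grouping and adduct
  componentization are out of scope — inputs are picked peak tables
  and optional annotation tables.
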