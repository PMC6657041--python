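# Methods

This note documents the models, rules and numerical choices behind
`mobispace`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Trajectory model and geodesy

A fix is a WGS84 coordinate pair with a timezone-aware timestamp.
Distances use the haversine formula on a sphere of radius 6371.0 km. All
planar work (hulls, ellipses, variances, overlap) runs on an
azimuthal-equidistant projection centred at the participant's home (day
centroid when no home is known). This projection preserves distances from
the origin exactly, so home-centred quantities (maximum distance, OH
buffer) carry no projection error; for points within the ~10 km daily
range of the cohort the round-trip error is far below 1 m (tested to
500 km).

Outlier removal drops fixes implying more than 330 km/h — the fastest
plausible ground travel — judged against the previous *retained* fix, so a
single corrupted fix cannot invalidate the genuine fix after it. The
filter is a single forward pass and is idempotent. Days are split at 3 AM
local time with a half-open convention (a fix at exactly 03:00 starts the
new day): splitting at night minimises the chance of cutting an activity
in two. Weekend means Saturday or Sunday of the logical date.

## Stop/move segmentation

Stops follow time-based clustering: a candidate grows from an anchor fix
while successive fixes stay within 150 m of the anchor; if the candidate
spans at least 5 minutes it becomes a stop (centre = per-coordinate median
of its members, arrival/departure = first/last member timestamps),
otherwise the anchor advances by a single fix. The single-fix advance
matters: releasing a whole failed candidate can leave the next stop's
detected arrival minutes late when the failed candidate was anchored on a
transitional fix near the stop boundary. A time gap longer than 60 min
inside a candidate ends it at the gap, so the dwell before and after form
two separate stops; a fix that *exits* the region after such a gap is
labelled a jump (typically the first fix after in-building signal loss at
a new place). Jumps join no segment and feed only trajectory-level
indicators (hulls, OH time), where every retained fix counts.

Runs of unassigned fixes between stops become moves when they span more
than 3 minutes; shorter runs are residue. Adjacent stops are merged when
only residue lies between them, their centres are closer than 150 m and
the inter-stop interval is under an hour; merging unions the member fixes,
recomputes the median centre, and iterates to a fixpoint (idempotent, and
stop/move time-disjointness is preserved because only non-move intervals
are absorbed).

Transport mode uses the 90th percentile of consecutive-fix-pair speeds
(linear-interpolation percentile): ≥ 25 km/h ⇒ passive (motorised), else
active. A move with fewer than two fixes has no defined speed; it is
classified active and flagged.

Home detection clusters the first and last fix of every valid day with
DBSCAN (haversine, eps 60 m, minPts 3). The candidate is the cluster
centroid closest to the address home (the largest cluster without one).
The GPS candidate replaces the address only when it captures more than one
percentage point more of all retained valid-day fixes within a 60 m
buffer. Out-of-home flagging uses a closed 150 m buffer around home (a
point at exactly 150 m is at home). Stop-location clustering across the
selected days uses DBSCAN (60 m, minPts 2) on stop centres; clustered
stops are multiply-visited, noise stops get singleton ids.

## Validity, inclusion, day selection

A day is valid iff the span between its first and last fix reaches the
wear-time threshold (8, 9 or 10 h — gaps do not count against it), at
least one stop was detected, and no fix lies within 200 m of the lab on
the first/last study day. A participant is included iff the GPS and
address homes agree within 170 m, there are at least `min_days` valid days
including one weekend day and `min_days − 1` weekdays, at least one valid
weekend day and two valid weekdays contain a move, and no non-habitual
movement was reported (an input flag — this information comes from a
post-study questionnaire, not from the GPS record). Inclusion is monotone: tightening day or hour thresholds
never admits an excluded participant.

Day selection is seeded and reproducible. Scheme R draws one valid weekend
day plus `min_days − 1` valid weekdays uniformly; scheme M draws one
weekend day and two weekdays among valid days containing at least one
move. The selected-set composition (exactly one weekend day) is enforced
strictly; inclusion guarantees feasibility.

## Indicators

Daily values, computed on each indicator's scheme days:

- **MaxDist** (km): haversine distance from home to the farthest fix.
- **CHull** (km²): convex-hull area of the projected fixes (shapely;
  degenerate hulls have zero area and out-and-back perimeter).
- **SDE** (km²): standard deviational ellipse — mean centre, orientation
  from the principal axis of the sample covariance (ddof = 1), semi-axes
  the 1-SD standard deviations along the principal directions, area
  π·σ₁·σ₂. No √2 inflation is applied; for a bivariate normal cloud the
  1-SD ellipse covers ≈ 39 % of points, and descriptions attaching "68 %"
  to it import the one-dimensional rule. Fewer than three points or a
  collinear cloud ⇒ missing.
- **LocVar** (log km²): ln(var x + var y + ε), ε = 10⁻⁶ km², sample
  variances on projected km. The floor bounds the degenerate all-home day
  at ln ε ≈ −13.8.
- **LengthPerTrip** (km): mean move path length (all moves; missing when
  none). **DurPTM/DurATM/MaxDurATM** (min): passive/active totals and the
  longest single active move (zero when no such move — the semantics force
  a zero, not a missing value).
- **TOH** (min): summed inter-fix intervals where both fixes are OH and
  the gap is ≤ 60 min, i.e. interpolating across short in-building signal
  losses but not long ones.
- **Entropy** (nats): −Σ pᵢ ln pᵢ over the day's dwell-time shares per
  stop cluster, home included.
- **NumLoc**: OH stops that day, counting repeat visits each time;
  **NumUniqLoc** is the week-level count of distinct OH clusters over the
  M days (a daily median of a uniqueness count would be self-contradictory,
  so it is computed once per week).
- **RevisitedLS / AvgRevisitedLS**: for each M day, the fraction of its
  hull covered by the union of the other days' hulls, and the mean
  pairwise overlap fraction (shapely polygon intersection).
- **SDDirMaxDist**: the day's initial bearing from home to the farthest
  fix (earliest fix on ties); aggregated weekly as the circular SD
  √(−2 ln R̄) of the daily bearings (undefined when R̄ = 0, e.g. an
  antipodal pair).
- **GravCompact**: K = P/(2√(πA)) of the hull; 1 for a circle, larger for
  elongated shapes. **Maj2MinAxis**: SDE semi-axis ratio (≥ 1).
- **TimeMaxDist / TimeFirstMove** (min since 3 AM) and
  **TimePeriodActive**: OH activities (moves and OH stops) counted by
  start-time period — morning 06–12, afternoon 12–18, evening 18–23;
  code 1 when morning > evening activities, 3 when evening > morning, 2
  otherwise; activities starting outside 06:00–23:00 are uncounted.

Weekly aggregation is the median of non-missing daily values over the
scheme days, except circular SD for SDDirMaxDist and the mean for
TimePeriodActive. Missing daily values are dropped; an indicator with no
value is reported missing, never zero-filled.

## Factor analysis

Each column is transformed by whichever of identity, √x, log(x + offset)
minimises absolute sample skewness (offset = the smallest positive float,
used only when zeros are present; candidates requiring non-negative input
are skipped otherwise; ties keep the least aggressive transform). KMO is
computed from the correlation and anti-image partial correlations;
Bartlett's sphericity from −(n−1−(2p+5)/6)·ln|R|.

The factor count combines four non-graphical scree rules on the
correlation eigenvalues: Kaiser (> 1, strict), parallel analysis (above
the mean eigenvalues of 100 seeded standard-normal data sets of the same
shape), optimal coordinates (observed eigenvalue at or above its linear
extrapolation from the next eigenvalue and the last one, counted from the
front until the first failure), and acceleration factor (the position
before the largest second difference of the scree). The chosen count is
the mode of the four; with exactly two modes the median is used, and with
no repeated value — a case the two-mode rule does not cover — the median
as well. On pure noise the Kaiser count sits near p/2, so the combined
rule typically lands at 2–3 there while parallel analysis correctly says
≤ 1; planted-structure recovery, not noise behaviour, is what the rule is
used for.

Extraction is maximum-likelihood factor analysis on the standardized data
(statsmodels) with varimax rotation; factors are ordered by explained
variance and sign-fixed so each factor's largest loading is positive.
Variance shares are per-factor sums of squared rotated loadings divided by
p; the model-fit p-value is the Bartlett-corrected likelihood-ratio
sufficiency test computed from the fitted loadings and uniquenesses.
Near-zero uniquenesses (Heywood cases) and non-convergence raise errors;
the repeated-run driver records such runs and continues. Participants with
any missing weekly indicator are dropped listwise before the EFA. The pair
matrix assigns each indicator to every factor with |loading| ≥ 0.4
(absolute value — meaningful negative loadings count) and counts, per run,
pairs sharing at least one factor.

## Synthetic data

The cohort generator emulates one week of smartphone GPS per participant:
nights at home, a Poisson number of daily out-of-home visits at
destinations drawn from a persistent pool (reused with the routine-overlap
probability) placed anisotropically around home, walk (3–6 km/h) or
vehicle (30–90 km/h) trips along straight paths, fixes every 60 s
(smartphone logging granularity) with isotropic Gaussian noise, and
in-building drop-out episodes at stops (10–40 min, below the 60-min TOH
interpolation window, since building-related loss is what the
interpolation rule is designed to bridge). Trips under 2 km are always
walked and vehicle speeds are capped so every trip exceeds the 3-min move
threshold; destinations sit at least 500 m from home. Planted stop
arrival/departure times are recorded at the crossings of the 150 m stop
region — the construct segmentation estimates; a pedestrian spends 1.5–3
minutes traversing that region, which makes "the moment a stop begins"
inherently soft at walking speed, so the dedicated boundary-recovery days
use motorised transitions (40–60 km/h), where the crossing is sharp
relative to the 30 s sampling used there.

Cohort profile distributions (extent scale lognormal with median 2.5 km,
1–3.5 visits/day, walk propensity Beta(2.5, 2), routine overlap 0.3–0.8,
elongation 1–3, noise 10–40 m, gap rate 0.05–0.25/h, homes on an 8 km
urban disk) were chosen to produce weekly descriptives of the same order
as published older-adult cohorts (median TOH a few hundred minutes/day,
median maximum distance a few km, ~2 OH locations/day). Address-based
homes err by < 50 m except for a configurable fraction (default 5 %)
planted beyond the 170 m exclusion threshold.

What the generator does *not* emulate: road networks (paths are straight),
multi-modal trips, device non-wear (simulated wear is near-continuous, so
the five wear-time conditions admit nearly identical cohorts — on real
data they formed a gradient), unstructured wandering, and GPS error
autocorrelation (noise is i.i.d.). Passing tests therefore demonstrate
algorithmic correctness against a controlled truth, not performance on
real smartphone data.

The planted factor model draws indicator rows from x = Λf + ε with
orthonormal factors and uniquenesses 1 − λ², using a six-dimension default
pattern (life-space extent; quantity of OH activity; active-transport
time; life-space stability; elongation; timing) with loading magnitudes in
[0.6, 0.9]. Weaker loadings are not separable from noise by any scree
method at n = 95, so the planted pattern stays within the recoverable
band by design.

## Problem sizes and determinism

The test suite and the acceptance script run the cohort pipeline at the
study scale (95 participants × 7 days at 60 s sampling, ≈ 0.9 M fixes,
about half a minute end to end) and validation batches of 100
planted-schedule days and 200 planted trips. Every random draw flows
through explicit integer seeds (`numpy.random.default_rng`); identical
seeds give byte-identical outputs, including day selection and parallel
analysis.

## Known limitations

- Stop-boundary timing at walking speed is limited by the region-crossing
  ambiguity described above (~2–3 min), not by the detector.
- ML factor analysis at n = 95 with 20 variables occasionally hits Heywood
  boundaries; such runs are reported as failures rather than silently
  regularised (in the 5 × 10-run study, typically one run per condition).
- KMO/Bartlett and the scree rules assume a complete, non-degenerate
  correlation matrix; constant indicator columns (e.g. a cohort with no
  motorised travel at all) raise a clear error instead of propagating
  NaNs.
- The 1 % home-replacement rule counts all retained fixes of valid days;
  counting only a subset (e.g. boundary fixes) would be an equally
  defensible reading of the rule, and the choice shifts the decision only
  for participants whose two home candidates nearly tie.
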