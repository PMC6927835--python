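# Methods

## Calendar model

A respondent record holds two fixed-width strings — states and reasons —
plus the interview month and the calendar start month as century-month
codes (CMC: months since January 1900, January 1900 = 1). The observed
window spans `cmc_interview − cmc_calendar_start + 1` months. Stored
strings follow the recode convention of most DHS extracts: the interview
month sits at the left end of the non-blank region and time runs backward
along the string, so the expander reverses it into chronological order. A
`calendar_direction: oldest_first` switch handles extracts that were
already reversed, because exported files vary.

Blank characters outside the observed window are padding and are stripped.
A blank *inside* the window is kept as an unobserved month: the record
invariant we enforce is that the blank-stripped span has exactly the
window's length, and interior blanks surface as person-months with a null
state. Downstream rules treat unobserved months as "not reported": an
unobserved month cannot anchor a new-use episode (neither as the non-use
month nor as the baseline), and an unobserved follow-up month excludes the
episode.

Sampling weights follow the survey convention of storing the design weight
times 10^6 as an integer; `dhs_weight: false` takes the column as-is.

## Episode and pairing rules

- **Entry**: month *m* ≥ 1 is a baseline iff state(*m*) is a method and
  state(*m* − 1) is the non-use code. Month 0 never qualifies (no observed
  prior month). A woman contributes every such episode in her window;
  overlapping follow-up horizons are allowed.
- **Follow-up**: the destination is the state at *m* + horizon
  (default 12 months). If that month is past the window or unobserved the
  episode is excluded and tallied as "no 12-month observation" — the
  both-endpoints rule.
- **Pregnancy at follow-up** collapses to non-use by default, because the
  destination side of the diagrams shows methods and non-use only;
  `pregnant_as_state: true` keeps a separate destination.
- **Reason attribution**: for a switch or quit, the reason is read at the
  first observed month after baseline whose state differs from the origin
  method — the end of this episode — never at a later discontinuation
  inside the horizon. Continuers carry no reason.
- **Exclusions**: pairs whose reason is "wanted to become pregnant" are
  dropped at the pair level (the episode's own discontinuation reason, not
  the whole woman), so the analysis focuses on women trying to avoid
  pregnancy. Never-users hold no episodes by construction and enter the
  exclusion tally only as a reported count.

A real extract can, in principle, contain a discontinuation with a blank
reasons calendar; such a pair keeps `reason=None` and is accepted by the
flow matrix but rejected by the reason matrix, which treats it as an
upstream data defect. The simulator always records a reason at every
discontinuation, so the strict invariant (reason null iff continue) holds
on all synthetic cohorts.

## Matrices

The flow matrix orders labels by typical-use effectiveness with non-use
last; the default ranking (implants, sterilization, IUD, injections, LAM,
pill, condom, …, traditional methods) follows the standard typical-use
failure-rate literature and is fully configurable. The origin side carries
a zero row for non-use so both halves of the diagram share one label set.
Reason matrices aggregate switch pairs or quit pairs only, with reason
columns ordered in-need first. The mapping of reasons to "in need" versus
not (side effects, health concerns, access, cost, inconvenience, partner
disapproval, wanting a better method → in need; infrequent sex, menopause,
marital dissolution, fatalism, other → not) is a repository convention —
the underlying surveys publish no such mapping — and is configurable.

`collapse_methods` sums cells under any label grouping (e.g. long- versus
short-acting) and preserves the grand total; non-use maps to itself when
the grouping omits it.

## Chord-diagram geometry

Angles are measured clockwise from 12 o'clock; the right half is (0, π),
the left half (π, 2π), and the dashed divider is the vertical diameter.
Each side's usable angle is π − (*k* + 1)·g for *k* groups and gap g
(default 0.03 rad, same on both sides), divided among groups in proportion
to their marginals. Consequences tested exactly: per-side angle budgets
close to 1e-9; sub-arc partitions within each group are exact; all angles
are invariant to global rescaling of the matrix.

Zero-marginal groups keep a zero-width slot (and still count toward the
gap budget) so both sides always display the full label set in legend
order. Groups run top-to-bottom by effectiveness on both sides, so ribbon
direction is a pure rank comparison: up toward a more effective
destination, down toward a less effective one or non-use, flat for
continuation. Reason labels carry no effectiveness rank; ribbons into
reason arcs are marked "down" (movement into a terminal state). Within an
origin arc, sub-arcs follow destination display order, and symmetrically
on the destination side; this ordering is a convention and other chord
implementations may order sub-arcs differently without changing any
widths.

A ribbon's outline is: origin sub-arc along the circle, quadratic Bézier
with control point at the circle center to the destination sub-arc,
destination sub-arc, Bézier back. Paths are non-self-intersecting for
sub-arcs narrower than π, and enclosed area grows monotonically with the
flow's weight (checked against a shoelace-area oracle on sampled
outlines).

Rendering is deterministic (byte-identical SVG for identical inputs).
Interactivity is declarative only — an SVG `<title>` per ribbon provides
the hover annotation — keeping the artifact a single self-contained file;
an optional HTML wrapper embeds it. The method palette interpolates
linearly in RGB from dark to light blue along the effectiveness order,
which makes luminance strictly monotone in efficacy rank; non-use is
neutral gray; in-need reasons take dark blue shades, not-in-need light.
Canvas: 800×800 viewBox, circle radius 320, labels at 340.

## Synthetic cohorts

`simulate_cohort` draws each woman's monthly states from a first-order
Markov chain (row-stochastic monthly transition matrix, validated to
1e-12) and writes a reason — drawn i.i.d. from a per-origin-method
categorical — at every month the chain leaves a method. One seed drives
the cohort; each woman uses a counter-derived substream, so any record is
reproducible independently of iteration order. The stock demonstration
chain has four states (non-use, injections, pill, implants) with monthly
method-uptake hazards of 1–4% from non-use and discontinuation hazards of
2–7%, magnitudes typical of high-churn calendar data; 15% of simulated
discontinuation reasons are "wanted to become pregnant" so the exclusion
path is exercised.

What the simulator emulates: the calendar's data structure, weights, and
reason codes, and a memoryless approximation to monthly dynamics. What it
does not: postpartum non-use spells, duration dependence in
discontinuation, recall and social-desirability bias. Tests passing on
synthetic cohorts therefore validate the *bookkeeping* (rules, weights,
geometry), not any behavioral realism.

Because the chain is first-order, conditioning a baseline on prior
non-use does not alter the forward law: among new users with baseline
state *s*, the 12-month destination distribution is row *s* of P¹².
The recovery check simulates 20,000 women over 60 months and requires
every cell to match that analytic law within 3 binomial Monte-Carlo
standard errors; pairs are taken before the wanted-pregnancy exclusion so
the unconditional law applies.

`cohort_from_flow_table` realizes a printed count table deterministically:
per cell (origin, destination) with value *v*, it emits *v* unit-weight
women whose chronological calendar is one non-use month, the origin method
at baseline, and — for switchers and quitters — a change to the
destination six months after baseline with a configurable reason (side
effects by default, so the exclusion rules retain the pair). Any interior
change month reproduces the table; six is fixed for determinism. The
14-month window is the shortest that observes both endpoints.

## Problem sizes

The default test run uses 500 random calendars for the brute-force
equivalence suite, 4,000 women for distributional spot checks, and 20,000
women (one Markov draw, about ten seconds) for the cohort-scale recovery
check; the worked-example pipeline (1,207 women) runs in well under a
second. These sizes give per-cell Monte-Carlo standard errors of under one
percentage point where stochastic agreement is asserted.

## Known limitations

- Only delimited-text input is read; native Stata/SPSS exports must be
  converted upstream.
- The reason-to-need mapping and the exact palette are conventions, not
  survey facts; both are configurable.
- No inference on matrix cells (no confidence intervals or design-based
  variance); the output is descriptive.
- Hazard/time-to-discontinuation modelling is out of scope; the pipeline
  complements such models rather than replacing them.
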