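# Methods

## Quantities and conventions

Biodistribution data are stored as **%ID/g** (percent injected dose per gram
of tissue), decay-corrected to injection time — the convention produced by
gamma counting against a standard of the injected dose with decay correction
applied. A study-level flag records this, and every dosimetry step
reintroduces physical decay explicitly (`×e^(−λ_phys t)`), so the physical
decay handling is auditable rather than baked into the stored numbers.

Times are hours internally; input files may declare `h` or `d` per row.
Summary tables use the sample SD (n − 1), appropriate for n = 4 animal
groups, and report-table rounding is one decimal place, half-up.

Contrast ratios are reported in both conventions because group tables can be
read either way: **mean-of-per-animal-ratios** (with its SD) is the default
displayed statistic, since study tables are per-animal means;
**ratio-of-means** is what recomputation from a published mean table yields
and is used when checking printed cells.

## Pharmacokinetic model

Each organ's *mean* curve (not per-animal curves) is fitted with a single
falling exponential `A(t) = a₀·e^(−λ_bio t)` by ordinary least squares on
log-transformed means — the classic linearization, chosen because it is
reproducible and has no starting-value sensitivity; a nonlinear-least-squares
refinement on the natural scale is available by flag (`method="nlls"`).
Non-positive means are excluded with a warning; two positive points are the
minimum; a flat curve yields λ_bio = 0 (slopes below 1e−12/h are treated as
round-off and set to zero).

Cumulated activity per unit injected activity (the residence time τ) comes
from one of two schemes, recorded per organ in every output:

* **monoexp** (closed form): τ = (a₀/100)/(λ_bio + λ_phys). Used when the
  fitted λ_bio ≥ 0.
* **hybrid** (trapezoid + tail): the decay-inclusive curve is integrated by
  the trapezoidal rule from t = 0 to the last timepoint, plus an analytic
  tail `y_end/λ_tail`. A single falling exponential cannot represent an
  organ still accumulating at late times (the tumor peaks around day 7 for
  the ¹⁷⁷Lu label); whenever the raw fitted λ_bio is negative the pipeline
  clamps it to zero for any closed-form use, keeps the raw value as a
  diagnostic, and switches to this scheme.

Hybrid choices: the t = 0 anchor is 0 %ID/g for tissues (they fill from
blood) and a log-linear back-extrapolation of the first two points for
blood; the tail rate is λ_phys (`tail="physical"`, default — the organ
retains activity and only decay removes it, conservative for dose) or the
terminal two-point effective slope floored at λ_phys (`tail="fitted"`).

## Mouse-to-human extrapolation

The percent-kg/g (relative organ mass) method scales each timepoint:

    %ID_human,organ(t) = %ID/g_mouse(t) · M_mouse(kg) · m_organ,human(g) / M_human(kg)

assuming species-invariant pharmacokinetics on the relative scale. The
scaled whole-organ curves then follow the same fit/integrate path as mouse
curves. A `direct` mode (no body-mass adjustment) exists for sensitivity
analysis. Default mouse body mass is 0.020 kg (typical for 6–8-week female
athymic mice; study reports rarely print it), overridable everywhere.

The packaged phantom is a 70-kg reference adult with Cristy–Eckerman
(ORNL/TM-8381) organ masses and ICRP-23 total blood mass (see the data-file
header); any `organ,mass_g` file with a `body_mass_kg` header replaces it.
Study organ labels map onto phantom organs through an extensible alias
table (`S.I.` → small intestine, etc.); unmappable organs are skipped with
a warning, and the xenograft tumor is excluded from the human source list
by default (a reference human carries no implanted tumor).

Remainder of body: τ_remainder = τ_total − Σ τ_organ, floored at zero.
τ_total comes from a whole-body retention curve when the study has one;
otherwise the physical-decay bound T½/ln2 is used with a logged warning
(conservative — it assumes everything not accounted for stays in the body),
except for an all-zero study where the total is zero.

## Dose engines

**Organ doses (MIRD schema).** D(target) = Σ_source τ·S. Without a user
S-value file the engine is *self-dose-only*: S_self = Δ̄_np/m, with Δ̄_np the
mean non-penetrating (electron) energy per decay and
1 MBq·h = 3.6 × 10⁹ decays. For ¹⁷⁷Lu (Δ̄_e = 147.9 keV, β plus conversion/
Auger electrons) this is the dominant dose term; cross-organ photon dose
(208 keV at 10.4 %, 113 keV at 6.2 %) is omitted, every report header says
so, and red-marrow or other cross-fire targets are reproducible only in
S-matrix mode. This keeps the package free of redistribution-encumbered
phantom S-value tables while remaining numerically faithful for a low-energy
β⁻ emitter. Nuclide constants (ICRP-107 values, rounded) live in an
editable YAML file.

**Whole-body dose** is the total residence time (sources + remainder) times
the self-dose factor of the body mass.

**Sphere tumor dose.** Dose factors are tabulated over unit-density spheres
of 0.01–6000 g (60 log-spaced points by default): factor(m) = Δ̄_np/m,
optionally scaled by a user-supplied electron absorbed-fraction curve
φ(m) ∈ (0, 1]. The default φ ≡ 1 (full local electron absorption, photons
escape) is the dominant physics for ¹⁷⁷Lu at the 0.1–1 g tumor masses of
interest; below ~0.05 g β escape becomes appreciable and a φ curve should
be supplied. Interpolation is a straight-line least-squares fit in
log(mass)–log(factor) over the k nearest grid points (default k = 4,
minimum 2) — *local* rather than global, which keeps the interpolant exact
on any power-law grid (the default grid is exactly ∝ 1/m) while still being
a least-squares fit on logarithmic values; k is configurable. Queries
outside the grid range raise unless extrapolation is explicitly allowed.

A consequence worth knowing: with φ ≡ 1 and %ID/g input the tumor dose is
independent of the tumor mass (per-gram cumulated activity × m × 1/m
cancels); mass dependence enters only through a non-trivial φ.

The headline tumor-dose computation — published ¹⁷⁷Lu tumor means, 12.95 MBq,
0.15 g — uses the hybrid scheme with the physical tail and yields 42.5 Gy;
the scheme label is recorded in the result for auditability. The fitted-tail
variant and the mono-exponential closed form remain one flag away, since
which tail and fit the original sphere-model estimate used is not derivable
from the published material.

## Synthetic data generator

The generator emulates a sacrificial biodistribution design: n animals per
timepoint (default 4), per-organ mean kinetics, and multiplicative
log-normal noise with mean 1 and configurable CV (biodistribution data are
positive and right-skewed; default CV 0.15, typical of inbred xenograft
cohorts). Per-organ random substreams (`default_rng([seed, organ_index])`)
make studies reproducible and insensitive to adding organs. The blocking
arm multiplies the target organ's curve by a fixed factor in [0, 1], so the
estimated remaining-uptake percentage converges to that factor × 100 as the
noise shrinks.

Mean-curve shapes: mono-exponential washout; uptake-washout
`A·(e^(−λ_out t) − e^(−λ_in t))` for organs filling from blood (tumor,
muscle); and a sum of two falling exponentials for blood — intact-IgG blood
kinetics show a fast distribution phase over a slow elimination phase that
no single exponential fits, so the blood presets are biexponential by
design. Presets `lu177-reference` (2 h–14 d) and `cu64-reference` (2–72 h)
are tuned so the tumor/blood/muscle mean curves lie within 2 SD of the
published means at every tabulated timepoint, with blocking multipliers
equal to the published remaining-uptake fractions (0.297 / 0.488) and
normal-organ curves whose spleen > lungs > liver integrated uptake mirrors
the published organ-dose ordering.

What the generator does *not* emulate: inter-animal correlation across
organs (each sample is independently noisy), weighing/counting error
structure, partial-volume or recovery effects, and any physiology linking
organs (no mass balance across compartments). Tests passing on synthetic
data therefore validate the estimation chain, not the biology of any
particular study.

Every generated study carries a `TruthRecord` with the exact closed-form
residence times and doses implied by the generating kinetics
(∫(c(t)/100)·e^(−λ_phys t) dt has a closed form for all three shapes), used
by the recovery tests: noiseless mono-exponential studies round-trip through
the full organ-dose chain to < 0.5 %, and 500 noisy replicates (6 timepoints,
n = 4, CV 0.10) recover λ_bio and τ with median relative error below 5 %.

## Numerical choices and degenerate inputs

* Sample SD with n = 1 is undefined and reported as NaN, not 0.
* Negative specific binding in the cell-binding formula is returned as-is
  with a warning (evidence of an assay problem should not be clamped away).
* All-zero organ curves integrate to zero residence time without fitting;
  an all-zero study yields an all-zero dose report.
* Duplicate (organ, animal, time) rows, missing columns, mixed units and
  empty files are schema errors naming the offending row; CLI exit codes
  are 0 (ok), 1 (data/schema), 2 (configuration).
* The problem sizes in the test suite (500-replicate recovery studies,
  dense-grid oracles of a few thousand points) were chosen as the smallest
  that make the statistical assertions stable; everything runs in seconds.

## Known limitations

* Self-dose-only organ dosimetry omits photon cross-fire; organ doses for
  photon-dominated targets (red marrow, gonads far from sources) need an
  S-matrix file.
* The percent-kg/g extrapolation assumes species-invariant kinetics; no
  allometric time scaling is applied.
* Mono-exponential fitting of means discards animal-level variance; no
  uncertainty is propagated into residence times or doses.
* The sphere model ignores non-spherical geometry, dose-rate effects and
  any radiobiological weighting.
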