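# Methods

## Normative model

Each bone parameter y is modelled against age x as a piecewise
constant-then-quadratic curve with breakpoint t\* (default 37 yr):
y(x) = ȳ for x ≤ t\*, and y(x) = a + bx + cx² for x > t\*, subject to
continuity and zero slope at t\* (b = −2ct\*, a = ȳ − bt\* − ct\*²). The
plateau encodes the assumption that densitometric and geometric
properties stabilize by early adulthood and decline progressively later;
the breakpoint sits at 37 rather than 40 because the reference cohort
contains no participants aged 38–40, and placing a knot inside an empty
age window would let the fit invent structure there. A quadratic — rather
than spline-based centile machinery such as LMS/GAMLSS — trades
flexibility for robustness on a cohort of a few hundred: it cannot
produce spurious trend reversals, at the cost of missing genuinely
non-quadratic features (e.g. accelerated perimenopausal loss).

The fit is two-stage. ȳ and σ_young are the mean and SD (n−1 denominator)
of the young group alone; holding ȳ fixed, the constraints reduce the
old-group problem to y = ȳ + c(x − t\*)², a linear least squares in the
single parameter c with closed form c = Σ(yᵢ−ȳ)(xᵢ−t\*)² / Σ(xᵢ−t\*)⁴.
Both constraints therefore hold exactly (verified to 1e−10 relative on
every constructed curve). The two-stage choice pins the plateau to the
young reference rather than letting old-group noise shift it, which is
the behaviour wanted from a *reference* curve; its cost is that
baseline-mean error propagates into ĉ with factor Σd²/Σd⁴ (d = x − t\*),
which dominates the curvature error when the young group is much smaller
than the old group.

Scores use the young-adult reference SD at all ages: T = (X − ȳ)/σ_young,
Z = (X − y(age))/σ_young. An age-varying dispersion is deliberately not
modelled (a single SD per stratum is all the reference data support); the
Z-score denominator is configurable in principle by substituting another
SD into the curve object. Band classification partitions the score axis
as green [−1, 2], yellow [−2.5, −1), red [−3.5, −2.5), below/above range
outside — half-open on the upper side of the negative bands so that every
score has exactly one class; the boundary values −3.5, −2.5, −1, 2 are
classified deterministically (closed on the side of the worse band for
negative boundaries, green owning −1 and 2).

## Monitoring statistics

Per stratum: μ, σ (n−1), CV = σ/μ; the short-term precision error
PE_st = 100·√(mean over participants of (sd_i/mean_i)²) over same-day
repeat scans, the RMS-CV estimator standard in densitometric
repeatability work (unbiased for the per-scan CV because each scan
carries independent error); the median annual change, defined as the
median over an integer age grid 38–92 yr of the relative slope
100·y′(x)/y(x); and the trend assessment interval
TAI = 1.8·PE_st/|annual change|, infinite (flagged "not assessable")
for a flat trend. The 1.8 margin is the short-term trend-assessment
factor of the monitoring literature; before adoption it was checked to
reproduce every published TAI in the shipped descriptive tables from the
corresponding printed PE and rate values within their input rounding.
The evaluation grid choice matters only weakly: the relative slope is
monotone in age for a sign-definite c, so the median equals the value at
the middle grid age (65 yr for the 55-point grid). Rounding to the
published 3 decimals happens only at serialization.

The shipped descriptive tables are printed to 2–3 decimals; consistency
checks therefore use interval arithmetic (half-ULP of each printed input)
and demand exact 3-dp agreement only where the input precision determines
a unique 3-dp result. Low-precision rows (e.g. cortical porosity, where
μ = 0.015 carries under two significant digits) are covered by the
interval check only.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
individual: 144 women and 237 men (configurable), ages uniform on
[20, 37] ∪ [41, 92] with per-sex young-group weights 54/144 and 60/237,
reproducing the empty 38–40 yr window; per parameter/sex/site a plateau
mean and SD taken from the published descriptive tables; a curvature
solved from the published median annual change by inverting the relative
slope at the grid-median age 65 (c = (r/100)·ȳ / (2d − (r/100)d²),
d = 65 − t\*), which makes generator-target and recomputed rate agree
exactly; additive homoscedastic Gaussian measurement noise (default SD =
the published cohort SD — the tables report one SD per stratum, not
age-resolved variance); and a precision subgroup (19 F, 20 M) whose scans
each carry independent multiplicative noise (1 + ε), ε ~ N(0, CV), so
that the RMS-CV precision error recovers the configured CV. Values are
clipped to their physical domain (densities > 0, ratios in [0, 1]); at
the shipped noise levels clipping is only ever active for cortical
porosity and negligibly biases its mean.

Each parameter draws from an RNG stream split deterministically from the
master seed (CRC of "sex|site|parameter" mixed into a SeedSequence), so
cohorts are reproducible and adding a parameter leaves others unchanged.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: cross-parameter correlation (real
microstructural parameters correlate strongly with densities; generated
ones are independent), age-dependent variance, non-quadratic age trends,
site-to-site coupling within a participant, measurement-error skew, and
scanner drift. Recovery tests demonstrate that the estimator recovers the
model's own truth at realistic noise, not that the model is true.

## Fabric-based material model

Elasticity: compliance assembled in the fabric principal frame with
E_i = E₀ρᵏm_i²ˡ, G_ij = μ₀ρᵏ(m_im_j)ˡ, ν_ij/E_i = ν₀/(E₀ρᵏm_iˡm_jˡ)
(symmetric by construction), Voigt order (11, 22, 33, 23, 13, 12) with
engineering shear strains, then inverted; symmetry is enforced to
round-off and positive definiteness asserted. Fabric eigenvalues are
normalized to m₁m₂m₃ = 1 on construction — the degree of anisotropy
m₃/m₁ is scale-free, so the convention is harmless and makes ρ carry all
density dependence. Defaults: trabecular E₀ = 10480 MPa, ν₀ = 0.2289,
μ₀ = 3350 MPa, k = 1.55, l = 0.82; cortical E₀ = 15992 MPa, ν₀ = 0.339,
μ₀ = 5846 MPa, k = l = 1 (an isotropic cortex by default; a transversely
isotropic cortex is obtained by supplying a fixed fabric with m₁ = m₂).

Yield: superposed quadric y(σ) = √(σ:F:σ) + f:σ − 1 in the fabric frame,
with per-axis coefficients pinned by the three calibration states —
uniaxial tension σ₀⁺, uniaxial compression σ₀⁻, pure shear τ₀ each
evaluate to exactly 0 (√B_i = (1/t_i + 1/c_i)/2, f_i = (1/t_i − 1/c_i)/2,
C_ij = 1/τ_ij²). Normal–normal interaction coefficients are set to zero:
the published constants do not determine them, and the chosen form is the
minimal convex criterion consistent with all nine calibration states per
compartment. The form is convex (norm plus linear) and objective under
joint rotation of stress and fabric frame. Strengths scale with ρᵏ and
m_iˡ like the elastic constants by default; both exponents are exposed
because the yield-specific exponents of the underlying criterion are a
calibration choice. Defaults: trabecular 62.01/78.58/31.83 MPa, cortical
71.00/124.20/41.30 MPa.

## Derived parameters

Rel.Ct.Th = Ct.Th/√(Tot.Ar/π) and apparent yield stress
σ_y = F_y/Tot.Ar (F_y converted kN → N exactly once, at this division;
result in MPa) are invariant under uniform scaling of the section —
the operational meaning of "size-independent". Mean diameter
D = 2√(Tot.Ar/π) assumes a cylindrical section. Apparent strain is
displacement over initial section length. Apparent stress is computed
per participant (ratio of that participant's force and area), not as a
ratio of cohort means. Tb.DA = m₃/m₁; the MSL→MIL power correction
DA_MIL = a·DA_MSLᵇ keeps (a, b) as configuration with identity defaults,
since those coefficients are scanner-generation calibration constants
rather than universal values.

## Numerical and testing choices

- Constraint residual tolerance 1e−10·max(1, |ȳ|); curve construction
  rejects violating coefficient sets.
- The closed-form curvature is cross-checked in tests against an
  independent bounded 1-D minimizer of the constrained SSE
  (scipy `minimize_scalar`, xatol 1e−14) to 1e−8 on 100 seeded datasets;
  the minimizer is never the implementation path.
- Degenerate designs (all old ages at t\*) and under-sized groups
  (< 2 young, < 3 old) raise fit errors; repeat scans are excluded from
  all reference fits and descriptive statistics.
- Recovery tests use 200 young + 200 old records per sex over 50 seeds:
  with the published noise the analytic error budget (direct term
  σ/√Σd⁴ plus baseline propagation Σd²/Σd⁴·σ/√n_young) predicts a
  median relative curvature error of 5–7%, comfortably inside the 10%
  acceptance bound while keeping the whole suite under a few seconds.
- A participant aged exactly t\* belongs to the young group.
- Infinite TAI serializes as an empty cell plus a `not_assessable` flag,
  never a sentinel number.

## Limitations

The quadratic decline cannot represent menopause-related acceleration or
late-life plateaus; the constant young SD understates dispersion growth
with age if present; generated cohorts are statistically idealized (see
above); the cortical density-to-ρ conversion for the material model and
the MSL→MIL coefficients are user-supplied calibration inputs; and the
yield quadric beyond its nine calibration states follows the chosen
zero-interaction form, which is one convex completion among several.
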