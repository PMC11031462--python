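# Methods

## Optical model

All computations live in the paraxial (Gaussian) domain. The working
representation is the vergence `V = n/l` in dioptres (`l` = signed distance
from wavefront to focus in metres, `n` = index of the current medium), with

* refraction at a surface of power `P` (dpt): `V' = V + P`,
* transfer over `d` mm in index `n`: `V' = V / (1 − (d/1000/n)·V)`.

Sign convention: light travels left → right, distances positive rightward,
radii positive when the centre of curvature lies right of the vertex,
vergence positive = converging. Under this convention a meniscus PIOL
(convex front, concave back, both curving toward the cornea) has two
*positive* radii: the front surface power is positive, the back negative.
Geometry is mm at every API boundary; conversion to metres happens only
inside the vergence/matrix arithmetic. Flat surfaces are a dedicated
sentinel (`FLAT`), not an infinite radius, to keep float overflow out of the
arithmetic.

Every element chain can also be collapsed to a 2×2 ray-transfer matrix in
the reduced-angle convention (rays `(y, n·u)`, elementary matrices
`[[1, d/n], [0, 1]]` and `[[1, 0], [−P, 1]]`, hence `det = 1` exactly).
Vergence propagation and the bilinear matrix map
`V' = (D·V − C)/(A − B·V)` must agree to 1e−9 dpt; the test suite enforces
this on randomized systems. The matrix route is an *oracle only* — the eye
model never computes through it.

Thick lenses reduce via the Gullstrand equation
`P = P1 + P2 − (t/n_lens)·P1·P2` (reduced thickness in metres) and the
principal-plane offsets `h = n_before·t·P2/(n_lens·P)` from the front
vertex, `h' = −n_after·t·P1/(n_lens·P)` from the back vertex; the
equivalence of the thick lens and the thin-lens-between-principal-planes
reduction is asserted against the matrix oracle.

## Scenarios and the REF/ΔM computation

Four scenarios combine thick/thin models of cornea and PIOL (A thick/thick,
B thin cornea, C thin PIOL, D thin/thin). The thin cornea is a single
surface of keratometric power `PC = (n_K − 1)/RC_a`, `n_K = 1.3375`, at the
corneal front vertex with aqueous (`n_A = 1.336`) directly behind it — this
keeps ACD-referenced axial distances meaningful. The thick cornea uses
`n_C = 1.376`. The PIOL is immersed in aqueous on both sides (it sits in
the posterior chamber between iris and crystalline lens); its labelled
power is verified as the equivalent power in aqueous to 1e−6 dpt for every
design the package emits.

The implant plane `SLPOS = ACD − vault` is referenced to the corneal front
vertex in all four scenarios (equivalently `AQD − vault` behind the corneal
back vertex; both accessors exist and are algebraically identical because
`ACD = AQD + CCT` holds exactly). In the thick-PIOL scenarios the *back
vertex* of the lens sits at SLPOS, so the aqueous gap from the corneal exit
is `AQD − vault − PIOLT` (scenario A) or `ACD − vault − PIOLT` (scenario B).

REF: a plane wave (object at infinity, fully corrected pseudophakic state)
is propagated through the postoperative chain to just behind the PIOL,
giving `V_SLPOS`; the preoperative chain (cornea only) is then inverted
from SLPOS back through the vertex distance to the spectacle plane. Both
directions are exact closed-form vergence algebra, so re-substituting REF
forward reproduces `V_SLPOS` to machine precision — that re-substitution is
a standing invariant of the test suite.

ΔM multiplies the per-refraction ratios `V/V'` over refracting surfaces
only (translations cancel out of lateral magnification): preoperatively
spectacle + cornea, postoperatively cornea + PIOL, both fully corrected.
With the object at infinity the first incoming vergence is zero in both
chains; the 0/0 pair is cancelled symbolically, which equals the finite-
object limit. The implementation is validated against an object at 10⁶ m,
agreeing to 1e−6 on the dimensionless magnification-ratio scale (the
percent scale carries an O(VD/L) bias of ~1e−6 % at that distance, which is
the finite-distance approximation error, not an implementation tolerance).
`REF = 0` exactly (zero-power thin implant) would make the spectacle factor
0/0; the limit is no magnification change, and ΔM is returned as 0 there.

Defaults: vault 0.4 mm (manufacturer's target clearance to the crystalline
lens), vertex distance 12 mm for cohort work; the packaged clinical example
uses 14 mm, the customary refraction-lane distance it was stated with. Both
are plain configuration.

## Surrogate design family

The true ICL radius/thickness schedules exist only as patent drawings and
are not digitized here; loading a real table via `read_design_csv` is the
supported route for exact design data. The shipped surrogate family is
calibrated once, a priori, to preserve the behaviours that the published
analysis derives from the real designs:

* material index fixed at the back-calculated consensus `n = 1.4490`;
* 58 steps at −17.0 (0.5) −3.0 and 3.0 (0.5) 17.0 dpt;
* central thickness 0.2 mm for all minus lenses (minus ICLs are thin, which
  is why the thin-lens model is nearly exact for them), rising affinely
  from 0.2 mm at +3 dpt to 0.6 mm at +17 dpt — this reproduces a thin-lens
  REF error that grows with plus power to ≈0.5 dpt (0.43 dpt at +17 on the
  clinical-example eye);
* front radius falling affinely with power from 12 mm at −17 dpt to 6 mm at
  +17 dpt (within the physically plausible 6–12 mm optic-zone band); the
  back radius of every step is solved from the labelled power.

The affine schedules are the simplest family meeting those constraints; the
6 mm endpoint additionally guarantees `P1 > P·n_lens/n_A` at every plus
step, which is the condition for the image-side principal plane to lie in
front of the *front* vertex for plus lenses (behind the *back* vertex for
minus lenses — automatic for a converging front surface). Both placements,
and the growth of the principal-plane distance toward low powers, are
asserted for all 58 steps.

Back-calculations: the index solves a quadratic (two admissible roots can
exist; the smaller, material-plausible one is taken and verified by
re-substitution to 1e−9 dpt); the back radius is closed-form,
`P2 = (P − P1)/(1 − (t/n)·P1)`, rejecting non-meniscus results.

## Synthetic cohort

The reference population is known only through descriptive statistics
(N = 2365 eyes after preprocessing; means/SDs per parameter). The generator
draws `(RC_a, RC_p, CCT, AQD, LT)` from a multivariate normal with those
marginals, truncated by rejection at ±3 SD per parameter and at the
manufacturer's implantation floor AQD ≥ 2.8 mm; `ACD = AQD + CCT` is set
exactly and `PC` derived. The AQD floor sits 1.37 SD below the mean, so the
realized AQD mean is inflated by the one-sided truncation shift (+0.04 mm);
the test suite checks it against the closed-form truncated-normal
expectation rather than the nominal mean.

Correlations are not published. Defaults: `corr(RC_a, RC_p) = 0.9` (front
and back corneal curvature track each other), `corr(AQD, LT) = −0.3`
(deeper chambers, thinner lenses), all others 0 — configurable, and the
regression results of interest are insensitive to the choice because REF
and ΔM are near-deterministic functions of the predictors. What a green
cohort test establishes is marginal/correlation fidelity and determinism;
the generator does not emulate axial-length structure, age/sex strata,
measurement noise, or the left/right-eye correlation of real exports (the
synthetic generator emits one eye per notional patient; the random one-eye
selection and deduplication rules apply to real CSV ingest only).

## Regression study

For scenarios A and B (thick-lens PIOL; the thin-PIOL scenarios are
excluded because their REF bias at plus powers makes them unsuitable as a
prediction target), the cohort × 58-step grid of REF and ΔM feeds a
bidirectional stepwise OLS: start from the constant model, add the excluded
term with the smallest two-sided t-test p-value while p ≤ 0.01, then drop
included terms with p ≥ 0.1, to convergence. Candidates are the linear
terms (scenario A: RC_a, RC_p, CCT, ACD, LT, PIOLP; scenario B: PC, ACD,
LT, PIOLP) and, for degree 2, their squares — no interactions. Exact
p-value ties resolve by lexicographic candidate order, for determinism.
Whether single-term p-values come from t-tests or partial F-tests is
immaterial (they coincide for one added coefficient); t-tests are used.

Performance is reported **in-sample** (residual RMSE, adjusted R², F vs the
constant model), matching how shortcut formulas of this kind are quoted.
All coefficients are refit per model; the linear and quadratic models
therefore share linear coefficients only up to sampling noise (the power
schedule is symmetric, making PIOLP and PIOLP² orthogonal over the grid, so
the shared-coefficient property holds to high accuracy anyway).

On the default synthetic cohort (1000 eyes, seed 1) the scenario-A numbers
computed by `scripts/acceptance.py` are: linear REF RMSE 0.807 dpt with
PIOLP coefficient 0.827; quadratic REF RMSE 0.189 dpt with PIOLP²
coefficient −0.00922; linear ΔM RMSE 1.228 % with PIOLP coefficient
−1.210. The dominant linear-model error is the curvature of REF in PIOLP
(the principal-plane displacement of the thick implant adds a systematic
quadratic component), which is why the quadratic term removes ~75 % of the
residual.

## Numerical choices and limitations

* Exact closed forms throughout; no iteration, no tolerances except where
  stated (design label identity 1e−6 dpt; oracle agreements 1e−9).
* Focal singularities (a wavefront focusing exactly on a target plane) and
  impossible geometry (PIOL front vertex ahead of the corneal exit, i.e.
  `AQD − vault − PIOLT < 0`) raise typed errors rather than returning
  infinities.
* Paraxial only: no astigmatic/toric meridians (meridian radii are averaged
  on ingest), no wavefront aberration, no chromatic dispersion, no
  non-paraxial ray tracing — at large ray angles the vergence scheme is
  known to lose accuracy.
* The vault is a fixed configuration value, not predicted from biometry.
* Magnification is relative (percent change), not absolute retinal image
  size.
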