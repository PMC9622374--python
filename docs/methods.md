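# Methods

## Coordinate system and sign conventions

The optical axis is `z`, the origin is the anterior corneal apex, distances
are millimetres and light travels toward +z. A surface radius is positive
when its centre of curvature lies toward +z, so a normal cornea has two
positive radii and a biconvex IOL has a positive front and negative back
radius. Surfaces are conics of revolution `z = c r² / (1 + √(1−(1+k)c²r²))`;
a clinically reported corneal eccentricity `e` maps to the conic constant
`k = −e²` (prolate flattening). Reported eccentricities can be negative
(oblate steepening); the squared mapping deliberately uses only the
magnitude, which slightly understates oblate corneas — a documented
simplification, not an oversight worth a sign convention of its own, since
the paraxial refraction is independent of `k` and the spot metric is only
weakly sensitive at a 3 mm pupil.

## Exact ray tracing

Ray–conic intersection uses the implicit quadric
`c(x²+y²) + c(1+k)Z² − 2Z = 0`: a numerically stable closed-form quadratic
selects the forward root on the apex sheet, and for aspheres (k ≠ 0) the
root is polished by Newton iteration to 1e−12 mm (at most 50 steps; in
practice one). Refraction is the vector form of Snell's law with an
explicit total-internal-reflection error. There is no randomness anywhere
in the tracer, and the ray fan is a fixed hexapolar pattern (centre point
plus `n_rings` rings of 6·i points; 127 rays at the default 6 rings), so
every result is bit-reproducible.

Two independent Gaussian reductions accompany the exact tracer:

- `paraxial_power` — a 2×2 refraction/translation matrix cascade giving
  equivalent power, focal distances and principal planes;
- `paraxial_refraction` — a backward vergence cascade from the image plane
  to the spectacle plane, giving the closed-form refraction of the eye.

These share no code with the exact tracer and serve as oracles in the test
suite: at a 0.2 mm pupil the exact search agrees with the vergence cascade
to better than 0.02 D across synthetic cohorts.

## Segmented axial length

SS-OCT biometers display an ultrasound-compatible axial length computed
with a composite group index of 1.3496 after the linear device calibration
`0.9573·AL + 1.3304`. The segmentation inverts this: the total optical path
is reconstructed, the corneal (1.376), aqueous (1.336) and lens optical
paths are subtracted, and the remainder divided by the vitreous index
(1.338) is the vitreous geometric depth. As typeset in its source the
vitreous term *adds* the segment optical paths; that reading yields a
vitreous depth longer than the whole eye, so the physically meaningful
subtraction is implemented. The displayed lens thickness is converted with
`n_lens/1.426`, where 1.426 is taken to be the device's display index for
the lens segment (implemented as printed; its provenance is not documented
publicly). For nuclear cataracts strictly above LOCS III grade 3 the lens
index 1.450 replaces 1.410 in both lens terms; the two substitutions nearly
cancel, leaving a net step of about −9 µm at the threshold. The
ELM-to-retinal-pigment-epithelium offset defaults to 0 mm (no public value
exists) and is configurable within ±0.2 mm.

The result is linear in the displayed AL with slope
`1.3496·0.9573/1.338 ≈ 0.9655` (exact by construction), and setting every
constant to 1 collapses the formula to the identity — both are tested.

## IOL depth (effective lens position) model

The implant's resting depth is modelled as an additive linear function of
segmented AL, the preoperative lens-centre plane (LT/2 + AQD), the
angle-to-angle depth and the lens-equator depth, fitted by OLS with an
intercept. The published model lists the same four regressors but prints no
operators or coefficient values; an additive multiple regression is the
standard form for IOL-depth prediction and is the interpretation adopted
here. Shipped default coefficients (a=0.10, b=0.20, c=0.15, d=0.40,
e=−1.4595) are chosen so that the synthetic population mean maps to the
population-mean IOL depth of 4.14 mm with a predicted-depth SD of ~0.22 mm;
they are simulation artifacts, clearly labeled non-clinical. With 0.11 mm
of depth noise at n = 315 the in-sample fit quality lands at MAE ≈ 0.09 mm
and R² ≈ 0.8, the regime reported for OCT-based depth prediction on real
eyes of this population size.

## Predicted refraction and power selection

For each candidate power the four-surface eye (cornea front/back, IOL
front/back; media air / 1.376 / 1.336 / n_IOL / 1.338) is assembled with
the IOL front apex at `CCT + predicted depth` and the image plane at the
segmented AL. The thin capsule is ignored and aqueous assumed between
cornea and IOL. The predicted refraction is the spectacle sphere (ideal
thin lens 12 mm before the cornea — the ophthalmic vertex convention)
minimising the RMS spot radius of a parallel hexapolar fan on the image
plane. The objective is unimodal in the sphere, so a golden-section search
on [−30, +30] D to 1e−4 D is used; pupil diameter defaults to 3.0 mm
(photopic). Refractions are reported raw; any 0.125 D rounding happens only
when synthetic manifest refractions are generated. Power selection takes
the table row closest to the target refraction, breaking ties toward the
higher power (the myopic side, the conventional clinical choice).

Useful sensitivities at the population mean, from the vergence oracle:
+1 mm of axial length ≈ −2.6 D of spectacle refraction; +1 mm of IOL depth
≈ +1.3 D; adjacent 0.5 D IOL steps ≈ 0.35 D at the spectacle plane.

## Synthetic data

The cohort generator draws a truncated multivariate normal over 13
biometric fields whose means, SDs and truncation ranges describe a typical
cataract-surgery population (AL 24.31 ± 1.54 mm in [21.33, 29.82], CCT
0.545 ± 0.032 mm, AQD 2.69 ± 0.41 mm, LT 4.68 ± 0.39 mm, ATA 3.25 ± 0.21 mm,
LE 4.14 ± 0.32 mm, nuclear grade 2.2 ± 0.4, corneal radii/eccentricities to
match). Correlations are literature-informed assumptions (AL–AQD +0.45,
AL–LT −0.30, AQD–LT −0.55, ATA–AQD +0.50, LE–AQD +0.60, 0.1 elsewhere);
that nominal matrix is very slightly indefinite, so it is projected to the
nearest well-conditioned correlation matrix (eigenvalue floor 0.01,
unit-diagonal rescale — entries move by less than 0.02). Rejection sampling
enforces the truncation ranges; truncation shifts the AL mean up by
~0.1 mm, still inside the 3-standard-error band asserted in the tests.

IOL geometry is an equi-biconvex stand-in (real per-power geometry is
proprietary): for each labeled power the radius is solved by bisection so
the thick-lens Gaussian power in aqueous equals the label to 1e−6 D, with
centre thickness 0.55 + 0.015·P mm and index 1.55 (hydrophobic acrylic).

Outcome simulation draws the true IOL depth from the linear model plus
Gaussian noise (default 0.11 mm), selects the implanted power toward a
−0.25 D target using the noise-free predicted depth, computes the true
refraction by the exact tracer at the true depth, and quantises the noisy
manifest refraction (default noise 0.25 D) to 0.125 D phoropter steps.
Power selection uses a closed-form vergence pre-screen to shortlist
candidates before the exact trace decides — the refraction table is
strictly monotone in power, so the selection is identical to scanning the
full exact table. Default problem sizes in the tests (cohorts of 50–315,
100 eyes for the closure and equivalence checks, 1000 bootstrap replicates)
were chosen as the smallest sizes at which the stochastic assertions are
stable.

What passing these tests shows: the tracer, segmentation, regression and
statistics are internally consistent and correctly calibrated against
closed-form oracles. What it cannot show: that the depth model or the
synthetic IOL geometry match real anatomy or a real lens — clinical
accuracy claims require the real cohort and manufacturer geometry, which do
not ship here. The generator also ignores surgically induced corneal
change, capsule contraction over time and inter-device measurement drift.

## Statistical procedures

- SD uses the n−1 denominator; band percentages are inclusive (|e| ≤ 0.25,
  0.50, 1.00 D).
- Zero-adjustment subtracts each formula's mean error (SD invariant).
- SD comparison between paired formulas: two-sided paired percentile
  bootstrap on ΔSD of zero-adjusted errors (default 10 000 resamples, fixed
  seed, +1 continuity on the counts). The historical "heteroscedastic test"
  procedure is not publicly reproducible; the bootstrap is this package's
  documented stand-in, and its type-I error calibrates to 5 % ± 2 % on
  correlated equal-variance pairs.
- Friedman and Cochran Q are implemented from their rank/count formulas
  (average-rank tie correction; Q reduces to the uncorrected McNemar
  statistic at k = 2) and cross-checked against scipy and statsmodels.
- Sample size for a two-group mean comparison iterates the per-group n
  upward under the exact noncentral-t power function; Δ = 0.25 D with
  SD 0.5 D at α = 0.05 / power 0.80 gives 128 eyes in total.

## Known limitations

Spherical-equivalent only (steep/flat corneal radii are averaged; no toric
planning). No IOL tilt/decentration, no wavefront or chromatic effects, no
Stiles–Crawford apodization, no post-refractive-surgery corneas. The
keratometric-vs-Gaussian corneal power gap asserted in the tests
(0.3–1.3 D) holds on the modelled population's Gullstrand ratios
(posterior/anterior ≈ 0.82–0.85) and anterior radii within ±2 SD of the
mean; flatter ratios push the gap above that band, which is a property of
the 1.3375 convention itself, not of this implementation.
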