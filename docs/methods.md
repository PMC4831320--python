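# Methods

## Model

Each encoder ("model unit") is a divisively normalized difference of
Gaussians evaluated at a single point.  For a luminance image `f` on a
square lattice with a center pixel at the origin,

    r = Σ f·(g_c − g_s)  /  Σ f·g_n

where `g_c`, `g_s`, `g_n` are 2D Gaussians with standard deviations σ_c
(center, the fixed reference scale, 1.0 in internal units), σ_s
(antagonistic surround) and σ_n (normalization pool), each sampled at
pixel centers and renormalized to discrete sum exactly 1.  Because image
and filter share one lattice, the "convolution" reduces to a dot product
at the center — the model is purely spatial and produces one scalar per
stimulus.  Half-wave rectification then defines the ON response
`max(r, 0)` and the OFF response `max(−r, 0)`; no additional output
nonlinearity exists, so every ON/OFF asymmetry the package measures is
created by the divisive stage.

Two consequences are exact on the lattice, by construction:

* a uniform image gives r = 0 (both DoG Gaussians sum to exactly 1 after
  discrete renormalization, so the numerator annihilates constants);
* scaling the image by any α > 0 leaves r unchanged (numerator and
  denominator are both homogeneous of degree 1) — contrast constancy
  within a polarity.

The discrete renormalization is why kernels are not left at their
analytic normalization 1/(2πσ²): it makes these two qualitative claims
hold to machine precision rather than only up to truncation error.

## Stimuli and rasterization

Contrast responses use uniform disks of diameter 4σ_c at Weber contrast
c = 100(d − b)/b between −100% and +100% on a uniform background (50 by
default; the choice is irrelevant by scale invariance, and the test suite
checks 50 vs 100 explicitly).  Luminance responses use uniform squares of
width 4σ_c whose *absolute* luminance is varied on one of three fixed
backgrounds — 2, 61 and 120 cd/m² — so that, unlike the disk sweeps,
responses on different backgrounds correspond to different Weber
contrasts.

Rasterization is a pixel-center membership test at a configurable
resolution (default 16 px/σ_c), with one refinement: a pixel whose center
lies *exactly* on the stimulus boundary receives weight 1/2 (squares use
the product of two 1D memberships, so corner pixels get 1/4).  The
stimulus half-extent (2σ_c) falls exactly on pixel centers at every
power-of-two resolution; a strict inside test would then shrink the
footprint by half a pixel per side — a systematic O(h) bias that
dominates the discretization error, worst for squares whose entire edge
is affected.  The tie rule is the midpoint-rule-consistent convention (a
cell centered on the boundary is half inside) and restores clean
convergence: rasterized responses agree with the closed forms below to
0.3% (disks) and 0.04% (squares) at 32 px/σ_c, versus 3% for squares
with the strict rule.  Generic pixels remain binary; no general
anti-aliasing is performed.

The default lattice half-width is 5 × the unit's largest σ, leaving
truncated Gaussian mass below 1e−5 even for σ = 6σ_c.  Family sweeps put
every unit on one shared lattice so that statistics that mathematically
depend only on σ_n (all the per-unit ratio statistics — the DoG mass
cancels) are exactly constant across σ_s instead of merely within
truncation error.

## Closed-form oracles

For a uniform figure of luminance d on background b the image is
`b + (d − b)·mask`, so in the continuum limit

    r = (d − b)·A / (b + (d − b)·L)

with A = M_c − M_s and L = M_n, where M_σ is the Gaussian mass inside the
footprint: `1 − exp(−R²/2σ²)` for a disk of radius R and
`erf(h/σ√2)²` for a square of half-width h.  These closed forms are the
independent oracle for the rasterized pipeline; equating the two across a
deterministic grid of units and contrasts (and verifying first-order or
better convergence as the resolution doubles) is part of the test suite.
The same affine structure gives the sweeps an exact fast path: the two
discrete footprint masses (kernel·mask dot products) determine the
response to every contrast on that footprint, bit-compatibly with
rendering each image, at a fraction of the cost.

## Derived statistics

* **Contrast response functions** are sampled at 1% steps from 0 to 100%
  (ON from increments, OFF from decrements).  The step is fine enough
  that finite-difference slopes at 5% contrast are stable.
* **Nonlinearity index**: log10 of the CRF slope at 50% contrast over the
  slope at 5%, slopes by central finite differences on the sampled curve;
  positive = accelerating.  The log base is a reporting choice — the
  OFF > ON ordering, which is the scientifically meaningful claim and is
  asserted for every evaluation contrast from 20 to 90%, is
  base-invariant.
* **OFF/ON ratio at 100% contrast** equals (1 + L)/(1 − L) in the
  continuum limit and therefore depends only on σ_n.  It ranges from
  ~1.11 (σ_n = 6σ_c) to ~13.7 (σ_n = σ_c) across the canonical family.
  The σ_n = σ_c endpoint is near-degenerate — a −100% disk is truly
  black, leaving only the far Gaussian tail in the pool — so it is
  resolution-sensitive; it is included (with an annotation in the
  population table) rather than excluded.
* **Luminance response functions** sample 60 evenly spaced targets from
  the background to the extreme (2 for OFF, 120 for ON), both endpoints
  included.  **Rmax** is the rectified response at the largest presented
  luminance contrast.  **L50** is the target at which the response first
  reaches Rmax/2, located by linear interpolation between samples and
  expressed as a proportion of the sampled |target − background| range.
  Interpolation makes the statistic insensitive to the exact sampling
  density.
* **Population background ratios**: per unit, OFF light/gray (120/61)
  and ON dark/gray (2/61) ratios of L50 and of Rmax, aggregated across
  the 42 units by the arithmetic mean (a config option allows the
  median, which gives visibly different values for the strongly skewed
  ON ratios).  Typical values at the defaults: OFF L50 ≈ 1.0, ON L50 ≈
  0.135, OFF Rmax ≈ 1.05, ON Rmax ≈ 5.0.

## Cone adaptation module

`V = I_b/(I_b + I_a)` with I_a both the adaptation level and the
half-saturating intensity, so V(I_a) = 1/2 is the baseline.  The
contrast-domain curves are computed with intensities expressed in units
of I_a, making their independence from the adaptation level exact by
construction (the two default adaptation levels, 10 and 100, are
arbitrary for this reason).  The depolarizing (dark) branch |V − 1/2| is
convex in contrast magnitude and the hyperpolarizing (bright) branch
concave, with magnitudes 1/2 and 1/6 at 100% contrast — a 3:1
dark/bright asymmetry mirroring the spatial model's OFF/ON asymmetry.

## Degenerate inputs and numerical guards

The response is undefined when the normalization output is not positive.
The guard raises (never clamps) when the denominator falls below
1e−12 × the background level; an all-black image is the canonical case.
Family sweeps record per-unit failures in a `note` column and continue.
Slope-based indices report NaN when a finite-difference slope is not
positive rather than guessing a sign.

## Scope and limitations

The model is spatial only: no temporal filtering, spike generation,
noise, or parameter fitting to neural data.  ON responses to dark
contrasts and OFF responses to bright contrasts are outside the model by
construction (each polarity sees only its own sign of r).  The model
predicts OFF slopes ≥ ON slopes at *all* contrasts, so reports of higher
ON sensitivity at low contrast are outside what this normalization
mechanism can produce — a genuine limitation, not a bug.  Because the
package generates all of its own stimuli (uniform figures on uniform
backgrounds), passing tests demonstrate the internal consistency of the
model and its statistics, not agreement with any particular neural
dataset; empirical ON/OFF populations differ in ways this model
deliberately omits (e.g. the ON Rmax background ratio of real LGN cells
is near 1, while the model's is ~5).
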