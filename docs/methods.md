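# Methods

## Physical model

A light absorber irradiated by an intensity-modulated beam heats and
expands periodically, radiating a monochromatic pressure wave (the
photoacoustic effect).  For a 2D absorber with interior sound speed `vs`
and density `rho_s` in an ambient fluid (`vf`, `rho_f`), the complex
pressure amplitude `psi` obeys a Helmholtz equation with a heat-deposition
source inside the absorber,

    lap psi + ks^2 psi = i*omega*mu*beta*I0/Cp       (inside, ks = omega/vs)
    lap psi + kf^2 psi = 0                           (outside, kf = omega/vf)

with continuity of pressure and of normal particle velocity
`(1/rho) d(psi)/dr` at the boundary.  `mu` is the optical absorption
coefficient, `beta` the isobaric thermal expansion coefficient, `I0` the
light intensity and `Cp` the specific heat; all four default to one
(dimensionless working units), so field amplitudes are reported in those
units, not pascals.  The interesting physics is in the sound-speed contrast
`c_hat = vs/vf`: a nonzero contrast makes each absorber an acoustic
scatterer of every other absorber's wave.

## Exact disk solution and the discrete-particle approximation

For a single disk of radius `a` the equation separates in polar
coordinates.  With `A = i*mu*beta*I0*vs/Cp`,
`rho_hat = rho_s/rho_f` and the boundary determinant

    D = J1(ks a) H0(kf a) - rho_hat*c_hat*J0(ks a) H1(kf a)

(`Hn` the outgoing Hankel function of the first kind), the field is

    psi_s(r) = (A/ks) * [1 + rho_hat*c_hat*J0(ks r) H1(kf a) / D]   r <= a
    psi_f(r) = (A/ks) * J1(ks a) H0(kf r) / D                       r > a

The `(A/ks)` prefactor is the particular (volumetric heating) solution;
the `J0` term is the homogeneous correction that enforces the boundary
conditions.  Both branches reduce to `(A/ks) J1(ks a) H0(kf a)/D` at
`r = a`, and the normal-velocity match can be verified analytically from
`J0' = -J1`, `H0' = -H1`.  The published rendering of the interior
solution is typographically ambiguous about what divides by `D`; the form
above is the unique reading satisfying both boundary conditions, which we
verified symbolically and enforce in tests to 1e-6 (pressure) and 1e-4
(velocity, by central differences).

For a dilute collection of N disks the discrete particle approach (DPA)
sums the exterior solutions of the individual disks at the field point.
It is exterior-only and, by construction, single-scattering: the wave
emitted by one cell is not re-scattered by another.  The difference
between DPA and the full-wave solver below is therefore a direct measure
of multiple scattering.

## Convergent Born series

Adding a damping term `i*eps` to the background and compensating inside
the scattering potential turns the pair of equations into one
inhomogeneous problem on the whole plane,

    (lap + kf^2 + i*eps) psi = -S - V psi,
    S = -i*mu*beta*I0*omega/Cp   inside sources, 0 outside
    V = ks^2 - kf^2 - i*eps      inside sources, -i*eps outside.

The damped background Green's function is diagonal in Fourier space,
`g(p) = 1/(|p|^2 - kf^2 - i*eps)`, giving the fixed-point form
`psi = G(V psi + S)` with `G = IFFT . g . FFT`.  Plain iteration (the
traditional Born series) converges only for weak, small scatterers; the
convergent Born series preconditions the iteration with
`gamma = (i/eps) V`:

    psi_0     = gamma * G S
    psi_{l+1} = psi_l - gamma * (psi_l - G(V psi_l + S))

which converges for arbitrary contrast whenever
`eps >= max|ks^2 - kf^2|`.  (Some renderings of the preconditioner print
it as `i*eps*V`; only `(i/eps)V` makes the leading correction term of the
update `(i/eps)V psi` and reproduces the series of the original CBS
literature, so that is what is implemented.)  At the fixed point the
`i*eps` contributions of the left side and of `V` cancel identically, so
the converged field solves the *undamped* physical problem; the damping
only shapes the path to it.  We use `eps = 0.8 kf^2`, which covers every
contrast between vs = 1200 and 1950 m/s in a 1500 m/s ambient
(`|c_hat^-2 - 1|` at most 0.5625) and implies an effective background
attenuation `alpha = eps/(2 kf) = 0.4 kf` — about 122.8 Np/cm at
7.32 MHz — that localizes the Green's function within the domain.

### Discretization

The domain is a square lattice of `n x n` pixels of pitch `h` (defaults
n = 2048, h = 100 nm, i.e. 204.8 um per side).  Pixel `i` sits at
`(i - n/2) h`, so a disk at the origin is centered exactly on a lattice
point; this matters because the convergence metric and all profile
comparisons run along the lattice row through the center, and a
half-pixel offset between that row and the disk center measurably
degrades the match to the analytic solution at high frequency.  A pixel
belongs to a disk iff its center lies within the disk radius (no
anti-aliasing; the boundary-pixel ambiguity is O(h/a) ~ 4% of the rim).
`g` is evaluated on the FFT-native lattice `p = 2*pi*m/(n h)`; forward
and inverse transforms are mutually inverse (no extra pixel-area scaling,
matching the update formulas as written).

### Absorbing boundary layer

The FFT imposes periodic boundaries, so outgoing waves would wrap
around.  A frame of thickness `d` pixels (default 500) multiplies the
field after every update with a separable sigmoid profile per axis,
`1/(1 + exp(-kappa (x - d h/2)))` with `x` the physical distance from the
outer boundary and `kappa = 61.36e2 Np/cm`; the interior
`(n - 2d)^2` region is untouched (window exactly 1).  The profile is 0.5
mid-frame and ~2e-7 at the outermost pixel; after convergence the edge
field is below 1e-3 of the interior peak (asserted in tests).  Corners
take the product of the two axis profiles; the taper is applied to the
initial field as well as to every iterate, and the convergence error is
evaluated on the field actually carried forward (i.e. after the window).

### Convergence monitoring

After each update the relative change of the center row `c = n/2` (1-based;
0-based index `n/2 - 1`) is

    err = sum_m |psi_new(c,m) - psi_old(c,m)| / sum_m |psi_old(c,m)|

and iteration stops when `err < 1e-4` (at most 2000 iterations; hitting
the cap returns the field flagged unconverged with a warning rather than
raising).  Iteration counts reported anywhere are the number of update
applications performed.  The traditional-series solver shares all
machinery minus the preconditioner and flags divergence when the error
grows for 10 consecutive iterations, exceeds 1e6, or overflows.

Every frequency is solved independently (eps, g, V, gamma all depend on
kf), so sweeps are embarrassingly parallel but are run serially here.

## Phantom generation

A blood smear is modelled as N equal disks of radius 2.75 um at a target
area fraction (2D hematocrit) inside a square or circular region of
interest (ROI).  N is the smallest integer whose disk area reaches the
requested fraction of the ROI area — 133 for 40% of a 50 um-radius
circle.  Positions are continuous: disks are thrown down uniformly at
random (overlaps allowed), each overlapping pair is charged 1000 kB*T,
and single-disk teleport proposals (fresh uniform position) are accepted
by the Metropolis rule on the energy change — always for decreases, with
probability `exp(-dE)` otherwise, which at 1000 kB*T per pair effectively
forbids creating overlaps while always accepting their removal.  The
chain stops when the energy is exactly zero (an integer pair count, so no
tolerance is needed).  Overlap is strict (`distance < a_i + a_j`);
tangency is legal.  Disks are kept fully inside the ROI by sampling
centers from the radius-eroded region, consistent with the 133-disk
arithmetic.  Energies are stored in kB*T units (no physical temperature
exists in the model).  Everything is deterministic given the seed;
ensemble realization `i` uses `base_seed + i`.

At 40% coverage the acceptance probability of a teleport into an
overlap-free position is roughly `exp(-4*phi/(1-...)) ~ 0.2`, so chains of a
few hundred cells finish in well under a sweep budget of 20000·N
proposals; above ~55% coverage random packing may stall, and the
generator warns.

## Detectors and statistics

Center-line read-out returns the monitor row itself.  Off-lattice
detectors (e.g. 200 points on a 51 um ring) use bilinear interpolation of
the complex field — at 100 nm pitch the field varies by well under 1%
per pixel at any frequency in the band.  Detector-averaged spectra
average *magnitudes*, not complex values: for random scenes the phase
varies with detector angle and complex averaging would cancel the signal.

Ensemble center-line statistics average |psi| over the exterior,
non-ABL pixels of the monitor row (the DPA reference does not exist
inside sources, so the comparison is restricted to pixels where both
sides are defined), then report mean and standard deviation over
realizations for each contrast, for the CBS and DPA routes on the same
realizations.

## Test and validation scale

The exact disk solution is the oracle: on the reference lattice and on a
512^2 reduced lattice (same pitch, same physical sigmoid profile,
d = 128) the CBS center line matches it to ~1-3% relative L2 inside and
outside the source at 183-732 MHz for all three contrasts, comfortably
inside the 5% validation bound; the residual is dominated by disk
rasterization.  One CBS update is verified against a dense-DFT
re-implementation on a 32^2 lattice to 1e-12.  The test suite and the
ensemble experiments run on the 512^2 lattice so the full suite completes
in minutes; the 2048^2 reference setup is exercised once, at the top of
the frequency band where iteration counts peak (and is the configuration
behind the CLI defaults).

What the reduced-scale ensemble does and does not show: with a 10 um ROI
and 6 cells the multiple-scattering gap between CBS and DPA at nonzero
contrast is an order of magnitude above the zero-contrast numerical
floor, reproducing the qualitative signature; quantitative ensemble
curves at the published scale (100 realizations of ~400 cells on 2048^2)
are a cluster-scale computation and are not run in the test suite.  The
phantoms also idealize real smears: monodisperse radii, no aggregation,
no cell deformation, uniform illumination.

## Known limitations

* 2D only; fluid (shear-free) disks; lossless media outside the
  artificial eps-damping.
* Uniform illumination (one global `I0`); per-cell intensities would
  require a per-source amplitude.
* The sigmoid ABL is thick (500 pixels per side at reference scale),
  spending ~half the domain area on absorption.
* Iteration counts depend at the +-1 level on unstated conventions
  (whether the first windowed field counts as an iterate, where the error
  is measured); bounds on counts should be read with that granularity.
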