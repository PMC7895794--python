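# Methods

## Filters

All filters operate on a `Volume`: a finite 3-D scalar grid with physical
voxel spacing in mm. Every output voxel is a convex combination of
observed intensities — weights are positive and normalised to sum to one —
so outputs stay inside the range of their candidate values and
non-negative inputs give non-negative outputs.

**Patch distance.** The dissimilarity of two patches is the plain sum of
squared intensity differences over all patch voxels (no per-voxel
averaging, no noise-variance offset). Patches that cross a volume border
are completed by reflect padding; this boundary policy is shared verbatim
by the brute-force reference implementations used in the tests, so
border voxels are covered by the oracle comparisons too.

**Intensity normalisation.** Distances (and the bilateral intensity
kernel) are computed after dividing by the target volume's global maximum,
so `h` and `sigma_intensity` are dimensionless and comparable across
acquisitions with different activity scales. The weighted averaging itself
is applied to the raw intensities; algebraically the two formulations are
identical, and numerically the averaging is done in residual form
(`target + Σ w·(candidate − target) / Σ w`), which makes the degenerate
identities exact: identical auxiliaries, a zero search radius or a zero
FWHM return the input bit for bit.

**Conventional NLM.** Candidates are all voxels of a per-axis search
window (default half-widths (5, 5, 1), i.e. 11×11×3) *clipped* to the
volume; candidate centres are never reflected. The self term is included
with its natural weight exp(0) = 1 — no max-of-neighbours heuristic. The
default patch half-widths (2, 2, 0) give the 5×5 in-plane patch applied
slice by slice; fully 3-D patches and windows are configuration away.

**MR-NLM.** The search window is replaced by the stack of co-registered
auxiliary reconstructions: auxiliary *j* contributes one candidate, its
centre voxel, weighted by the distance between the target's patch and the
auxiliary's patch *at the same location*. `include_target` (default on)
adds the target's own voxel with weight 1. If every auxiliary weight
underflows and the target term is excluded, the output falls back to the
target value rather than dividing zero by zero. The filter is
deterministic and invariant to auxiliary ordering (up to floating-point
summation order, bounded by ~1e-15 relative).

**Choice of h.** `h` trades selectivity for smoothing: candidates at
patch distance ≲ h² are averaged in, candidates much farther are ignored.
For two patches of |v| voxels that differ only by independent noise of
standard deviation σ (in max-normalised units), the expected distance is
2|v|σ²; `h` should sit above that and well below the distance contributed
by a real activity edge. With the generator defaults (σ ≈ 0.025 of
maximum, |v| = 25, hence 2|v|σ² ≈ 0.03, edges contributing ≳ 1) the
package default is h = 0.3. Published h values for this family of filters
are not transferable: under the literal weight exp(−Σ Δ²/h²) an h of order
10⁻³ underflows every non-self weight for any realistic noise level, so
whatever normalisation produced such values, it is not recoverable; h here
is defined by the formula above and documented in its own units.

**Gaussian.** Isotropic in mm: per-axis σ in voxels is
FWHM/(2√(2 ln 2)) divided by the voxel size; `fwhm_mm = 0` is the exact
identity. Delegated to `scipy.ndimage.gaussian_filter` (reflect
boundaries).

**Bilateral.** Weight = spatial Gaussian (σ in voxel units, truncated at
a spherical radius of 3σ) × intensity Gaussian on max-normalised values.
Defaults σ_sp = 3.8, σ_in = 0.35. Note the cost: 3σ_sp = 11.4 voxels means
~12 000 neighbour offsets per volume, minutes on a full phantom grid; the
shipped default pipeline therefore omits bilateral (it is fully tested and
available via config/CLI).

## Phantom and pseudo-reconstruction emulator

The digital phantom is a 100 mm-radius, 180 mm-tall cylinder at
3.6 kBq/ml holding six spheres (diameters 11.89, 14.43, 17.69, 21.79,
26.82, 33.27 mm) at 18.4 kBq/ml — a 5:1 hot-sphere contrast — sampled at
2×2×3 mm with voxel-centre-in-solid membership. Sphere positions are not
standardised by the physical phantom's data sheet alone, so the generator
places them on a 55 mm circle in the central transaxial plane (explicit in
the config so tests are stable); geometry validation rejects overlapping
or out-of-bounds spheres.

A pseudo-reconstruction with setting (iterations i, subsets s) and
effective iteration number E = i·s is emulated as

    blur(truth, FWHM · (E_ref/E)^0.3)  +  σ · (E/E_ref)^0.5 · background · noise_field

clipped at zero, with E_ref = 42 (the 2i:21s clinical default). The noise
field is white Gaussian made spatially correlated by a 4 mm-FWHM Gaussian
kernel and rescaled to unit variance, so `noise_sigma` is the actual
background noise SD as a fraction of the background activity (the median
positive voxel of the noiseless volume). The exponents encode only the
qualitative ordered-subset trade-off — more effective iterations converge
further but amplify noise — and make no quantitative claim about any
scanner. Defaults: PSF FWHM 5 mm (typical clinical whole-body PET
resolution), noise_sigma 0.13 (chosen so the unfiltered phantom lands at
SNR ≈ 20–25, the regime reported for real 5:1 hot-sphere acquisitions).
Per-realisation seeds are split from the master seed with
`numpy.random.SeedSequence([master, index])` (target = index 0), so a
dataset is bit-reproducible while all realisations are independent.

**What the emulator does not model** — and hence what a green test does
not establish: Poisson count statistics and activity-dependent
(nonstationary) noise, reconstruction-correlated streak/texture
artefacts, convergence that differs between hot and cold regions,
attenuation/scatter residuals, and any coupling between the noise of
different reconstructions of the same raw data (emulated auxiliaries are
fully independent, which if anything flatters multi-image averaging). One
consequence is measurable and deliberate to leave visible: with stationary
correlated Gaussian noise on a piecewise-constant scene, a conventional
NLM window (~363 candidates) out-averages 13 co-located samples, so in
this synthetic world the conventional filter reaches a slightly *higher*
SNR than MR-NLM at matched smoothing — the reverse of what real scanner
studies report, where genuinely similar patches are scarce and noise is
structured. The end-to-end ordering test asserts the real-world direction
and is accordingly expected to fail on this generator; it is kept as an
honest record of that gap rather than weakened to pass.

**VOI pairs.** Each sphere's voxel set is paired with a background VOI of
identical size and shape: the same voxel set translated to the first
position — scanning integer-voxel translations in order of increasing
physical distance — that keeps 8 mm clearance from every sphere and the
cylinder boundary and does not collide with previously placed background
VOIs. The scan order is fixed, so placements are deterministic.

## Metrics

Sample (n−1) standard deviations everywhere. SNR uses the background-VOI
SD of the image being evaluated. Phantom bias is signed
(100·(μ−μ_ref)/μ_ref; partial volume makes it negative for hot spheres);
clinical-style bias is reported as the magnitude of the deviation from
the unfiltered image with the sign recorded in a separate report column.
Undefined statistics (zero SDs or denominators) raise typed errors rather
than propagating infinities into aggregates. The paired t-test is
two-sided on matched per-VOI values; all-zero differences return p = 1 by
convention and no multiple-testing correction is applied.

## Matched-smoothing comparison

Smoothing parameters of different filter families are not commensurable,
and tuning each per noise level is standard practice. The experiment
driver compares methods at *matched background smoothing*: MR-NLM runs at
its default h; its residual background-VOI SD defines the operating
point; the Gaussian FWHM is then chosen from the conventional 2–9 mm grid
(0.5 mm steps, closest match) and the NLM h by 8-step bisection on log h
over [0.02, 2] (background SD is monotone decreasing in h). At equal
residual noise, SNR and bias differences isolate signal preservation.
Calibration is deterministic and is reused across replicate seeds, since
the noise level is seed-independent.

## Numerical notes

* Patch sums inside the vectorised filters use a separable moving average
  (`scipy.ndimage.uniform_filter`); the drift against literal summation
  is ≲ 1e-13 and covered by the 1e-10 oracle-equivalence tolerance.
* Weights that underflow to 0 stay 0; normalisation denominators are
  guarded so a fully-underflowed voxel returns the target value.
* Reflect padding of a length-1 axis degenerates to edge replication.
* All filters are deterministic; randomness exists only in the phantom
  emulator and is fully seeded.

## Known limitations

* No tomographic reconstruction, sinogram/list-mode handling, TOF/PSF
  modelling or attenuation/scatter simulation; the emulator is a stand-in
  with the caveats above.
* The bilateral filter is O(neighbourhood volume) per voxel and slow at
  the recommended σ_sp on full-size grids.
* Clinical (patient-data) evaluation is supported only in the
  bias-versus-unfiltered sense; no SUV computation or lesion segmentation.
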