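# Methods

This note documents the models and conventions behind `cryolabel`, the
parameters that matter, and what the synthetic fixtures do and do not show.

## Grid model and MRC dialects

A volume is a scalar field on a regular orthogonal grid. Internally the
array index order is `(i, j, k) = (z, y, x)` and the *center* of voxel
`(i, j, k)` sits at `origin + (i·vz, j·vy, k·vx)` (Å). All distance
computations in the package refer to voxel centers.

MRC/CCP4 files may store the volume with any axis permutation
(`mapc/mapr/maps`); reading always undoes the permutation, so downstream
code sees one canonical layout. Voxel size is `cell length / sampling` per
axis. Two origin dialects coexist in public depositions: the MRC2014
`origin` record and the older `nxstart/nystart/nzstart` offsets. The reader
uses the origin record when any component is nonzero and otherwise falls
back to `nstart × voxel`, which is the prevailing convention across EMDB
entries and what map/model alignment requires. Only orthogonal (90°, 90°,
90°) cells are supported — single-particle cryo-EM maps satisfy this; maps
are written as mode 2 (32-bit float) with canonical axis order, so
write-then-read is the identity up to float32 representation.

## Structure handling and atom classes

Parsing keeps all heavy atoms (element ≠ H/D) of the first model in file
order; waters are removed, and for alternate conformations the first altloc
is kept (deterministic, and what map-simulation tools commonly do).
Biological-assembly expansion is *not* performed: supply the assembly file
if the map contains the full assembly.

Atom classes for the atom-type label: Cα → 1, Cβ → 2, backbone carbonyl
C → 3 (all three require element C *and* an amino-acid residue, so a
calcium ion named "CA" stays out of class 1), any oxygen → 4, any
nitrogen → 5, everything else → 0. The O/N rules intentionally apply to
side-chain and non-protein atoms too — restricting them to the backbone
would silently discard side-chain labels, and nothing in the labeling
scheme requires the restriction.

## Resampling (standardization)

Deposited voxel sizes range roughly 0.7–1.6 Å; all maps are brought to
1 Å isotropic. Resampling evaluates the input field at the new voxel
centers by trilinear interpolation: per axis the output length is
`floor(extent / target) + 1` with `extent = (n−1)·voxel`, the origin is
unchanged, and sample points outside the input support are 0 (solvent
background). Trilinear interpolation is local and exact on affine fields,
every output value is a convex combination of inputs, resampling at the
native size is the identity, and 1 Å → 1 Å is idempotent — each of these is
a test. No Fourier cropping, sharpening or intensity normalization is
applied; only the sampling changes.

## Density simulation

The idealized map is a sum of isotropic, unit-integral Gaussians at the
atom positions, sampled at voxel centers. Parameters:

* `resolution` *d* (Å) — nominal resolution; use the map's reported value.
* `kernel_sigma_factor` — σ = factor × d; default 1/(2√(2 ln 2)) ≈ 0.4247,
  i.e. the kernel FWHM equals *d*. Real-space convolution tools differ in
  this convention, so it is explicit and configurable.
* `amplitude_mode` — `unit` (default) or `mass` (atomic-mass weighting).
  Unit weighting is the default because downstream learners consume
  per-map-normalized values; mass weighting is available for closer fidelity
  to mass-weighted convolution tools.
* `cutoff_sigmas` — kernel truncation radius, default 4σ (the neglected
  tail mass of a 3-D Gaussian beyond 4σ is 1.13 × 10⁻³).

Contributions are stamped per atom inside the cutoff window; a brute-force
triple-loop evaluation serves as the test oracle. A σ below half the voxel
size triggers an aliasing warning. Electron scattering form factors,
per-atom B-factors and solvent models are out of scope; consequences for
FSC comparisons are noted below.

## Label generation

Three volumes share the experimental map's exact geometry and depend only
on that geometry (never on the experimental densities — two noisy
observations of the same grid give identical labels):

* **regression** — simulated density inside the union of 6 Å balls around
  the atoms' *continuous* coordinates (distance to voxel centers, boundary
  inclusive), exactly 0 outside.
* **classification** — 1 at the voxel containing each atom
  (`floor((coord − origin)/voxel)` per axis, i paired with z), 2 at the
  remaining in-ball voxels, 0 background; 1 beats 2 regardless of atom
  order.
* **atom type** — classes 1–5 at the atom voxels only; neighboring voxels
  have no unambiguous chemical identity and stay 0. When two atoms share a
  voxel the later atom in file order wins (logged).

The 6 Å radius reflects how far density meaningfully extends around an
atom at the resolutions involved and absorbs the precision loss of
continuous-to-discrete coordinate conversion. Atoms falling outside the
grid are skipped and counted in logs. `extract_subcubes` tiles label or map
volumes into 64³ blocks (zero-padded at the edges, offsets recorded) for
memory-bounded training.

## FSC and resolution estimation

Unmasked FSC over spherical shells of the discrete Fourier transforms.
Shells are one reciprocal-grid step wide; on anisotropic grids the physical
frequency magnitude is binned with the coarsest axis's step
(`ds = max_i 1/(n_i v_i)`), nearest-integer assignment, value reported at
the shell-center frequency. The DC term is excluded and shells run to the
most limiting axis's Nyquist frequency. The threshold resolution is `1/s*`
with `s*` the first crossing found by linear interpolation between
adjacent shells; a curve that starts below the threshold crosses at the
first shell, and a curve that never crosses reports the Nyquist resolution
(2 × voxel) with `crossed = False`. No mask is applied anywhere.

Map–model FSC correlates a map with density simulated from its model on
the same grid. Because the simulator uses Gaussians rather than electron
scattering factors, threshold resolutions agree with scattering-table
implementations only approximately; ±0.3 Å is the documented tolerance
for benchmark comparisons.

`percent_improvement(before, after) = 100 (before − after)/before` and
`summarize_resolutions` (mean, median, linear-interpolation quartiles,
1.5 IQR whiskers) provide the corpus-level summary statistics.

## Curation and splits

Manifest filters, applied in order so each dropped entry is counted under
one rule: no model → drop; no reported resolution → drop; resolution
outside [1, 4] Å (inclusive) → drop; several maps per model → keep the
best (smallest) resolution, ties broken by lexicographic map id (the
choice of which redundant map to keep is this package's, made
deterministic). Duplicate map ids are a manifest error.
`split_by_resolution` stratifies entries into resolution bins and
allocates train/val/test within each bin by a seeded shuffle and
largest-remainder rounding, so splits are deterministic and difficulty
distributions comparable.

## Synthetic fixtures

The fixture is an ideal poly-alanine α-helix (CA trace on a 2.3 Å
cylinder, 1.5 Å rise, 100° twist; N/C/O/CB at fixed offsets in the
rotating local frame) with a simulated clean map and a noisy copy (clean +
seeded Gaussian white noise). It reproduces the properties the tests rely
on — a model and map in one physical frame, labels aligned to the grid,
resolution degrading monotonically with noise — and nothing else: no
structural (ice/carbon) noise, no CTF or detector model, no conformational
heterogeneity, no B-factor variation. Passing tests therefore demonstrate
the correctness of the label geometry, simulation and FSC machinery, not
performance on real micrograph-derived noise.

Problem sizes: tests and the acceptance script use helices of 2–8 residues
on grids of roughly 20³–30³ voxels, where the brute-force oracles
(triple-loop Gaussian sums, per-voxel minimum distances, direct DFTs on
16³ grids) remain exact and cheap.

## Numerical choices and limitations

* All label volumes use exact comparisons (masks are computed from
  continuous coordinates, not rasterized atoms); regression background is
  exactly 0.
* FSC denominators of empty shells would be 0; such shells report 0
  correlation (they do not occur on the grids used).
* Half-map FSC with noise substitution, masked/local resolution, B-factor
  sharpening and assembly symmetry expansion are out of scope.
* The pipeline is a pure function of its inputs; the only randomness in
  the package lives in the fixture noise and split shuffles, both seeded.
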