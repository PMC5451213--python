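# Methods

## The quantity being inferred

A cleavage-stage zebrafish embryo holds far more core histone than its
chromatin can bind. The analysis infers the nuclear concentration of the
*non-DNA-bound* fraction by combining three independent measurements:

1. absolute histone amounts per embryo (quantitative mass spectrometry,
   molecules of H3, H4, H2A, H2B);
2. volumes from live lightsheet imaging — total animal-cap volume V_total,
   the fraction v of it occupied by nuclei, and the mean single-nucleus
   volume V_nucleus;
3. the nuclear-over-cytoplasmic intensity ratio R of endogenous histone H4
   immunofluorescence, taken as the nuclear/cytoplasmic concentration ratio.

## Stoichiometry

The unit of account is the "genomes worth" (GW): the number of copies of
each core histone needed to assemble one diploid genome into nucleosomes,

    copies = round(ploidy · G / NRL) · 2 ,

two copies of each histone per nucleosome, nucleosome repeat length NRL =
187 bp. The default genome preset (`grcz10`) uses a haploid length of
1,464,443,470 bp, which makes the constant exactly 31,324,994; a second
preset (`grcz10-text`) uses the assembly's rounded headline size of 1.46 Gb
and lands 0.3% lower. The nucleosome count is rounded before doubling so
the constant is even.

Per-cell excess uses H2B — the least abundant core histone, hence the one
that can limit nucleosome assembly — and subtracts g GW of chromatin-bound
histone per cell. g defaults to 1.5, the average of the pre-replication (1)
and post-replication (2) states of a diploid nucleus, and is constrained to
[1, ploidy]. A cocktail of the four histones is valued at the GW of its
limiting (minimum-copy) species.

Stoichiometric scalars carry unit tags (`GW`, `GW/cell`, `molecules`, …);
adding or subtracting across tags raises, so per-embryo and per-cell
quantities cannot be mixed silently. The canonical concentration unit
elsewhere is molecules/µm³, with GW/µm³ and nM as derived views
(1 molecule/µm³ = 1/(N_A·10⁻¹⁵ L) mol/L ≈ 1.66 nM).

## Two-compartment model

Conservation of the embryo-wide amount across summed nuclear and
cytoplasmic volumes, plus R ≈ [H_nuclear]/[H_cytoplasm], gives the closed
form

    [H_nuclear] = (H_total / V_total) · R / (1 + v(R − 1)) ,
    [H_cytoplasm] = [H_nuclear] / R ,
    [H_free] = [H_nuclear] − g·copies_per_genome / V_nucleus .

The closed form is verified against a direct solve of the underlying 2×2
linear system to 10⁻¹² relative error, and the re-assembled amounts return
H_total to 10⁻⁹ relative. A negative [H_free] is reported with a deficit
flag, never clamped: it diagnoses inconsistent inputs (e.g. an H_total too
small for the assumed bound share). The per-stage R entering the model is
the median over included nuclei (configurable to mean); the per-stage
V_nucleus is the mean over included nuclei.

Error amplification is worth noting: [H_free] is a difference of two
comparable terms when the bound share is large, so a relative error ε in
H_total inflates to ε·[H_nuclear]/[H_free] in the free concentration —
about 2.4× at the 1K-stage defaults of the simulated series. This is
intrinsic to the subtraction, not to the implementation.

## Image analysis

All geometry is computed in physical µm; axis order is ZYX, voxel centres
at `index × voxel_size`, default anisotropic voxel (1.0, 0.5, 0.5) µm.

**Nucleus segmentation.** A single Otsu threshold cannot separate nuclei
from cytoplasm on a three-level image (background, cytoplasm, nuclei), so
the seed threshold is found in two stages: Otsu for the embryo foreground
(skipped when a cap mask is supplied), then Otsu within the foreground for
the nuclei. Seed components above a minimum volume (default 30 µm³, a noise
guard well below any real nucleus) are refined individually: Otsu is
recomputed inside the component's padded bounding box (pad 4 µm),
restricted to the embryo region — without that restriction the local
histogram re-splits background|embryo and the segment balloons — and the
connected component (26-connectivity) containing the previous centroid is
kept, iterating until the voxel set changes by <1% or 10 iterations. If the
centroid voxel falls below the local threshold the iteration stops rather
than jumping to a brighter neighbour. Seed voxels left unclaimed by refined
segments are recycled as new seeds (up to two extra passes); this is the
mechanism by which two merged nuclei of different brightness separate.
Masks are hole-filled; refined masks are kept mutually disjoint.

Two numerical details matter on synthetic (discrete-level) images. First,
Otsu thresholds are computed from the exact level histogram whenever an
image has ≤256 distinct values: a binned threshold can sit at the centre of
a bin containing a level, silently flipping that level across a strict `>`
comparison. Second, for noisy stacks a lateral 3×3 median filter (pipeline
default) is applied for mask determination only — a Gaussian blur of
comparable strength smears small nuclei and biases the threshold outward,
while a full 3D median erodes their polar z-planes. Intensities are always
measured on the raw image, so noise-free stacks round-trip exactly
(segment masks equal planted labels voxel-for-voxel).

**Cytoplasm shells.** Each nucleus mask is dilated in two steps of 2 µm
(default); the once-extended shell and every nucleus voxel are removed from
the twice-extended shell. Dilation by a physical distance r is implemented
as thresholding the Euclidean distance transform (anisotropy-aware
sampling), which is exact for ball structuring elements. The pipeline also
intersects shells with the cap mask so surface-proximal nuclei do not
sample dark out-of-embryo voxels — an empty shell flags the nucleus out of
ratio statistics.

**N/C ratio.** R = (mean nuclear − background)/(mean shell − background),
background being a per-channel scalar measured from secondary-only
controls (0 for default synthetic stacks, whose background field only
exists outside the embryo; a uniform planted `intensity_offset` exercises
the subtraction). Non-positive denominators flag the segment invalid. Only
nuclei with R strictly greater than 2 enter downstream statistics,
excluding mitotic or degraded nuclei.

**Animal cap.** The cap threshold comes from the 256-bin histogram of the
maximum-intensity z-projection in two stages: a 2-class Otsu on the
log-compressed projection gives a rough background|embryo split (the log
shrinks the bright-nucleus tail, which would otherwise attract the
threshold), and the final threshold is the midpoint of the two class
medians — insensitive to nucleus brightness and centred between the modes,
so the boundary bias under symmetric noise is ~zero. The threshold is
applied to all 3D voxels (default) or extruded from the 2D projection mask
(both modes provided); the largest connected component is kept. The
pipeline thresholds a 1 µm-Gaussian-smoothed copy because a threshold
derived from a noisy projection otherwise punches holes through the cap;
`segment_cap` itself defaults to no smoothing, keeping noise-free
segmentation exact.

**Tracking and volume fraction.** Nuclei are linked across consecutive
frames by greedy mutual-nearest centroid matching, ties broken by distance
then lowest label, with a maximum linking distance of twice the median
nuclear radius by default. Unmatched segments start or terminate tracks;
after a division one daughter continues the parent track and the other
starts a new one. v is the sum over tracks of each track's maximal volume
divided by the cap volume ("maximal extension" of each nucleus within its
cell cycle); v ≥ 1 is an error. Cell counting is accepted-segment counting.

## Synthetic data

The generator emulates a lightsheet field of view of the animal cap: a
hemisphere (flat face down) of cytoplasm-level voxels containing
non-overlapping spherical nuclei (2 µm placement margin — cells have
cytoplasm between nuclei) at intensity R × cytoplasm, over dark background,
with Gaussian noise and optional Poisson resampling applied last and
intensities clipped at 0. Ground truth records the exact rasterized label
volume, per-nucleus voxel-count volumes, cap volume and v, so mass
conservation and the two planted-v definitions agree exactly. Default
noise sd 20 at cytoplasm level 100 corresponds to SNR 5 — a conservative
choice, since the field's acquisition settings vary and are rarely
reported. Time-lapse frames move each nucleus by a fixed step in a random
direction (reflected at the cap boundary); at a division frame each
nucleus is replaced by two daughters of half the volume offset ±1.1 radii,
far enough apart to be resolvable.

What the generator does *not* model: PSF/partial-volume mixing, stripe
artifacts, spherical aberration, intensity gradients with depth, nuclear
import dynamics within a cycle, or chromatin texture. Passing tests
therefore demonstrate correctness of the inference chain on
piecewise-constant imagery, not robustness to every optical artifact of
real lightsheet data — the deliberately simple image model is what makes
exact round-trip oracles possible.

The series generator plants per-stage H2B totals implied by per-cell
excesses of 3098 GW (1-cell), 518 GW (8-cell) and 9 GW (1K at 1024 cells),
with intermediate stages interpolated smoothly and the other histones
scaled 1.1–1.2× above H2B; abundance tables add multiplicative noise
(default 10% relative sd, 3 replicates) and keep a noiseless truth column.
qPCR tables hold the maternal normalizer at a constant Ct (default 15) and
targets at a detection-floor Ct of 35 cycles before their activation
stage, standard qPCR practice for "not detected".

## Pipeline defaults and problem sizes

The simulated end-to-end series covers four stages (128-cell to 1K) with
4→14 nuclei per 64×128×128-voxel field of view, v rising 1.2%→5.5%, R
falling 7→4, and a planted free concentration falling 0.020→0.006 GW/µm³ —
the per-field nucleus counts stand in for the stage's cells, and the
stage's histone total is planted on the field's own geometry. Tests and
the acceptance script use 20 seeded stacks at v ≈ 1.1% and 7.1% with R
spanning 2.2–10; these sizes keep a full run under a minute while leaving
every estimate's error far from its tolerance. The end-to-end check feeds
the planted H_total through exactly (`ms_noise_sd=0`): it validates the
imaging-and-partition chain against the planted trajectory, which the
amplification argument above shows would otherwise be dominated by
replicate scatter in the abundance table.

## Known limitations

* Touching nuclei of equal brightness are not separable (no watershed); the
  R > 2 filter and placement margins make this rare in intended use.
* The tracker is greedy and division-agnostic; it is exact below half the
  inter-nucleus spacing but has no motion model for faster dynamics.
* Replicate SEM is passed through, not propagated into [H_free].
* The qPCR model fixes amplification efficiency at 2.0 (configurable); no
  standard-curve calibration is implemented.
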