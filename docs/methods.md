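# Methods

## Scope and model overview

`embryodose` computes the energy imparted and the ICRU specific energy
(z = ε/m) in three nested compartments of a 2-cell *C. elegans* embryo —
chromatin ⊆ AB nucleus ⊆ embryo, plus the non-irradiated P1 nucleus as a
negative control — under targeted irradiation with a focused 3 MeV proton
microbeam. The pipeline is: parametric synthetic embryo → confocal-like
image stack → threshold segmentation → labelled voxel phantom → straight-
line condensed-history proton transport → per-compartment dose report.

## Synthetic embryo geometry

The embryo envelope is an axis-aligned ellipsoid, default semiaxes
**25 × 15.5 × 8.0 µm**. These are calibrated, not measured: the volume
(1.30 × 10⁴ µm³ → 1.3 × 10⁻¹¹ kg at water density) matches the whole-embryo
mass used in the dose accounting, and the beam chord through the AB target
point (x = −6.5 µm) is ≈ 15.5 µm, which makes the whole-embryo energy per
proton (LET × chord ≈ 30 fJ) self-consistent with the compartment masses.

The AB nucleus is a spheroid of lateral diameter **7.4 µm** (a 212 µm³ ≈
2.1 × 10⁻¹³ kg sphere by default; biological range 6.5–8.5 µm). Its extent
along the beam axis is independently settable: it equals the central beam
chord, which is the single geometric quantity the nuclear energy deposit is
most sensitive to. The P1 nucleus (default diameter 6.5 µm) sits 12.5 µm
from the AB centre along the anteroposterior axis — far enough that a
1.5 µm-FWHM beam can never reach it, making the zero-deposit contract
exactly testable.

Population sampling draws the AB beam chord from a **uniform distribution
with mean 6 µm and SD 1.5 µm** (i.e. uniform on 6 ± √3·1.5 µm). The SD
convention is deliberate: the observed cell-to-cell fluctuation of the
nuclear energy is ~25%, which equals SD/mean = 1.5/6, and a ±2.8 pJ SD on
a 10.5 pJ mean carries the same ratio. Interpreting the 1.5 µm spread as a
uniform half-range would halve the CV and is inconsistent with those
numbers. With the SD convention the flattest nuclei reach ≈ 0.45× the
nominal nuclear mass — the price of honouring the printed spread.

## Chromatin condensation states

Total chromatin volume is fixed at **22 µm³** (2.2 × 10⁻¹⁴ kg) in every
state; only the arrangement changes. Five states are modelled:

| state | arrangement | ~share of nuclear energy |
|---|---|---|
| interphase_decondensed | 1-layer on-axis plate r = 1.05 µm + 6 peripheral blobs | ~2.5% |
| prophase_early | 1-layer plate r = 1.8 µm + 6 blobs | ~4% |
| prophase_late | 2-layer plate r = 1.12 µm + 5 blobs | ~6% |
| anaphase | two spheroids at x = ±1.6 µm | ~15–25% |
| metaphase | one compact spheroid (r ≈ 1.74 µm) on the axis | ~50–60% |

The diffuse states put most of the chromatin in a ring of blobs at 2.9 µm
lateral radius — outside the beam column — and represent the portion the
beam does traverse as a thin on-axis plate (1–2 voxel layers, i.e. 0.2–
0.4 µm at the default pitch). Plate radii were calibrated once against the
closed-form estimate (deposit ≈ S(E) × expected path, with the beam's
lateral Gaussian integrated over the plate) so that the prophase states
bracket a ~0.5 pJ chromatin deposit per 10³ protons and a ~4% energy
share, and the metaphase plate yields 50–60%; they were then frozen. The
anaphase separation (±1.6 µm) keeps the two bodies disconnected on the
0.2 µm lattice (gap > one voxel).

Voxelized chromatin volume is matched across states by bisecting the free
blob radius against the target voxel count, evaluated after intersection
with the nucleus. Voxel counts jump in lattice-symmetric shells, so the
achievable granularity is ~1% of the 22 µm³, not one voxel; in flattened
nuclei the metaphase spheroid clips into a lens and the bisection
compensates automatically.

## Imaging and segmentation

Stacks are rendered at **SNR 10** (additive Gaussian noise on a constant
background; levels 600/1600 in uint16 units). No optical PSF, bleaching or
refraction is simulated — any monotone threshold separates the classes, so
passing segmentation tests demonstrates the pipeline's bookkeeping, not
robustness to realistic microscopy artefacts.

The default threshold is a **robust background model**: background level =
histogram mode, σ estimated from the lower half-distribution only
(median(mode − x)/0.674), threshold = mode + 6σ. This estimator is
independent of the foreground fraction, which spans ~50% (embryo channel)
to < 0.1% (chromatin channel) — a range over which histogram-shape methods
(Otsu, triangle) each fail on one end; plain Otsu is retained as an option
and is exact on the dense embryo channel. The nuclear compartment comes
from a user-supplied ROI when given (mirroring manual outlining), else from
the thresholded green channel; the two green components are assigned to
AB (contains the beam target) and P1 (largest remainder).

## Phantom and file format

Voxels are labelled outside / embryo_only / nucleus / chromatin /
p1_nucleus with the hierarchy enforced at build time; chromatin voxels
found outside the nucleus are absorbed into it and counted, and a majority
outside is treated as a channel mix-up (hard error). All labelled voxels
are liquid water (1000 kg m⁻³); compartment mass is voxel count × voxel
volume × density. The grid is cropped to the labelled bounding box with
the position shift adjusted, which is what makes the text format's
write → read → write cycle byte-identical. Indices are 0-based; a voxel's
position is its centre; world position = shift + index × pitch.

## Transport physics

* **Stopping power**: relativistic Bethe formula for protons in liquid
  water, I = 75 eV, Z/A = 0.55509, no shell/Barkas/density corrections.
  S(3 MeV) = 11.95 keV/µm (the canonical ~12); agreement with standard
  tables is within 5% over 1–5 MeV (the model overshoots low energies
  where shell corrections matter, ~3.5% at 1 MeV). Validity window
  0.5–10 MeV; a proton leaving it mid-grid aborts the run.
* **Tracks are straight**: lateral MCS displacement of 3 MeV protons over
  ≤ 30 µm of water is far below the 0.64 µm beam σ.
* **Energy-loss straggling**: optional (default on) Gaussian per-step noise
  with the Bohr variance (8.7 keV²/µm in water). Over a 6 µm chord the σ
  is ~10% of the 72 keV mean loss; the Gaussian approximation is marginal
  (Vavilov regime) but only broadens per-proton statistics — compartment
  means are unaffected.
* **Secondary electrons are deposited locally** by default: the ~1 µm
  maximum delta-ray range at 3 MeV is comparable to the voxel pitch. An
  optional lateral Gaussian blur of the tally is provided as a sensitivity
  tool; it conserves total energy but deliberately does not recompute the
  per-proton compartment record.
* **Bookkeeping is exact**: the voxel tally sums to the total energy lost
  by all tracks in the grid to < 10⁻⁶ relative, and per-proton compartment
  deposits are recorded for SE estimates. The beam uses
  σ = FWHM/(2√(2 ln 2)); all RNG is seeded and echoed in the tally config.

The axis-aligned beam uses a vectorized layer-by-layer sweep; arbitrary
directions fall back to per-ray Siddon traversal (used in tests to check
the fast path).

## Dose reporting conventions

Per-proton energies in fJ (mean ± SE of the per-proton record), masses in
kg, per-proton specific energies in mGy, run totals in pJ and Gy. z·m = ε
holds algebraically, not to a tolerance. Estimates with relative SE > 2%
are flagged. The population summary prints both an SE-based 95% CI
(1.96·SD/√n) and the SD-based interval (1.96·SD), since either convention
appears in summary reporting of such populations.

## Problem sizes and numerical choices

Default voxel pitch 0.2 µm (grid ≈ 255 × 161 × 85). The reference run uses
10⁴ protons (~1 s), the condensation study 40 cells × 10³ protons (~5 s);
these sizes put the Monte-Carlo SE of the nuclear estimate near 0.3%, far
below the geometric effects being measured. Plate thicknesses are defined
in voxel layers, so chromatin state geometry is resolution-coupled; the
calibrated behaviour refers to the default pitch. Degenerate inputs are
handled explicitly: zero chromatin volume (valid, empty compartment), zero
beam FWHM (all protons on axis), empty segmentation (warning + empty
compartment flag), massless compartments (undefined-dose error).

## Limitations

* No event-by-event track structure: ionization clustering, radical
  chemistry and explicit secondary-electron transport are out of scope;
  quantities that depend on them (e.g. sub-µm dose heterogeneity) are not
  reproduced. Compartment-level energetics are LET × chord dominated and
  are what the scheme targets.
* The reference nuclear deposit is ≈ 14 fJ/proton — LET × the 7.4 µm
  nuclear chord. Published table values for a comparable geometry are
  ~20% lower than LET × chord for the nucleus; that difference (plausibly
  energy carried out by secondaries, or a flatter segmented nucleus) is
  noted, not modelled.
* The synthetic generator emulates compartment geometry and staining
  contrast, not real microscopy (no PSF, attenuation, anisotropic z
  resolution); segmentation scores near Dice 1.0 here say nothing about
  robustness on real stacks.
* One embryo per stack; no eggshell or polar bodies; no dose-rate/timing
  effects; no RBE or lineal-energy spectra.
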