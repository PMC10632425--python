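# Methods

`asymcycle` implements three quantitative analyses used to characterize the
ATP-coupled conformational cycle of the heterodimeric ABC exporter BmrCD in
lipid bilayers: global Gaussian-mixture analysis of DEER (PELDOR) dipolar
decays, protein–lipid interaction analytics on MD trajectories, and
structural-asymmetry measurements on coordinate models. Each strand is
exercisable end to end on synthetic data with a known ground truth.

## DEER forward model

A doubly spin-labelled protein measured with the dead-time-free four-pulse
DEER sequence yields a normalized dipolar evolution signal

    V(t) = B(t) · [ 1 − λ + λ · ∫ P(r) K(t, r) dr ],

with t the dipolar evolution time (µs) after zero-time correction and
normalization (instrument-level phase/zero-time corrections are assumed done
upstream and are not modelled).

**Dipolar kernel.** K(t, r) = ⟨cos[(1 − 3cos²θ)·ω_dd·t]⟩ averaged over
uniformly distributed cosθ (isotropic powder), with ω_dd = D/r³. The dipolar
constant defaults to the standard nitroxide value D = 2π·52.04 MHz·nm³
(≈ 3.27 × 10⁵ rad µs⁻¹ Å³) and is overridable in `KernelSpec` for other
label chemistries. Two numerically equivalent evaluations are provided: a
Gauss–Legendre quadrature over cosθ, whose order scales automatically with
the maximal dipolar phase of each distance column (a fixed low order cannot
resolve the ≈100 oscillations that occur at r = 20 Å, t = 5 µs), and a
closed form in terms of Fresnel integrals. The two agree to ≈1e-14; the
fitter uses the Fresnel form for speed.

**Distance distribution.** P(r) is a sum of Gaussians with centers μ_k and
widths σ_k on a grid of [15, 80] Å in 0.5 Å steps, covering the full range
accessible to nitroxide DEER and the ≈35–55 Å distances relevant to the
transporter's nucleotide-binding sites. The mixture is renormalized on the
grid by the trapezoid rule, which also handles components truncated at a
grid edge. Halving the grid step changes V(t) by < 1e-4 for σ ≥ 1.5 Å.

**Background.** B(t) = exp(−k·t^(d/3)) with d = 3 by default (homogeneous
three-dimensional bath of background spins), making the background's
log-linear slope −k. The stretched form (d ≠ 3) exists for excluded-volume
geometries but is off by default; whether the original analysis fixed d was
an open choice and d = 3 is the simplest defensible reading of a
per-condition background "slope".

## Global fitting and model selection

Decays recorded under C experimental conditions for the same label pair are
fit jointly: μ_k and σ_k are shared across conditions while the component
amplitudes (populations) w_{k,c}, the modulation depth λ_c and the
background rate k_c vary per condition. The parameter count is therefore
p = 2K + C·(K + 1), counting K − 1 free amplitudes per condition since the
weights live on the simplex.

Weights are parameterized internally by a softmax over K − 1 logits (last
logit pinned at 0) so the optimizer is box-constrained only; bounds are μ
within the grid, σ ∈ [0.5, 15] Å, λ ∈ [0.01, 0.99], k ∈ [0, 2] µs⁻¹.
Optimization is trust-region-reflective nonlinear least squares from
multiple random starts (default 4): μ drawn uniformly on the grid interior,
σ ∈ [1.5, 6] Å, λ ∈ [0.1, 0.6], k ∈ [0, 0.3], all from a caller-supplied
seed — runs are bitwise reproducible. Components are reported sorted by
ascending center for identifiability.

The number of components is selected by the Bayesian information criterion
with the Gaussian profile log-likelihood,

    BIC = n·ln(RSS/n) + p·ln(n),

n being the total residual count pooled over conditions. Ties below 1e-6
break toward smaller K (parsimony). A per-condition view of a global fit
reports a per-condition BIC using the standalone parameter count 3K + 2,
since the shared p is not attributable to single conditions. No uncertainty
bands are produced by default; a residual bootstrap (200 resamples,
seed-controlled) is a natural extension but is not wired into the CLI.

## Lipid interaction analytics

Inputs are trajectories with a fixed atom roster flagging protein atoms,
lipid molecules and lipid phosphorus atoms (DCD/XTC with a topology, or a
plain multi-frame PDB fallback so fixtures need no binary writer). Frames
are assumed wrapped with the protein whole; periodic-boundary imaging is not
performed.

* **Leaflets.** Per frame, the bilayer midplane is the mean z of all lipid
  phosphorus atoms; a lipid's leaflet is the majority vote of the sign of
  (P_z − midplane) over frames.
* **Minimum distance.** Per-lipid, per-frame minimum over heavy-atom pairs
  between the lipid and the protein, the stability readout for individual
  modeled lipids.
* **Residence fractions.** For each basic surface residue, the fraction of
  frames in which any lipid heavy atom lies within a cutoff of any
  side-chain heavy atom of that residue, on the normalized 0–1 scale whose
  maximum (1.000) an always-bound lipid attains. The cutoff defaults to
  4.0 Å heavy-atom–heavy-atom and reports are recomputed at {3.5, 4.0,
  4.5} Å to expose sensitivity. Contact is any-lipid by default (per-lipid
  available); no debouncing is applied. Dwell-time distributions (contiguous
  bound-run lengths) are available from the same contact series.
* **Density maps.** Phosphorus (X, Y) positions within a 20 Å shell of the
  protein are pooled per leaflet across frames and smoothed by a Gaussian
  KDE (Scott's rule by default) on a regular grid padded by three
  bandwidths; the grid spacing is clamped to the bandwidth so the kernel is
  always resolved, and the map is renormalized to unit mass on the grid.
  Sharp peaks mark stable binding sites; smeared density marks gliding
  lipids. For peak-localization checks on a single pinned lipid an explicit
  bandwidth at the jitter scale (0.5 Å) is used, because Scott's rule
  drastically undersmooths near-duplicate points and the argmax of an
  undersmoothed KDE is noisier than its own bandwidth.
* **Side-chain angle.** For Lys/Arg residue i, v1 runs from the centre of
  mass of the backbone atoms (N, CA, C, O) of residues i−1 and i+1 to
  Cα(i), and v2 from Cα(i) to the centre of mass of the terminal charged
  nitrogens (NZ for Lys; NH1/NH2 for Arg); the reported angle is
  arccos(v̂1·v̂2) in [0, 180]°. The direction of v1 (toward Cα) is a
  documented choice; the angle between the two vectors is unchanged if both
  are flipped. Residues at chain termini are rejected; frames with
  degenerate geometry are skipped and recorded.
* **Basic surface residues.** By default, all Lys/Arg whose side-chain
  Shrake–Rupley accessibility on the first frame exceeds 0.2 of the
  residue's theoretical maximum (Tien et al. scale); an explicit residue
  list always overrides.

All metrics are invariant under global rigid transforms of each frame.

## Structure comparisons

* **Superposition** is the closed-form Kabsch/SVD solution with the
  determinant correction; degenerate (collinear) point sets are rejected.
  It is cross-checked in the test suite against an independent solver of
  the same problem.
* **Paired RMSD** pairs Cα atoms by identical (chain, residue number) —
  matched-atom counts from sequence-independent alignment tools will differ,
  so retained-pair counts are reported but only RMSD values are meaningful
  across tools. Outlier rejection iterates: superpose, drop pairs deviating
  by more than 2× the RMS per-pair deviation, repeat (≤5 cycles). The RMS is
  used as the scale because deviation norms are chi-distributed: a threshold
  of 2× their standard deviation would sit below their mean and reject most
  pairs under pure noise.
* **Half-transporter asymmetry profile.** Given an externally supplied
  residue correspondence between the two pseudo-symmetric halves (the
  package consumes a two-column map file; it does not recompute structural
  alignments), the first half's Cα set is superposed onto the second's
  (no rejection) and the ordered per-pair distances quantify local
  asymmetry, optionally annotated by TM helix ranges supplied as
  configuration.
* **Helix tilt.** Both models are superposed on a reference chain's Cα
  trace; each helix axis is the dominant principal axis of the range's Cα
  atoms and the tilt is the angle between axes folded into [0, 90]° (axis
  sign is arbitrary).
* **Ionic-latch distances** are minima over side-chain heavy-atom pairs
  (the printed "side-chain distance" does not name specific atoms; the
  minimum is the conservative reading). Glycine has no side chain and is
  rejected by name.

## Synthetic data and what it does (not) show

* **DEER generator:** forward signals plus i.i.d. Gaussian noise on V(t)
  (the real noise structure of echo detection is not modelled). The default
  preset mirrors a consensus-site pair: shared components at 35 and 45 Å
  (σ = 2/3 Å) with per-condition populations 0.8/0.2, 0.5/0.5, 0.2/0.8,
  modulation depths 0.25–0.35, background rates 0.03–0.08 µs⁻¹, 300 points
  over 3 µs, noise sd 0.005.
* **Lipid generator:** a cylindrical protein proxy (rings of alanine-like
  stubs plus lysine anchors whose NZ points into the bilayer) with
  two-heavy-atom lipids confined to upper/lower z-slabs. Bound lipids follow
  a discrete two-state Markov chain (geometric dwells — the simplest model
  matching a target stationary bound fraction and mean dwell) pinned 2 Å
  outside the anchor NZ when bound; bulk lipids random-walk in an annulus
  kept clear of contact range; "gliding" lipids circulate the perimeter
  inside the density shell without stable contacts. The default study
  condition uses 12 sites at bound fraction 0.6 with mean dwell 20 frames
  over 5000 frames: with these kinetics the realization error of the
  across-site mean is ≈0.008, so a ±0.02 recovery band tests the estimator,
  not Markov noise. The truth record stores realized per-site fractions.
* **Structure generator:** Cα clouds or ideal helices under known rigid
  transforms plus optional isotropic noise, and exact two-fold symmetric
  homodimers with an optionally displaced helix.

Passing on these fixtures demonstrates correctness of the estimators and
the fitting machinery, not fidelity to real force-field lipid dynamics,
spectrometer artifacts (phase drift, dead time, orientation selection), or
cryo-EM coordinate error. In particular the generator's lipids have no
internal conformational dynamics, so residence recovery shows contact
bookkeeping is right, not that a 4.0 Å cutoff is optimal for real bilayers.

## Problem sizes and numerical choices

Default analysis sizes: 3 conditions × 300 time points for DEER (multistart
fits take ≈0.2 s; a K = 1..3 BIC scan ≈1 s); 5000 frames × ≈640 atoms for
the binding trajectory; density maps from every 5th frame where maps of the
full bilayer are needed. Multi-seed recovery studies use 20 independent
noise realizations. Degenerate inputs are errors, not silent results: empty
selections warn, empty residue lists / all-rejected pairings / missing
neighbours raise with the offending identifier.

The deposited-model comparisons (accessions 8FMV, 8SZC, 8FPF, 8T3K, 8FHK,
8T1P, 7M33) download coordinates from the RCSB at run time
(`analysis/05_deposited_models.py`); no coordinate files are bundled.

## Known limitations

* No Tikhonov/model-free inversion and no joint fitting across different
  label pairs; BIC is the only model-selection criterion implemented.
* Background dimensionality is fit-fixed at d = 3 unless overridden.
* The residue correspondence between pseudo-symmetric halves must be
  supplied; the package does not perform sequence-independent structural
  alignment.
* No periodic-boundary handling, free-energy estimates, or lipid
  classification beyond the reported metrics.
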