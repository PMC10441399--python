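# Methods

This note documents the models, conventions, default parameters and known
limitations behind each analysis stage of `sytllps`. All empirical numbers
quoted here are produced by the package's own tests or by
`scripts/acceptance.py`.

## 1. Sequence charge metrics (`seqcharge`)

For a sequence of per-residue charges `q_i` (length N):

- `f+ = n+/N`, `f- = n-/N`, `FCR = f+ + f-`, `NCPR = f+ - f-`;
- `SCD = (1/N) * sum_{m>n} q_m q_n sqrt(m - n)`.

The default charge scheme assigns K, R → +1 and D, E → −1, with histidine
neutral — the appropriate assignment at the study pH of 7.4, well above the
His side-chain pKa. An alternative `his-half` scheme (H → +0.5) is
selectable but non-default. Terminal amine/carboxyl charges are excluded
because the linker is an internal fragment of the protein.

**SCD convention sensitivity.** SCD has no single universal normalisation
in the literature: variants differ in the spacing exponent (`sqrt(m-n)` vs
`(m-n)`), the index window, and whether the 1/N factor is applied. This
package uses the most common form above (1/N, square-root spacing,
unordered pairs over the whole input window). For the wild-type syt1
linker (residues 80–142) this yields SCD = −5.24 — strongly negative,
i.e. a blocky, "strong" polyampholyte (FCR = 0.556 > 0.3) expected to
phase separate and to resist moderate salt. Published per-sequence SCD
values computed with other conventions can differ by factors of several;
users comparing against external numbers must confirm the convention.
The packaged WT sequence itself is pinned by independent anchors (19
lysines in 80–142, C82, K98, T112/T125/T128, the C2A boundary at E140)
and reproduces the published FCR exactly.

**JuxtaK fixture.** The lysine-neutralised mutant shipped as
`syt1_linker_juxtak_synthetic.fasta` is a synthetic reconstruction: all
linker lysines except K141 are replaced by glutamine. Only directional
properties (lower FCR than WT; condensate dissolution in the simulator)
are derived from it, and none depends on which polar residue substitutes
or which single lysine is retained.

## 2. Coarse-grained condensate simulator (`cgsim`)

A one-bead-per-residue implicit-solvent model in the hydropathy-scale
(HPS) family, built as a desk-scale surrogate whose job is to reproduce
directional condensate phenomenology, not force-field thermodynamics.

Pair potential between non-bonded beads:

    U(r) = U_AH(r; sigma_ij, lambda_ij, eps) + q_i q_j l_B kB T exp(-kappa r)/r

- **Ashbaugh–Hatch term**: for `r <= 2^(1/6) sigma`,
  `U_AH = U_LJ + (1 - lambda) eps`; beyond, `U_AH = lambda U_LJ`.
  Arithmetic-mean combining rules for `sigma` and `lambda`; cutoff 2 nm.
  Per-residue stickiness `lambda_i` comes from a normalised atomistic
  hydropathy scale embedded in `HYDROPATHY_LAMBDA` (0 = least, 1 = most
  hydrophobic).
- **Debye–Hückel term**: Bjerrum length `l_B = e^2/(4 pi eps0 eps_r kB T)`
  (0.70 nm at 298 K, eps_r = 80) and screening length
  `kappa^-1 = (8 pi l_B N_A I)^(-1/2)` (0.97 nm at 0.1 M); cutoff
  4 kappa^-1. The continuum-water permittivity 80 is used because solvent
  is implicit here.

Defaults: T = 298 K, eps_r = 80, eps = 0.8 kJ/mol, sigma = 0.6 nm
(uniform), harmonic bonds k = 2000 kJ mol⁻¹ nm⁻² at 0.38 nm, uniform bead
mass 110 g/mol, timestep 0.01 ps, friction 1 ps⁻¹, BAOAB Langevin
integration with minimum-image orthorhombic periodic boundaries. The box
edge must exceed twice the largest cutoff. All randomness flows from one
`numpy` generator seeded by `SimConfig.seed`; identical configs give
bit-identical trajectories.

**Initial structures.** Chains are grown as self-avoiding random walks
(per-step direction retries, minimum inter-bead separation 0.35 nm).
Before dynamics, a deterministic force-capped steepest descent (500
steps, ≤0.02 nm/bead/step) removes residual packing strain; an isolated
bead at T = 0 therefore does not move, and diverging energies
(|U| > 1e9 kJ/mol) raise an instability error advising a smaller
timestep.

**Droplet-stability protocol.** Nucleating a condensate from dispersed
chains is far too slow for desk-scale runs (a 63-mer diffuses ~1 nm in
the 400 ps default run), so the default `condition_scan` protocol starts
from a pre-formed droplet (walks confined to a 3.5 nm sphere) and asks
whether inter-chain contacts persist or dissolve — mirroring how
condensate stability is probed against mutation and salt in much larger
simulations. The condensation summary per run is the trailing-quarter
mean of `dQ(t)` (Section 3) plus the final largest-cluster fraction.
Study conditions for the scan: six 63-residue chains in a 12 nm box,
40 000 steps, three seeds. At these conditions the WT linker retains
about 3.5× more inter-chain contact gain than the JuxtaK mutant at 0.1 M,
and the WT droplet loosens monotonically (per seed) from 0.1 M to 1 M.

Known surrogate artifacts: (i) runs are far from equilibrium — only
directional, seed-replicated statements are meaningful; (ii) the
net-charged JuxtaK mutant *gains* contacts at 1 M salt (screened
repulsion, a salting-out effect), so salt monotonicity is claimed for the
WT sequence only; (iii) the largest-cluster fraction percolates easily at
scan density and is reported but not used as an acceptance quantity;
(iv) no pressure coupling, explicit solvent, or coexistence-density
(slab) analysis.

## 3. Condensate metrics (`condensate`)

- **Contact function**: `q_ij = 1/(1 + (r_ij/r0)^6)` with r0 = 0.5 nm —
  the algebraically identical evaluation of the rational switching form
  `(1-(r/r0)^6)/(1-(r/r0)^12)`, removing the removable singularity at
  r = r0 (`q(r0) = 1/2` exactly).
- **Order parameter**: `Q(t)` sums q_ij over all *unordered* distinct
  bead pairs, intra- and inter-chain, bonded neighbours included. The
  unordered convention halves an ordered-pair sum; since only relative
  and directional quantities are consumed downstream, the factor is
  immaterial but fixed here. An `exclude-bonded` policy is selectable;
  the `dQ` baseline subtraction cancels intra-chain constants either way.
- **Baseline**: `<q_single>` is the time-averaged Q of one isolated chain
  simulated under identical conditions; `dQ(t) = Q(t) - N <q_single>`
  then isolates condensation-driven inter-chain contacts (dispersed
  identical chains give dQ ≈ 0; the identity is asserted on every
  `ContactSeries`).
- **Clustering**: chains are graph nodes, connected when any inter-chain
  bead pair lies within 0.8 nm (minimum image); connected components via
  `scipy.sparse.csgraph`.
- **Hydrogen bonds**: a donor–hydrogen–acceptor triple is bonded iff
  d(D,A) < 0.35 nm and the angle *at the donor* between D→A and D→H is
  < 30°. This "A-D-H" convention is implemented exactly as printed in
  the protocols this package follows; the common alternative (deviation
  from linearity at the hydrogen) is selectable via
  `angle_vertex="hydrogen"`. Occupancy = fraction of frames bonded; mean
  continuous lifetime is reported in frames. The PDB convenience reader
  infers donor hydrogens by proximity (H within 0.12 nm of N/O) and
  warns when a structure lacks hydrogens.
- **SASA**: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points, probe 0.14 nm). An isolated sphere reproduces
  `4 pi (rho + probe)^2` to machine precision by construction of the
  accessible-point count; convergence in point count is monotone. Radii:
  embedded van-der-Waals table for atoms, sigma/2 for coarse beads. The
  condensate-masking report compares per-residue SASA between condensate
  and isolated contexts with a seeded bootstrap 95% CI over frames
  (default 1000 resamples).

## 4. Sequential-site ITC model (`itc`)

The "n sequential binding sites" model: stepwise macroscopic dissociation
constants `K_d1..K_dn` (µM) and per-step enthalpies `dH_1..dH_n`
(kcal/mol). With `beta_i = prod_{j<=i} 1/K_dj`,

    F_i([X]) = beta_i [X]^i / sum_j beta_j [X]^j     (beta_0 = 1)
    Q_cell   = M_t V_0 sum_i F_i (dH_1 + ... + dH_i)

Free ligand solves `X_t = [X] + M_t sum_i i F_i([X])` — strictly monotone,
solved by safeguarded Newton to residual < 1e-10·max(1, X_t). Injections
use exact-mixing dilution (cell scaled by `1 - dV/V0`, then ligand added)
and the displaced-volume correction
`dQ_k = Q_k - Q_{k-1} + (dV_k/V0)(Q_k + Q_{k-1})/2`. Generator and fitter
share this scheme, so synthetic round-trips are exact in the noiseless
limit. Heat-of-dilution blanks are modelled as already subtracted
(an estimable constant offset would be the natural extension).

**Fitting.** Weighted trust-region least squares; binding constants are
parametrised as `log10 K_d1` plus non-negative log-increments, enforcing
`K_d1 <= ... <= K_dn`. The ordering matches the statistical-factor
behaviour of macroscopic stepwise constants and removes label-swap
near-degeneracies. Multi-start (default 32 log-spaced ladders) with a
cheap screening pass and deep polishing of the best candidates;
deterministic given a seed. Model order is compared by small-sample AICc.

**Identifiability and the `fixed_dh` protocol.** With all 2n parameters
free, the sequential model admits enthalpy–affinity compensation: an
arbitrarily tight phantom first site whose heat is redistributed over the
remaining steps changes the predicted titration by less than realistic
instrument noise (profile likelihood: moving K_d1 four decades changes
the attainable SSR by ~2e-5 µcal² against noise-level SSR fluctuations of
~5e-4 µcal²). Joint recovery of K_d1 from a single noisy titration is
therefore impossible for any estimator, even though the noiseless
round-trip recovers every parameter to ~1e-12 relative. The recommended
affinity-recovery protocol (`fixed_dh=...`) holds the per-step enthalpies
at their known calorimetric values and fits only the binding constants,
which are then sharply identified: K_d1 is recovered within a few percent
at 0.05 µcal noise for all three ground-truth parameter sets.

**Ground-truth fixture.** `data/itc_ground_truth.json` stores the
published stepwise K_d estimates for the three constructs (five-site
80-421 and 96-421; four-site JuxtaK) together with synthetic per-step
enthalpies: +4..+8 kcal/mol (endothermic) for the two wild-type-linker
constructs and −3..−9 kcal/mol (exothermic) for JuxtaK, matching the sign
of the measured reactions. Mixed endo-/exothermic steps are deliberately
avoided: cancelling heats flatten the isotherm and destroy affinity
identifiability — the same pathology that makes the linker-less construct
unfittable in practice.

**Model selection noise regime.** At 0.05 µcal noise the weakest fifth
site (K_d5 ≈ 2.5–2.9 mM, barely populated at the final free-Ca²⁺ of
~1.4 mM) is statistically unsupported and AICc correctly prefers four
sites; site-count recovery is therefore checked in the low-noise regime
(0.005 µcal), where AICc returns 5 for 5-site data and 4 for 4-site data.

## 5. FRAP (`frap`)

Normalisation: `(F_bleach - F_bg) / (F_nonbleached - F_bg)` per frame —
invariant to detector offset and to affine gain applied consistently to
all channels, and cancelling acquisition bleaching that affects bleached
and reference droplets equally. Time zero is the end of the bleach;
pre-bleach frames only set the pre-bleach intensity scale (no double
normalisation by default, since the normalisation formula has no
pre-bleach term).

Recovery model: `F(t) = F0 + (F_inf - F0) t/(t_half + t)` (3-parameter
hyperbola; `F(t_half) = (F0+F_inf)/2` by construction; a 2-parameter
F0 = 0 form is selectable). Mobile fraction `(F_inf - F0)/(1 - F0)`.

Pooling: per-experiment ROI means are combined with Bessel weights
`(n_i - 1)` — `s²_pooled = sum (n_i-1) s_i² / sum (n_i-1)` — and the SEM
of the pooled mean uses `sqrt(sum n_i)` in the denominator (the "mean ±
SEM" convention adopted here; single-ROI experiments carry zero variance
weight).

Generator defaults emulate the acquisition protocol: 15 frames/min
(4 s/frame), 60 s pre-bleach, 12 min recovery (180 recovery frames), six
experiments of 6–10 ROIs totalling 47, ground truth `t_half = 64 s`,
`F0 = 0.2`, `F_inf = 0.85` (realistic partial-bleach depth and plateau
for a liquid droplet), 5% relative ROI-to-ROI parameter jitter, mild
mono-exponential acquisition bleaching on both channels and Gaussian
noise (sd 0.02 of the normalised scale) on the bleached channel. The
full generate → normalise → pool → fit chain recovers the half-time to
well within 5% over three seeds.

## 6. Droplet imaging (`imaging`)

The segmentation chain mirrors the Fiji workflow: 256-bin Otsu
auto-threshold (IsoData selectable as the `isodata` method), 8-connected
component labelling, minimum area 4 px, per-droplet area (px² and µm²),
mean intensity and centroid. Synthetic fields render non-overlapping
pixel-exact disks, optionally convolved with a Gaussian PSF and corrupted
by Poisson shot noise plus Gaussian read noise, returning exact ground
truth. Droplet counts are exact on noiseless fields and within ±1 at
moderate noise; under a PSF the sub-pixel rim assignment is intrinsically
ambiguous, so mask-recovery statements are made about disk interiors
(eroded by the PSF width).

Phase diagrams over a condition grid use the operational presence rule
"≥ 5 droplets with median area ≥ 4 px²" per cell (a proxy for by-eye
droplet/no-droplet scoring). Condition comparisons report the count
ratio, area/intensity summaries, and a two-sided Mann–Whitney test —
exact by full enumeration of `C(n1+n2, n1)` labelings (tie-aware, point
mass included on both sides, so identical samples give p = 1) when both
samples have ≤ 8 droplets, tie-corrected normal approximation otherwise.

## 7. Reproducibility plumbing (`cli`)

Each stage validates its parameters against an explicit schema (unknown
keys are rejected by name), writes outputs atomically, and emits a
manifest JSON with input paths, output SHA-256 checksums, parameters,
seed and package versions. One global seed expands to per-stage seeds via
`crc32("<stage>:<seed>") & 0x7fffffff`, so stages are independently
replayable. `demo_pipeline` chains every stage at the demo scale above
(≈7 minutes on one CPU; a `tiny` scale exists for smoke testing) and
writes `demo_report.json` with the headline quantities.

## 8. Problem sizes

Defaults were chosen so the whole pipeline runs on a single CPU at
desk scale: condensate scans use six 63-residue chains for 40 000 steps
(0.4 ns) per condition with three seeds; ITC recovery fits 19-injection
titrations with 32 starts in a few seconds each; FRAP datasets hold 47
ROIs of 180 frames; droplet fields are 256×256 px. These sizes are three
to five orders of magnitude below the simulations they emulate, which is
why the simulator's claims are directional rather than quantitative.
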