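# Methods

This note documents the models implemented in `allonmr`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that were genuinely open.

## Two-state fast-exchange framework

All NMR stages assume the kinase domain exchanges between an autoinhibited
and an active conformer fast on the chemical-shift timescale.  Observed
shifts are then population-weighted averages,
δ_obs = (1 − p)·δ_inh + p·δ_act, so a panel of perturbations (activating
mutations, activation-loop phosphorylation) that only move the population p
displaces every responsive residue along a straight line in the spectrum.
This single assumption links the stages: CSPs scale with |Δp|, CHESCA
correlations of responsive residues approach |r| = 1, and CPMG dispersion
amplitudes carry Φ = p_A·p_B·Δω².

## Chemical-shift perturbations (`csp`)

Combined CSP: Δδ = √((α·Δδ_X)² + Δδ_H²), α = 0.154 for ¹⁵N amide data and
0.25 for ¹³C methyl data, applied uniformly to Ile, Leu and Val methyls.
Significance is a strict inequality at the 0.02 ppm default cutoff.  A peak
assigned in the reference but missing in the perturbed state is its own
category ("disappeared") rather than a large CSP, because exchange
broadening beyond detection carries different information than a shift.
Intensity retention is the perturbed/reference height ratio with an
attenuation threshold of 0.8; a zero reference height flags the ratio
undefined instead of raising.  Structure mapping writes the per-residue
scalar into the B-factor column of a cloned structure, sentinel −1.0 for
unmapped residues; residue-number translation between constructs is always
an explicit user-supplied map, never inferred.

## PRE distances (`pre`)

The oxidized/reduced retention is inverted through
I_ox/I_red = R₂,dia·exp(−Γ₂·t)/(R₂,dia + Γ₂) (strictly decreasing in Γ₂;
Brent root search, relative tolerance 10⁻¹⁰), then
r⁶ = (K/Γ₂)·(4τc + 3τc/(1 + ω_H²τc²)) with K = 1.23×10⁻³² cm⁶s⁻².
Defaults: τc = 22.2 ns, 600 MHz.  The diamagnetic rate and total transfer
time are not observable from a retention table alone; the defaults
R₂,dia = 40 s⁻¹ (appropriate for a ~35 kDa two-lobed kinase domain at 25 °C)
and t = 10 ms (a standard amide transfer period) are config-overridable.
Under these defaults retention 0.6 converts to 20.1 Å, consistent with the
~19 Å benchmark within the ±4 Å uncertainty quoted for spin-label distances
(the flexible MTSL linker dominates the error budget; the plain isotropic
point-dipole form is used, no order-parameter correction).  Branching:
an absent oxidized peak is a < 10 Å lower bound; retention ≥ 0.98 or a
calculated distance ≥ 25 Å is a > 25 Å upper bound; retentions above 1
(noise) are upper bounds, never errors.  At 22.2 ns and 600 MHz the
Lorentzian term contributes < 0.05% of 4τc, so the conversion is
effectively field-independent.

## CPMG dispersion (`cpmg`)

R2,eff = −ln(I_ν/I₀)/T with T = 40 ms; non-positive intensities become
flagged missing points.  ΔR2,eff = mean R2,eff(50 Hz) − mean R2,eff(1000 Hz),
replicates averaged for display only; dispersions are significant strictly
above 2 s⁻¹, and a residue enters the global fit only if significant at
every field where it was recorded.  The fast-exchange Luz–Meiboom profile
is fitted by bounded least squares with duplicates kept as separate
residuals, weighted by a pooled noise estimate from duplicate differences
((x₁−x₂)²/2 per pair; unit weights when no duplicates exist).  The
Φ–k_ex trade-off makes the cost surface shallow, so fits multi-start from
k_ex ∈ {500, 1000, 2000, 4000, 8000} s⁻¹; the lowest final cost wins and
ties break toward the smaller k_ex.  Parameterization: one k_ex (shared per
residue in individual mode, across everything in global mode), one Φ per
residue at the 600 MHz reference field with Φ scaled by the squared field
ratio at other fields (Δω is proportional to B₀; ¹H shift contributions are
taken as zero for the methyl multiple-quantum data), and one exchange-free
baseline R2⁰ per curve.  The global k_ex uncertainty is reported as the
standard deviation of the per-residue individual fits, which is the
convention the dispersion literature uses when individual fits justify a
global one.  No slow/intermediate-exchange (Carver–Richards) model is
provided; data outside the fast regime are out of scope.

## CHESCA (`chesca`)

CCS = 0.2·δ_N + δ_H over the residues present in every state (≥ 3 states
required).  Before correlation, residues whose shift difference between the
unphosphorylated and phosphorylated reference states is below 10 Hz in ¹H
and 5 Hz in ¹⁵N are excluded; the thresholds convert to ppm using the
panel's ¹H frequency and the ¹⁵N/¹H gyromagnetic ratio (0.10136919).  The
exclusion rule is read as AND by default — a residue moving strongly in
either dimension is informative — with OR available behind a flag, since
the sentence-level convention differs between labs.  Residue clustering:
Pearson correlation of CCS profiles, complete linkage on 1 − |r|, clusters
cut as the *maximal subtrees whose every pair satisfies |r| ≥ 0.97*,
verified exactly on the correlation matrix rather than through merge
heights (floating-point-safe); singletons are discarded, zero-variance
profiles dropped with a warning, and residues are sorted before linkage so
ties at equal merge heights resolve deterministically.  Validation: per
cluster, a complete-linkage state dendrogram on Euclidean distances over
standardized profiles (standardization affects only these dendrograms —
Pearson correlation is scale-invariant); pooled over clusters, an SVD of
the states × residues matrix with each residue profile centered, reporting
the PC1 variance fraction and per-residue loadings.  One shared
conformational equilibrium puts every network residue on PC1 with a single
sign pattern.  Dendrograms are serialized as Newick with branch lengths
equal to merge-height differences.

## Structure geometry (`geometry`)

Measurements are plain coordinate geometry on one chain of one PDB model
(altloc A or blank retained): Euclidean atom distances, the signed
N–CA–CB–γ χ1 dihedral in (−180°, 180°], and polar contacts as the minimal
heavy-atom N/O distance between selections — no hydrogen placement and no
angle term, matching how such contacts are quoted in crystal-structure
figures.  Cutoffs: 3.5 Å for hydrogen bonds, 4.0 Å for salt bridges,
4.5 Å for the αC-tether van der Waals contact; all configurable.  The
four-site report measures, per structure and residue map: the brake-triad
side-chain contacts (engaged when at least two of the three N/E/K pairs are
within the H-bond cutoff — the triad is a chained hydrogen-bond network,
and requiring two edges tolerates one borderline distance); the DFG-Phe
ring tip (Cζ) to the nearest side-chain carbon of each latch partner (CG1
convention for branched residues, minimum over γ/δ carbons available); the
A-loop aspartate side chain to the two methionine Sδ/Cε atoms; the minimal
arginine-Nη/Nε to aspartate-Oδ plug distance; the DFG-Phe χ1; and a β9
fingerprint — at least two backbone N–O pairs within the H-bond cutoff
between the A-loop strand (DFG+2 … DFG+7) and the catalytic-loop strand
(plug aspartate ± 3).  Classification is a pure function of these fields:
activated-like when the brake is disengaged, the plug broken and the closer
tether contact ≤ 4.5 Å; autoinhibited-like when brake and plug are both
engaged; otherwise mixed.  A `fetch_structure` helper downloads wwPDB
entries when network is available; all tests of the measurement code run on
generated fixtures.

## Synthetic generators (`simulate`)

*State panels*: 300 residues (numbering from 459, mirroring a kinase-domain
construct) with an 18-residue network spread evenly through the sequence;
seven states with active-state populations 0, 0.15, 0.30, 0.45, 0.60, 0.75
and 1 (unphosphorylated WT, five graded A-loop mutants, phosphorylated WT).
Network Δω magnitudes are drawn from 0.05–0.12 ppm (¹H) and 0.5–1.2 ppm
(¹⁵N) with a common sign per residue so the two dimensions reinforce in the
CCS; shift noise is 0.002 ppm ¹H / 0.02 ppm ¹⁵N, i.e. a CCS noise of
~0.005 ppm against network CCS amplitudes of 0.15–0.36 ppm, which keeps
planted pairwise correlations above ~0.99 while unperturbed residues stay
uncorrelated.  *Dispersion*: six ILV methyl probes at 600 and 800 MHz on
the nine-frequency grid (50–1000 Hz) in duplicate, k_ex = 2000 s⁻¹, Φ
values 8 000–17 100 s⁻² (ΔR2,eff ≈ 3–8 s⁻¹ at 600 MHz), R2⁰ = 20 s⁻¹,
Gaussian noise σ = 0.3 s⁻¹.  *PRE*: heights from the forward ratio relation
with multiplicative log-normal noise (σ = 0.02) and a 0.5% detection limit
below which the oxidized peak is reported absent.  *Structures*: minimal
PDB files whose marker residues sit at exactly known coordinates, arranged
as spatially separated site islands so each measurement is independent;
the χ1 fixture builds side chains by internal-coordinate placement, exact
to coordinate precision.

What the generators do **not** emulate: peak overlap and assignment
ambiguity, temperature/concentration referencing drifts, anisotropic
tumbling and spin-label rotamer ensembles, intermediate-exchange
lineshapes, and correlated (non-Gaussian) noise.  Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
two-state model, not robustness to every pathology of real spectra.

## Problem sizes and determinism

Default test workloads are desk-scale by construction: 300-residue panels,
six-residue two-field dispersion sets, and 50-replicate recovery studies,
which keep the full suite in the seconds-to-minutes range on one core.
Every stochastic path takes a single integer seed (NumPy `default_rng`),
and identical seeds reproduce outputs bit-for-bit, including written TSV
and PDB artifacts.

## Known limitations

- The PRE conversion's R₂,dia and transfer time are defaults, not fitted;
  absolute distances inherit that choice, though the ±4 Å band absorbs it
  over the sensitive 10–25 Å range.
- Global dispersion fitting assumes pure fast exchange; k_ex estimates
  bias upward as Δω approaches k_ex.
- CHESCA cluster membership is sharp at the |r| cutoff; residues at the
  boundary flip with noise realization, which is inherent to the method.
- The β9 detector is a fingerprint, not a secondary-structure assignment;
  it requires the catalytic-loop strand to be resolved in the model.
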