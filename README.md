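# allonmr

Solution-NMR and structural analysis of long-range allosteric networks in
protein kinases — built around the four-site autoinhibition model of FGFR-family
kinase domains (molecular brake, DFG latch, αC tether, A-loop plug), but usable
for any two-state conformational-exchange system probed by a panel of protein
states.

The package is aimed at structural-NMR practitioners who have tabulated peak
lists, CPMG dispersion tables, PRE height pairs and PDB coordinates, and want
the downstream quantitative analysis reproducible and testable:

- **CSP** — combined chemical-shift perturbations between two states,
  Δδ = √((α·Δδ_X)² + Δδ_H²) with α = 0.154 (¹⁵N) or 0.25 (¹³C), a 0.02 ppm
  significance cutoff, disappeared-peak tracking, intensity retentions
  (attenuated below 0.8), and mapping onto a structure's B-factor column.
- **PRE** — nitroxide spin-label distances from oxidized/reduced peak-height
  ratios via the Battiste–Wagner relation
  I_ox/I_red = R₂,dia·e^(−Γ₂t)/(R₂,dia + Γ₂) and the dipolar law
  r⁶ = (K/Γ₂)(4τc + 3τc/(1 + ω_H²τc²)), with the ~10 Å / ~25 Å sensitivity
  bounds and a ±4 Å uncertainty on measured distances.
- **CPMG** — constant-time R2,eff = −ln(I/I₀)/T, ΔR2,eff significance
  (> 2 s⁻¹ between 50 and 1000 Hz), and fast-exchange Luz–Meiboom fitting
  R2,eff(ν) = R2⁰ + (Φ/k_ex)(1 − (4ν/k_ex)·tanh(k_ex/4ν)),
  per residue or globally across residues and fields (Φ scaling with the
  squared field ratio).
- **CHESCA** — chemical-shift covariance analysis: CCS = 0.2·δ_N + δ_H,
  Hz-threshold residue filtering, complete-linkage clustering at |r| ≥ 0.97
  with an exact all-pairs guarantee, state dendrograms (Newick) and SVD
  validation of a common network.
- **Structure geometry** — distances, χ1 dihedrals, H-bond/salt-bridge
  contacts, β9-strand detection, and a four-site report classifying a kinase
  structure as autoinhibited-like or activated-like.
- **Synthetic data** — a two-state fast-exchange generator (population-weighted
  shift averaging over a state panel), Luz–Meiboom forward simulation, the PRE
  forward model, and exact-coordinate PDB fixtures, so every stage has a
  parameter-recovery test with known ground truth.

## Worked example

Simulate the standard seven-state panel plus dispersion and PRE tables, then
run three stages:

```sh
allonmr simulate --out-dir demo --seed 1
allonmr cpmg   --curves demo/cpmg_curves.tsv --out-dir demo/cpmg
allonmr chesca --peaklists WT_unphos=demo/peaklist_WT_unphos.tsv \
               --peaklists K659T=demo/peaklist_K659T.tsv \
               --peaklists K659N=demo/peaklist_K659N.tsv \
               --peaklists K659Q=demo/peaklist_K659Q.tsv \
               --peaklists K659M=demo/peaklist_K659M.tsv \
               --peaklists K659E=demo/peaklist_K659E.tsv \
               --peaklists WT_phos=demo/peaklist_WT_phos.tsv \
               --out-dir demo/chesca
allonmr pre    --heights demo/pre_heights.tsv --out-dir demo/pre
```

prints

```
simulated inputs written to demo
k_ex = 2016 +/- 55 s-1
1 clusters, 18 residues, PC1 variance fraction 0.999
4 PRE distances written
```

The global dispersion fit recovers the generator's exchange rate
(2000 s⁻¹) within its quoted uncertainty — the ± value is the standard
deviation of the per-residue individual fits.  Covariance clustering finds one
cluster containing exactly the 18 planted network residues, and their CCS
profiles lie on a single principal component (variance fraction 0.999),
i.e. one underlying equilibrium coordinate.  The PRE table
(`demo/pre/pre_distances.tsv`) shows the three sensitivity regimes:

```
residue_number  retention  distance  bound
466             1.0055     25        upper_bound_long
656             0.485495   18.8317   measured
657             0.497036   18.9519   measured
704             0          10        lower_bound_short
```

Residues 656/657 (simulated at 19 Å) come back at ~18.9 ± 4 Å; 704 (7 Å) is
broadened beyond detection, a < 10 Å lower bound; 466 (46 Å) is outside PRE
range, a > 25 Å upper bound.

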