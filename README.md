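# bindspec

Spectroscopic analysis of small-molecule binding to proteins — the classic
serum-albumin drug-binding workup — as a tested, reusable Python pipeline.
For researchers who titrate a fluorescent protein (e.g. bovine serum albumin,
intrinsic tryptophan emission at ~344 nm) with increasing ligand and want the
standard quantities with auditable numerics:

- **Stern–Volmer quenching fit** F₀/F = 1 + K_sv[Q], the bimolecular rate
  constant K_q = K_sv/τ₀, and the **static vs. dynamic mechanism call** from
  the temperature trend of K_sv and the diffusion limit (2×10¹⁰ L mol⁻¹ s⁻¹);
- **binding constant and stoichiometry** from the double-log fit
  log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q];
- **van't Hoff thermodynamics** log₁₀K_b = −ΔH°/2.303RT + ΔS°/2.303R,
  ΔG° = ΔH° − TΔS° (with −RT ln K_b as a cross-check), and binding-force
  classification from the signs of ΔH° and ΔS°;
- optional **inner-filter correction** F_corr = F_obs·e^((A_ex+A_em)/2);
- **CD secondary-structure fractions** by simplex-constrained least-squares
  unmixing against a basis set (molar ellipticity [θ] = 100·θ/(C·l));
- **UV trend and FT-IR amide-band peak shifts** with sub-grid parabolic
  peak refinement.

A synthetic-data generator with recorded ground truth (quenching law
F = F₀/(1 + K_b·Qⁿ), van't Hoff-consistent K_b(T), CD mixtures, Lorentzian
bands) makes every stage verifiable by exact parameter recovery — see
`docs/methods.md` for the model, assumptions and limitations.

## Worked example

Generate a synthetic study (three temperatures, 15 μM protein, ligand
0–120 μM, exothermic binding with ΔH° = −128.47 kJ/mol,
ΔS° = −359.49 J mol⁻¹ K⁻¹) and analyse it:

```sh
bindspec simulate --out demo --seed 42
bindspec report demo/config.yaml
```

which prints

```
bundle written; analysis config: demo/config.yaml
report written to demo/report
mechanism: static
force class: hbond_vdw
```

and writes `demo/report/quenching_table.tsv`:

```
temperature_K  Ksv_1e4_L_per_mol  Kq_1e12_L_per_mol_s  Kb_1e3_L_per_mol  n_sites
288.0          3.3278             3.3278               33.28             1.0
298.0          0.5500             0.5500               5.50              1.0
308.0          0.1022             0.1022               1.02              1.0
```

Reading the numbers: K_sv falls as temperature rises while every
K_q (~10¹¹–10¹² L mol⁻¹ s⁻¹) sits far above the 2×10¹⁰ diffusion limit, so
quenching is *static* — a ground-state complex, not collisions. The binding
constant at 298 K (5.50×10³ L/mol) with n ≈ 1 means moderate 1:1 binding.
`thermo_table.tsv` then gives, per temperature:

```
temperature_K  Kb_1e3  dG_kJ_per_mol  dG_from_Kb_kcal_per_mol  dS_J_per_mol_K  dH_kJ_per_mol  force_class
298.0          5.50    -21.34         -5.1                     -359.49         -128.47        hbond_vdw
```

ΔG° < 0: binding is spontaneous; ΔH° < 0 and ΔS° < 0: driven by hydrogen
bonding and van der Waals contacts (exothermic, entropically penalised).
The recovered ΔH°/ΔS° equal the generating truth because the titrations are
noiseless; rerun `simulate` with `--noise-sd 0.02` to see realistic scatter.
The same report covers the CD helix-loss trend, the UV 278 nm flag and the
amide I/II peak shifts when those inputs are configured.

Each stage is also available as its own subcommand (`quench`, `thermo`,
`cd`, `bands`) over plain two-column text spectra and YAML titration
manifests, and as library functions (`bindspec.fit_stern_volmer`,
`fit_binding`, `fit_vant_hoff`, `estimate_secondary_structure`, ...).

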