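# Study-shaped simulation profile: 4 rhizosphere + 15 endosphere strains,
# 190 carbon compounds in 9 classes, a 1500-site marker gene, and the
# published pan-genome Venn decomposition as exact planting targets.
n_rhizosphere: 4
n_endosphere: 15

# occupancy_rhizosphere/occupancy_endosphere -> cluster count
venn_counts:
  all/all: 3255
  all/some: 731
  some/all: 52
  some/some: 3157
  some/none: 268
  none/some: 3212

classes:
  - {name: carboxylic acids, size: 35, frac_rhizosphere: 0.75, frac_endosphere: 0.45}
  - {name: amino acids, size: 25, frac_rhizosphere: 0.80, frac_endosphere: 0.55}
  - {name: peptides, size: 15, frac_rhizosphere: 0.20, frac_endosphere: 0.55}
  - {name: sugar acids, size: 15, frac_rhizosphere: 0.25, frac_endosphere: 0.60}
  - {name: nucleosides, size: 10, frac_rhizosphere: 0.15, frac_endosphere: 0.55}
  - {name: monosaccharides, size: 25, frac_rhizosphere: 0.40, frac_endosphere: 0.70}
  - {name: substituted monosaccharides, size: 20, frac_rhizosphere: 0.55, frac_endosphere: 0.30}
  - {name: sugar alcohols, size: 15, frac_rhizosphere: 0.60, frac_endosphere: 0.35}
  - {name: miscellaneous, size: 30, frac_rhizosphere: 0.25, frac_endosphere: 0.45}

traits:
  - {name: siderophore_production, prevalence_rhizosphere: 1.0, prevalence_endosphere: 0.95}
  - {name: phosphate_solubilization, prevalence_rhizosphere: 0.25, prevalence_endosphere: 0.55}
  - {name: denitrification, prevalence_rhizosphere: 0.0, prevalence_endosphere: 0.3}
  - {name: protease_activity, prevalence_rhizosphere: 0.5, prevalence_endosphere: 0.7}
  - {name: sucrose_degradation, prevalence_rhizosphere: 0.5, prevalence_endosphere: 0.8}
  - {name: galactose_degradation, prevalence_rhizosphere: 0.0, prevalence_endosphere: 0.45}
  - {name: acc_deaminase, prevalence_rhizosphere: 0.0, prevalence_endosphere: 0.4}
  - {name: trehalose_uptake, prevalence_rhizosphere: 0.5, prevalence_endosphere: 0.65}

reactions:
  core: 1151
  shared_non_core: 175
  rhizosphere_only: 1
  endosphere_only: 105

prediction_error_rate: 0.24
marker_length: 1500
mutation_rate: 0.005
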