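# Pest/disease targets and their spray-coverage class.
#
# application_class drives the target factor f_target:
#   internal     -> 1.00  (whole canopy must be reached)
#   intermediate -> 0.75  (two thirds of the canopy)
#   external     -> 0.49  (outer third of the canopy)
#
# `warnings` are message identifiers resolved by citrusvol.messages.
# `aliases` are accepted case-insensitively by the lookup.
targets:
  # ------------------------------------------------------------------ internal
  - name: California red scale
    aliases: [Aonidiella aurantii, CRS, red scale]
    application_class: internal
  - name: Oleander scale
    aliases: [Aspidiotus nerii]
    application_class: internal
  - name: Two-spotted spider mite
    aliases: [Tetranychus urticae, TSM]
    application_class: internal
  - name: Citrus red mite
    aliases: [Panonychus citri, red mite]
    application_class: internal
  - name: Citrus mealybug
    aliases: [Planococcus citri]
    application_class: internal
  - name: Citrophilus mealybug
    aliases: [Pseudococcus citri]
    application_class: internal
  - name: Black scale
    aliases: [Saissetia oleae]
    application_class: internal
  - name: Chinese wax scale
    aliases: [Ceroplastes sinensis]
    application_class: internal
  - name: Brown soft scale
    aliases: [Coccus hesperidum]
    application_class: internal
  - name: Cottony cushion scale
    aliases: [Icerya purchasi]
    application_class: internal
    warnings: [no_authorized_products]
  - name: Citrus brown spot (autumn applications)
    aliases: [Alternaria alternata (autumn), alternaria autumn]
    application_class: internal
  # -------------------------------------------------------------- intermediate
  - name: Citrus thrips
    aliases: [Pezothrips kellyanus, thrips]
    application_class: intermediate
  - name: Cotton aphid
    aliases: [Aphis gossypii]
    application_class: intermediate
  - name: Green citrus aphid
    aliases: [Aphis spiraecola]
    application_class: intermediate
  - name: Woolly whitefly
    aliases: [Aleurothrixus floccosus]
    application_class: intermediate
  - name: Citrus leafminer
    aliases: [Phyllocnistis citrella]
    application_class: intermediate
  - name: Carob moth
    aliases: [Ectomyelois ceratoniae]
    application_class: intermediate
  - name: Honeydew moth
    aliases: [Cryptoblabes gnidiella]
    application_class: intermediate
  - name: Citrus brown spot (spring applications)
    aliases: [Alternaria alternata (spring), alternaria spring]
    application_class: intermediate
  - name: Brown rot of citrus fruit
    aliases: [Phytophthora brown rot]
    application_class: intermediate
  - name: Phytophthora foot rot and gummosis
    aliases: [foot rot, gummosis, Phytophthora foot rot]
    application_class: intermediate
    warnings: [trunk_application]
  # ------------------------------------------------------------------ external
  - name: Mediterranean fruit fly
    aliases: [Ceratitis capitata, medfly]
    application_class: external
    warnings: [bait_treatment]
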