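# Active-ingredient registry.
#
# moa_class drives the minimum required leaf deposit D (uL/cm2):
#   contact     -> 3.41  (organophosphate reference)
#   suffocating -> 4.72  (mineral-oil reference)
#
# Ingredients without their own deposit model are classed `contact` here
# (the safety-side reference) unless flagged suffocating; the classification
# lives in this file so it can be revised without touching code.
products:
  - active_ingredient: chlorpyrifos
    moa_class: contact
  - active_ingredient: mineral oil
    aliases: [paraffin oil, petroleum oil]
    moa_class: suffocating
  - active_ingredient: pyriproxyfen
    moa_class: contact
  - active_ingredient: abamectin
    moa_class: contact
  - active_ingredient: spirodiclofen
    moa_class: contact
  - active_ingredient: spirotetramat
    moa_class: contact
  - active_ingredient: etoxazole
    moa_class: contact
  - active_ingredient: clofentezine
    moa_class: contact
  - active_ingredient: tetrazine
    moa_class: contact
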