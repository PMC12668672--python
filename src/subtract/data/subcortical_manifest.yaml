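# Cortico-subcortical protocol roster: 11 bilateral tracts plus the
# commissural anterior commissure, expanding to 23 tract instances.
space: template
tracts:
  - {name: AMF,   laterality: bilateral}    # amygdalofugal pathway
  - {name: UF,    laterality: bilateral}    # uncinate fasciculus (revised)
  - {name: FX,    laterality: bilateral}    # fornix (revised)
  - {name: MB,    laterality: bilateral}    # Muratoff bundle / subcallosal fasciculus
  - {name: StB_f, laterality: bilateral}    # striatal bundle, frontal part
  - {name: StB_m, laterality: bilateral}    # striatal bundle, sensorimotor part
  - {name: StB_t, laterality: bilateral}    # striatal bundle, temporal part
  - {name: StB_p, laterality: bilateral}    # striatal bundle, parietal part
  - {name: EmC_f, laterality: bilateral}    # extreme capsule, frontal part
  - {name: EmC_t, laterality: bilateral}    # extreme capsule, temporal part
  - {name: EmC_p, laterality: bilateral}    # extreme capsule, parietal part
  - {name: AC,    laterality: commissural}  # anterior commissure (revised)
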