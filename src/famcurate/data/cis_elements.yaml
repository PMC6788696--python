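# Default cis-regulatory element library: consensus placeholders.
#
# The original survey scored AuxRE and B-ARR-6-BA sites with position
# weight matrices from an external database that is not redistributed
# here; these entries are canonical consensus stand-ins (the AuxRE core,
# and a degenerate type-B ARR binding core), user-editable.

- name: AuxRE
  consensus: TGTCTC

- name: B-ARR-6-BA
  consensus: RGATTN
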