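# Default WOX peptide-signature library.
#
# The HD nonapeptides and the two EAR variants are printed diagnostics and
# are encoded exactly.  The remaining clade motifs (WUS-box, T1WOX, T2WOX,
# WOX2, WOX1/6, WOX4) are published only as sequence logos, so the
# patterns below are SYNTHETIC placeholders: short stand-in consensi used
# by the synthetic-data generator and meant to be replaced by users with
# patterns derived from their own alignments.
#
# Pattern syntax: capital letter = itself; [DE] = character class;
# x = any residue.  kind: hd-signature | superclade-motif | clade-motif.
# region: hd-internal | upstream-of-hd | downstream-of-hd | c-terminal.

- name: hd_signature_t1
  pattern: NVYNWFQNR
  label: T1
  kind: hd-signature
  region: hd-internal

- name: hd_signature_t2
  pattern: NVFYWFQNR
  label: T2
  kind: hd-signature
  region: hd-internal

- name: hd_signature_t3
  pattern: NVFYWFQNH
  label: T3
  kind: hd-signature
  region: hd-internal

# WUS-box: shared by most T3 proteins; figure-only in the source study,
# synthetic placeholder pattern.
- name: wus_box
  pattern: TLxLFP
  label: T3
  kind: superclade-motif
  region: downstream-of-hd

# EAR repression-motif variants (printed diagnostics).
- name: ear_wox5_7
  pattern: L[DE]LRLS
  label: WOX5/7
  kind: clade-motif
  region: c-terminal

- name: ear_wus
  pattern: L[DE]L[ST]LN
  label: WUS
  kind: clade-motif
  region: c-terminal

# Clade motifs below are synthetic placeholders (figure-only in the source
# study); edit to taste.
- name: t1wox_motif
  pattern: WQDPSKF
  label: WOX10/13/14
  kind: clade-motif
  region: upstream-of-hd

- name: t2wox_motif
  pattern: VFINSQLQG
  label: WOX8/9-11/12
  kind: clade-motif
  region: downstream-of-hd

- name: wox2_motif
  pattern: CSNAGEW
  label: WOX2
  kind: clade-motif
  region: c-terminal

- name: wox1_6_motif
  pattern: SQFMGQD
  label: WOX1/6
  kind: clade-motif
  region: downstream-of-hd

- name: wox4_motif
  pattern: DQYHHGS
  label: WOX4
  kind: clade-motif
  region: upstream-of-hd
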