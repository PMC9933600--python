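# Schema for the 20-PNP zeta-potential modeling table.
id_column: structure_id
core_name_column: core
coating_name_column: coating
endpoint_column: zeta_mV
split_column: split
predicted_column: zeta_pred_mV
descriptors:
  AMW-P: {block: core, kind: continuous}
  nCsp2-C: {block: coating, kind: count}
  CC1rs: {block: corona, kind: binary}
  AA-I: {block: corona, kind: binary}
  kininogen-1: {block: corona, kind: binary}
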