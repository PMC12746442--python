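# Role annotation for the synthetic kink-turn template built by
# kturn.synthetic.  Residue numbering is the template's own (bulged strand
# then non-bulged strand on chain A); real structures need their own config
# because numbering schemes differ between deposits.
roles:
  C_-1b: {chain: A, resnum: 1}
  G_1b:  {chain: A, resnum: 2}
  A_2b:  {chain: A, resnum: 3}
  A_3b:  {chain: A, resnum: 4}
  G_L1:  {chain: A, resnum: 5}
  A_L2:  {chain: A, resnum: 6}
  A_L3:  {chain: A, resnum: 7}
  G_-1n: {chain: A, resnum: 11}
  A_1n:  {chain: A, resnum: 12}
  G_2n:  {chain: A, resnum: 13}
  G_3n:  {chain: A, resnum: 14}
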