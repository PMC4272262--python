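# Nearest-neighbor molar absorption parameters for single-stranded DNA at
# 260 nm, 25 C, neutral pH (Cantor, Warshaw & Shapiro convention, as used by
# oligo vendors).  Units: mM^-1 cm^-1.  The dinucleotide values are the
# "pair" values 2*eps(NpN'); the per-strand coefficient is
#     eps = sum(pair values over all dinucleotide steps)
#         - sum(monomer values over internal bases)
pairs:
  AA: 27.4
  AC: 21.2
  AG: 25.0
  AT: 22.8
  CA: 21.2
  CC: 14.6
  CG: 18.0
  CT: 15.2
  GA: 25.2
  GC: 17.6
  GG: 21.6
  GT: 20.0
  TA: 23.4
  TC: 16.2
  TG: 19.0
  TT: 16.8
monomers:
  A: 15.4
  C: 7.4
  G: 11.5
  T: 8.7
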