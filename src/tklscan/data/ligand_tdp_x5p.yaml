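# Donor/acceptor typing and region partition for the thiamine-diphosphate /
# xylulose-5-phosphate covalent adduct, keyed by het code and atom name.
# Atom nomenclature for the adduct varies between file sources (one het
# residue or several linked ones); edit the codes/names to match the input
# file. Sides: diphosphate, aminopyrimidine, thiazole, methylene-bridge,
# xylulose.
TDP: &tdp
  O1A: {roles: [acceptor], group: phosphate-O, side: diphosphate}
  O2A: {roles: [acceptor], group: phosphate-O, side: diphosphate}
  O3A: {roles: [acceptor], group: phosphate-O, side: diphosphate}
  O1B: {roles: [acceptor], group: phosphate-O, side: diphosphate}
  O2B: {roles: [acceptor], group: phosphate-O, side: diphosphate}
  O3B: {roles: [acceptor, donor], group: phosphate-OH, side: diphosphate, h_count: 1}
  N1': {roles: [acceptor], group: ring-N, side: aminopyrimidine}
  N3': {roles: [acceptor], group: ring-N, side: aminopyrimidine}
  N4': {roles: [donor], group: amino-N, side: aminopyrimidine, h_count: 2}
  C7': {roles: [], group: methylene, side: methylene-bridge}
  S1:  {roles: [acceptor], group: thiazole-S, side: thiazole}
  N3:  {roles: [], group: ring-N, side: thiazole}
TPP: *tdp
X5P:
  O1: {roles: [acceptor, donor], group: sugar-OH, side: xylulose, h_count: 1}
  O2: {roles: [acceptor, donor], group: sugar-OH, side: xylulose, h_count: 1}
  O3: {roles: [acceptor, donor], group: sugar-OH, side: xylulose, h_count: 1}
  O4: {roles: [acceptor, donor], group: sugar-OH, side: xylulose, h_count: 1}
  O5: {roles: [acceptor], group: sugar-O, side: xylulose}
  O1P: {roles: [acceptor], group: phosphate-O, side: xylulose}
  O2P: {roles: [acceptor], group: phosphate-O, side: xylulose}
  O3P: {roles: [acceptor], group: phosphate-O, side: xylulose}
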