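# Template (human TKT, chain A author numbering) active-site residue list:
# the union of residues reported to contact the TDP-X5P adduct — diphosphate
# cavity, aminopyrimidine/thiazole rings, and xylulose moiety.
# "catalytic" marks residues implicated in catalysis; the flag is metadata
# only and never enters classification logic.
# Note: the literature cites both G123 and G125 for the same ring-interaction
# glycine; this config ships G123 (the member of the G123-G93 TKT-TKTL1
# equivalence pair).
residues:
  - {number: 37,  name: HIS, note: "H-bond to X5P C3 hydroxyl"}
  - {number: 40,  name: SER, note: "hydroxyl to diphosphate"}
  - {number: 75,  name: LYS, note: "epsilon-NH2 to diphosphate"}
  - {number: 77,  name: HIS, catalytic: true, note: "tau-NH to diphosphate; absent in TKTL1"}
  - {number: 110, name: HIS, catalytic: true, note: "proton acceptor; absent in TKTL1"}
  - {number: 123, name: GLY, note: "ring interaction (also cited as G125)"}
  - {number: 125, name: LEU, note: "hydrophobic nodule at the methylene bridge"}
  - {number: 156, name: GLY, note: "backbone amide to diphosphate"}
  - {number: 157, name: GLU, note: "backbone amide to diphosphate"}
  - {number: 185, name: ASN, note: "amide-NH2 to diphosphate"}
  - {number: 189, name: ASN, note: "ring H-bond network"}
  - {number: 244, name: LYS, note: "epsilon-NH2 to diphosphate"}
  - {number: 258, name: HIS, note: "tau-N near thiazole sulphur; X5P C-hydroxyls"}
  - {number: 318, name: SER, note: "X5P phosphate region"}
  - {number: 342, name: THR, note: "non-polar ring contact"}
  - {number: 364, name: ILE, note: "non-polar ring contact; substituted by M337 in TKTL1"}
  - {number: 366, name: GLU, catalytic: true, note: "essential catalytic glutamate"}
  - {number: 389, name: PHE, note: "ring stacking"}
  - {number: 392, name: PHE, note: "ring stacking"}
  - {number: 428, name: GLN, catalytic: true, note: "equivalent of yeast H481"}
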