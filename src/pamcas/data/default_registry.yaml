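# Default building-block registry for poly(amide-carbosilane) dendrimers.
#
# Compositions are reconstructed from the described structures and pinned
# by the printed molecular weights: the AB3 module (para-alkoxybenzoic acid
# bearing one tri-allylsilylpropyl wedge) averages 330 g/mol, the AB6 module
# (3,5-bis-alkoxybenzoic acid bearing two wedges) 539 g/mol, the cysteamine
# hydrochloride cap 113.6 g/mol and the tetraallylsilane core precursor
# 192.4 g/mol.
#
# coupling_delta is the composition removed per amide attachment: water for
# the condensation plus HCl because every growth-state amine is carried as
# its ammonium chloride salt.
#
# smiles_fragment strings are attachment-annotated: "{a}" marks a site where
# the next arm (allyl terminus, capped ammonium terminus, or the next layer)
# is grafted.  The cap's arm is the thioether tether formed by anti-Markovnikov
# thiol-ene addition across a terminal allyl group.
blocks:
  - name: core
    role: core
    formula: C12H20Si
    multiplicity: 4
    coupling_delta: null
    token: null
    smiles_fragment: "[Si]({a})({a})({a}){a}"
    terminal_smiles: "CC=C"
    notes: tetraallylsilane, silicon branching center
  - name: AB3
    role: branch
    formula: C19H26O3Si
    multiplicity: 3
    coupling_delta: H3ClO
    token: "3"
    smiles_fragment: "c1ccc(OCCC[Si]({a})({a}){a})cc1"
    terminal_smiles: "CC=C"
    notes: 4-(3-(triallylsilyl)propoxy)benzoic acid, branching degree 3
  - name: AB6
    role: branch
    formula: C31H46O4Si2
    multiplicity: 6
    coupling_delta: H3ClO
    token: "6"
    smiles_fragment: "c1cc(OCCC[Si]({a})({a}){a})cc(OCCC[Si]({a})({a}){a})c1"
    terminal_smiles: "CC=C"
    notes: 3,5-bis(3-(triallylsilyl)propoxy)benzoic acid, branching degree 6
  - name: CA-HCl
    role: cap
    formula: C2H8ClNS
    multiplicity: 1
    coupling_delta: null
    token: null
    smiles_arm: "CCCSCC"
    smiles_head: "[NH3+]"
    smiles_counterion: "[Cl-]"
    notes: cysteamine hydrochloride, thiol-ene cap introducing ammonium end groups
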