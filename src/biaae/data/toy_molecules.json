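{
  "description": "Synthetic 20-molecule toy set for exercising the drug-likeness filter; every expected classification was hand-checked (molecular weight, element set, O/N presence, largest ring, tetracycline scaffold). 'expected' names the first failing rule in the order weight -> elements -> heteroatom -> ring -> scaffold, 'survivor' for molecules passing all rules, 'duplicate' for a repeat of an earlier survivor, 'unparseable' for broken strings.",
  "molecules": [
    {"smiles": "CC(=O)Nc1ccc(OCC(=O)N2CCN(c3ccccc3)CC2)cc1", "expected": "survivor", "mw": 353.4},
    {"smiles": "O=C(Nc1ccc(Cl)cc1)c1ccc(N2CCOCC2)cc1", "expected": "survivor", "mw": 316.8},
    {"smiles": "COc1ccc(CCN(C)CCc2ccc(F)cc2)cc1OC", "expected": "survivor", "mw": 317.4},
    {"smiles": "O=C(O)c1ccc(NC(=O)c2ccc(Br)cc2)cc1", "expected": "survivor", "mw": 320.1},
    {"smiles": "CCN(CC)CCNC(=O)c1ccc(N)cc1Cl", "expected": "survivor", "mw": 269.8},
    {"smiles": "CN1CCN(CC1)c1ccc(NC(=O)c2ccccc2O)cc1", "expected": "survivor", "mw": 311.4},
    {"smiles": "O=C(NCc1ccccc1)c1cccc(S(=O)(=O)N2CCCC2)c1", "expected": "survivor", "mw": 344.4},
    {"smiles": "CC(=O)Oc1ccccc1C(=O)O", "expected": "weight", "mw": 180.2},
    {"smiles": "CCO", "expected": "weight", "mw": 46.1},
    {"smiles": "c1ccncc1", "expected": "weight", "mw": 79.1},
    {"smiles": "NCC(=O)NCC(=O)NCC(=O)NCC(=O)NCC(=O)NCC(=O)NCC(=O)NCC(=O)NCC(=O)NCC(=O)O", "expected": "weight", "mw": 588.5},
    {"smiles": "Ic1ccc(NC(=O)c2ccccc2)cc1C(=O)NCCN", "expected": "elements", "mw": 409.2},
    {"smiles": "O=P(O)(O)OCC1OC(n2cnc3c(N)ncnc32)C(O)C1O", "expected": "elements", "mw": 347.2},
    {"smiles": "CCCCCCCCCCCCCCCCCCCC", "expected": "heteroatom", "mw": 282.6},
    {"smiles": "c1ccc(cc1)C(c1ccccc1)(c1ccccc1)c1ccccc1", "expected": "heteroatom", "mw": 320.4},
    {"smiles": "O=C1CCCCCCCCCCC1NC(=O)c1ccccc1", "expected": "ring", "mw": 301.4},
    {"smiles": "CC1(O)c2cccc(O)c2C(=O)C2=C(O)C3(O)C(=O)C(C(N)=O)=C(O)C(N(C)C)C3CC12", "expected": "scaffold", "mw": 444.4},
    {"smiles": "O=C(Nc1ccc(Cl)cc1)c1ccc(N2CCOCC2)cc1", "expected": "duplicate", "mw": 316.8},
    {"smiles": "C1CC", "expected": "unparseable", "mw": null},
    {"smiles": "notasmiles", "expected": "unparseable", "mw": null}
  ],
  "expected_counts": {
    "input": 20,
    "survivors": 7,
    "duplicates": 1,
    "removed": {"unparseable": 2, "weight": 4, "elements": 2, "heteroatom": 2, "ring": 1, "scaffold": 1}
  }
}
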