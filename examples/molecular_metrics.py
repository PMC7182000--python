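"""Molecule handling: drug-likeness filtering, tokenization and set metrics.

Runs the perturbation-dataset filter rules over the packaged toy molecule
set, shows the per-rule removal counts, and computes validity and internal
diversity (1 − mean pairwise Tanimoto on circular fingerprints) of the
survivors.
"""

import json
from importlib import resources

from biaae import (SmilesVocabulary, filter_molecules, internal_diversity,
                   validity_fraction)

manifest = json.loads(
    resources.files("biaae.data").joinpath("toy_molecules.json").read_text())
smiles = [m["smiles"] for m in manifest["molecules"]]

survivors, report = filter_molecules(smiles)
print(f"input molecules: {report.input_count}")
for rule, count in report.removed.items():
    print(f"  removed by {rule}: {count}")
print(f"  duplicates: {report.duplicate_count}")
print(f"survivors: {report.surviving_count}")

kept = [m.canonical_smiles for m in survivors]
print(f"validity of survivors: {validity_fraction(kept):.2f} (all parseable)")
print(f"internal diversity:    {internal_diversity(kept):.3f} "
      "(1 = structurally unrelated, 0 = a single repeated structure)")

vocab = SmilesVocabulary.from_smiles(kept)
ids = vocab.tokenize(kept[0])
print(f"tokenized {kept[0]!r} into {len(ids)} ids; "
      f"round-trip: {vocab.detokenize(ids) == kept[0]}")
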