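"""Molecular and expression-condition data handling.

SMILES strings are tokenized at character level (with ``Cl``/``Br`` as
single tokens) for the recurrent sequence models; molecule sets destined for
training are filtered with the drug-likeness rules used for the
perturbation dataset: molecular weight in [250, 550] Da, at least one
oxygen or nitrogen atom, elements restricted to {C, N, S, O, F, Cl, Br, H},
no ring larger than eight atoms, and no tetracycline scaffold. Expression
conditions carry a control profile, a perturbed profile over 978 landmark
genes and a log10-molar dose; training pairs match a perturbation with a
control drawn from the same assay plate.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")  # parse failures are reported via counts

__all__ = [
    "EXPR_DIM", "SmilesVocabulary", "MoleculeRecord", "ExpressionCondition",
    "FilterReport", "filter_molecules", "build_pairs", "split_by_drug",
    "read_smiles_file", "read_expression_table",
]

EXPR_DIM = 978

# tetracycline core: the linearly fused tetracyclic (naphthacene) carbon
# skeleton with any-order bonds, so partially saturated cores match too;
# swappable — any SMARTS string can be passed to filter_molecules
TETRACYCLINE_SMARTS = (
    "[#6]1~[#6]~[#6]~[#6]2~[#6]~[#6]3~[#6]~[#6]4~[#6]~[#6]~[#6]~[#6]~[#6]4"
    "~[#6]~[#6]3~[#6]~[#6]2~[#6]1"
)


class TokenizationError(ValueError):
    pass


class SmilesVocabulary:
    """Character-level SMILES vocabulary with start/end/pad specials.

    Two-character element tokens ``Cl`` and ``Br`` are single tokens.
    """

    PAD, START, END = "<pad>", "<s>", "</s>"

    #: default alphabet covering the filtered element set plus SMILES syntax
    DEFAULT_TOKENS = (
        list("CNSOFcnso") + ["Cl", "Br", "H"]
        + list("()[]=#+-\\/@123456789%")
    )

    def __init__(self, tokens: Sequence[str] | None = None):
        tokens = list(tokens) if tokens is not None else list(self.DEFAULT_TOKENS)
        self.tokens = [self.PAD, self.START, self.END] + tokens
        self.index = {t: i for i, t in enumerate(self.tokens)}
        self.pad_id = self.index[self.PAD]
        self.start_id = self.index[self.START]
        self.end_id = self.index[self.END]

    def __len__(self) -> int:
        return len(self.tokens)

    @classmethod
    def from_smiles(cls, smiles: Iterable[str]) -> "SmilesVocabulary":
        seen: dict[str, None] = {}
        for s in smiles:
            for tok in _split_tokens(s):
                seen.setdefault(tok)
        return cls(sorted(seen))

    def tokenize(self, smiles: str, add_specials: bool = True) -> list[int]:
        """SMILES -> token ids (start/end added unless disabled)."""
        if not smiles:
            raise TokenizationError("empty SMILES string")
        ids = []
        for tok in _split_tokens(smiles):
            if tok not in self.index:
                raise TokenizationError(f"unknown SMILES token: {tok!r}")
            ids.append(self.index[tok])
        if add_specials:
            return [self.start_id] + ids + [self.end_id]
        return ids

    def detokenize(self, token_ids: Sequence[int]) -> str:
        """Token ids -> SMILES; strips start/end/pad."""
        specials = {self.pad_id, self.start_id, self.end_id}
        return "".join(self.tokens[i] for i in token_ids if i not in specials)

    def pad_batch(self, sequences: Sequence[Sequence[int]]) -> np.ndarray:
        """Right-pad to a (batch, max_len) int array."""
        width = max(len(s) for s in sequences)
        out = np.full((len(sequences), width), self.pad_id, dtype=int)
        for i, s in enumerate(sequences):
            out[i, : len(s)] = s
        return out


def _split_tokens(smiles: str) -> list[str]:
    tokens = []
    i = 0
    while i < len(smiles):
        if smiles[i: i + 2] in ("Cl", "Br"):
            tokens.append(smiles[i: i + 2])
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


@dataclasses.dataclass
class MoleculeRecord:
    smiles: str
    canonical_smiles: str
    mol_weight: float
    token_ids: Optional[list[int]] = None

    @classmethod
    def from_smiles(cls, smiles: str, vocabulary: SmilesVocabulary | None = None):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        canonical = Chem.MolToSmiles(mol)
        token_ids = vocabulary.tokenize(canonical) if vocabulary is not None else None
        return cls(smiles=smiles, canonical_smiles=canonical,
                   mol_weight=Descriptors.MolWt(mol), token_ids=token_ids)


@dataclasses.dataclass
class ExpressionCondition:
    """Control/perturbed landmark-gene profiles with a log10-molar dose."""

    ge_b: np.ndarray   # control
    ge_a: np.ndarray   # perturbed
    eta: float         # log10 molar dose
    plate_id: str = ""
    molecule_id: str = ""

    def __post_init__(self):
        self.ge_b = np.asarray(self.ge_b, dtype=np.float64)
        self.ge_a = np.asarray(self.ge_a, dtype=np.float64)
        if self.ge_b.shape != (EXPR_DIM,) or self.ge_a.shape != (EXPR_DIM,):
            raise ValueError(
                f"expression profiles must have length {EXPR_DIM}; "
                f"got {self.ge_b.shape} and {self.ge_a.shape}"
            )

    @property
    def delta(self) -> np.ndarray:
        """Differential expression, always recomputed as perturbed − control."""
        return self.ge_a - self.ge_b


# -- filtering -------------------------------------------------------------------

_ALLOWED_ELEMENTS = {"C", "N", "S", "O", "F", "Cl", "Br", "H"}
_RULES = ("unparseable", "weight", "elements", "heteroatom", "ring", "scaffold")


@dataclasses.dataclass
class FilterReport:
    input_count: int = 0
    removed: dict[str, int] = dataclasses.field(
        default_factory=lambda: {rule: 0 for rule in _RULES})
    duplicate_count: int = 0
    surviving_count: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def check_consistency(self) -> bool:
        return self.input_count == (sum(self.removed.values())
                                    + self.duplicate_count + self.surviving_count)


def _largest_ring(mol) -> int:
    info = mol.GetRingInfo()
    return max((len(ring) for ring in info.AtomRings()), default=0)


def _first_failing_rule(mol, weight: float, scaffold) -> Optional[str]:
    """Removal attribution uses a fixed rule order:
    weight → elements → heteroatom → ring → scaffold."""
    if weight < 250.0 or weight > 550.0:
        return "weight"
    symbols = {atom.GetSymbol() for atom in mol.GetAtoms()} | {"H"}
    if not symbols <= _ALLOWED_ELEMENTS:
        return "elements"
    if not any(atom.GetSymbol() in ("O", "N") for atom in mol.GetAtoms()):
        return "heteroatom"
    if _largest_ring(mol) > 8:
        return "ring"
    if scaffold is not None and mol.HasSubstructMatch(scaffold):
        return "scaffold"
    return None


def filter_molecules(smiles_list: Sequence[str],
                     tetracycline_smarts: str = TETRACYCLINE_SMARTS,
                     ) -> tuple[list[MoleculeRecord], FilterReport]:
    """Apply the perturbation-dataset drug-likeness rules.

    Keeps molecules with 250 ≤ MW ≤ 550 Da, at least one O or N, elements
    within {C,N,S,O,F,Cl,Br,H}, no ring of more than eight atoms and no
    tetracycline scaffold match; de-duplicates by canonical SMILES. Returns
    survivors plus a per-rule removal report (first failing rule counts).
    """
    scaffold = Chem.MolFromSmarts(tetracycline_smarts) if tetracycline_smarts else None
    report = FilterReport(input_count=len(smiles_list))
    survivors: list[MoleculeRecord] = []
    seen: set[str] = set()
    for smiles in smiles_list:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            report.removed["unparseable"] += 1
            continue
        weight = Descriptors.MolWt(mol)
        rule = _first_failing_rule(mol, weight, scaffold)
        if rule is not None:
            report.removed[rule] += 1
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            report.duplicate_count += 1
            continue
        seen.add(canonical)
        survivors.append(MoleculeRecord(smiles=smiles, canonical_smiles=canonical,
                                        mol_weight=weight))
    report.surviving_count = len(survivors)
    return survivors, report


# -- pairing and splits ------------------------------------------------------------

def build_pairs(perturbations: Sequence[ExpressionCondition],
                controls: Sequence[ExpressionCondition],
                rng: np.random.Generator,
                augmentation: int = 1) -> tuple[list[ExpressionCondition], int]:
    """Plate-matched pairing: each perturbation is paired with `augmentation`
    controls drawn uniformly from the same plate.

    Returns the paired conditions (perturbation profile + sampled control)
    and the number of perturbations skipped because their plate had no
    control.
    """
    by_plate: dict[str, list[ExpressionCondition]] = {}
    for ctrl in controls:
        by_plate.setdefault(ctrl.plate_id, []).append(ctrl)
    paired: list[ExpressionCondition] = []
    skipped = 0
    for pert in perturbations:
        plate_controls = by_plate.get(pert.plate_id)
        if not plate_controls:
            skipped += 1
            continue
        for _ in range(augmentation):
            ctrl = plate_controls[rng.integers(len(plate_controls))]
            paired.append(ExpressionCondition(
                ge_b=ctrl.ge_b, ge_a=pert.ge_a, eta=pert.eta,
                plate_id=pert.plate_id, molecule_id=pert.molecule_id))
    return paired, skipped


def split_by_drug(conditions: Sequence[ExpressionCondition],
                  rng: np.random.Generator,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  ) -> tuple[list, list, list]:
    """Train/valid/test split sharing no molecule across splits."""
    drugs = sorted({c.molecule_id for c in conditions})
    order = rng.permutation(len(drugs))
    n_train = int(round(fractions[0] * len(drugs)))
    n_valid = int(round(fractions[1] * len(drugs)))
    train_set = {drugs[i] for i in order[:n_train]}
    valid_set = {drugs[i] for i in order[n_train:n_train + n_valid]}
    splits: tuple[list, list, list] = ([], [], [])
    for c in conditions:
        if c.molecule_id in train_set:
            splits[0].append(c)
        elif c.molecule_id in valid_set:
            splits[1].append(c)
        else:
            splits[2].append(c)
    return splits


# -- file I/O ---------------------------------------------------------------------

def read_smiles_file(path) -> list[str]:
    """One SMILES per line; blank lines skipped."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_smiles_file(smiles: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")


def read_expression_table(path, kind: str = "perturbation") -> list[ExpressionCondition]:
    """Read a delimited table: 978 gene columns g0..g977 plus plate, dose
    (log10 molar) and molecule_id columns. Control rows may carry the
    profile in the gene columns with dose ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    gene_cols = [f"g{i}" for i in range(EXPR_DIM)]
    missing = [c for c in gene_cols if c not in df.columns] or \
        [c for c in ("plate", "dose", "molecule_id") if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing[:5]}...")
    conditions = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        profile = np.array([getattr(row, c) for c in gene_cols], dtype=np.float64)
        if not np.all(np.isfinite(profile)):
            raise ValueError(f"non-finite expression values at line {row_number}")
        if kind == "perturbation":
            conditions.append(ExpressionCondition(
                ge_b=np.zeros(EXPR_DIM), ge_a=profile,
                eta=float(row.dose), plate_id=str(row.plate),
                molecule_id=str(row.molecule_id)))
        else:
            conditions.append(ExpressionCondition(
                ge_b=profile, ge_a=profile, eta=float(row.dose),
                plate_id=str(row.plate), molecule_id=str(row.molecule_id)))
    return conditions
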