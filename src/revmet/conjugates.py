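"""Combinatorial enumeration of amine-head x hydroxy-acyl-tail amide conjugates.

A conjugate is the amide condensation product of a primary amine "head"
(amino acid, polyamine, neurotransmitter) with a 3-hydroxy fatty-acid "tail":
head + tail - H2O. Heads with several primary amines yield one positional
isomer per amine site; isomers share formula and mass but differ in SMILES.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .chem import (
    AdductSpec,
    Composition,
    WATER_MASS,
    adduct_mz,
    combine_formulas,
    formula_to_string,
    monoisotopic_mass,
    subtract_formula,
)

RDLogger.DisableLog("rdApp.*")

# Primary amine: NH2 on an sp3 or aryl carbon; amide/thioamide/amidine and
# guanidino nitrogens are not condensation sites, nor is aromatic ring NH.
_PRIMARY_AMINE = Chem.MolFromSmarts("[NX3H2;$(N[CX4,c]);!$(N[CX3]=[O,S,N])]")
_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")

_TAIL_NAME = re.compile(r"C(\d+):(\d+)")


class TableError(ValueError):
    """Raised when an input head/tail table has structurally invalid rows."""


def _mol_formula(mol: Chem.Mol) -> Composition:
    """Elemental composition of an RDKit molecule, explicit hydrogens included."""
    comp: Composition = {}
    for atom in Chem.AddHs(mol).GetAtoms():
        symbol = atom.GetSymbol()
        comp[symbol] = comp.get(symbol, 0) + 1
    return comp


def _primary_amine_sites(mol: Chem.Mol) -> List[int]:
    """Atom indices of primary-amine nitrogens, in input atom order."""
    return sorted(idx for (idx,) in mol.GetSubstructMatches(_PRIMARY_AMINE))


@dataclass(frozen=True)
class AmineHead:
    """An amine head group available for amide conjugation."""

    name: str
    smiles: str
    formula: Mapping[str, int]
    mono_mass: float
    n_primary_amines: int
    diagnostic_fragments: tuple = ()

    @classmethod
    def from_smiles(
        cls, name: str, smiles: str, diagnostic_fragments: Sequence[float] = ()
    ) -> "AmineHead":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"malformed SMILES for head {name!r}: {smiles!r}")
        sites = _primary_amine_sites(mol)
        if not sites:
            raise ValueError(
                f"head {name!r} has no primary amine and cannot be conjugated"
            )
        formula = _mol_formula(mol)
        return cls(
            name=name,
            smiles=smiles,
            formula=formula,
            mono_mass=monoisotopic_mass(formula),
            n_primary_amines=len(sites),
            diagnostic_fragments=tuple(float(f) for f in diagnostic_fragments),
        )


@dataclass(frozen=True)
class LipidTail:
    """A 3-hydroxy fatty acid tail with a free carboxylic acid.

    Named ``3OH-Cn:m`` for n carbons and m unsaturations; the name encodes
    only the counts — the SMILES is authoritative for double-bond placement.
    """

    name: str
    smiles: str
    carbons: int
    unsaturations: int
    formula: Mapping[str, int]
    mono_mass: float
    hydroxyl_position: int = 3

    @classmethod
    def from_smiles(cls, name: str, smiles: str) -> "LipidTail":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"malformed SMILES for tail {name!r}: {smiles!r}")
        if len(mol.GetSubstructMatches(_CARBOXYLIC_ACID)) != 1:
            raise ValueError(
                f"tail {name!r} must carry exactly one free carboxylic acid"
            )
        carbons, unsats = parse_tail_name(name)
        formula = _mol_formula(mol)
        # CnH(2n-2m)O3 for a hydroxy fatty acid with m double bonds
        expected = {"C": carbons, "H": 2 * carbons - 2 * unsats, "O": 3}
        if formula != expected:
            raise ValueError(
                f"tail {name!r}: SMILES formula {formula_to_string(formula)} "
                f"inconsistent with name (expected {formula_to_string(expected)})"
            )
        return cls(
            name=name,
            smiles=smiles,
            carbons=carbons,
            unsaturations=unsats,
            formula=formula,
            mono_mass=monoisotopic_mass(formula),
        )


def parse_tail_name(name: str) -> tuple:
    """Recover (carbons, unsaturations) from a ``Cn:m`` style tail name."""
    match = _TAIL_NAME.search(name)
    if match is None:
        raise ValueError(f"cannot parse carbons/unsaturations from tail name {name!r}")
    return int(match.group(1)), int(match.group(2))


@dataclass(frozen=True)
class ConjugateTarget:
    """One head x tail amide conjugate (a single positional isomer)."""

    head: AmineHead
    tail: LipidTail
    isomer_index: int
    smiles: str
    formula: Mapping[str, int]
    mono_mass: float

    @property
    def name(self) -> str:
        return f"{self.tail.name} {self.head.name}"

    @property
    def pair(self) -> tuple:
        return (self.head.name, self.tail.name)

    def adduct_mz(self, adduct: AdductSpec) -> float:
        return adduct_mz(self.mono_mass, adduct)


def assemble_amide(head: AmineHead, tail: LipidTail, site_index: int = 1) -> ConjugateTarget:
    """Condense a tail's carboxylic acid onto the ``site_index``-th amine of a head.

    ``site_index`` is 1-based over the head's primary-amine sites in atom
    order. The product SMILES carries one new amide bond; its composition is
    head + tail - H2O.
    """
    if not 1 <= site_index <= head.n_primary_amines:
        raise ValueError(
            f"site_index {site_index} out of range for head {head.name!r} "
            f"with {head.n_primary_amines} primary amine(s)"
        )
    head_mol = Chem.MolFromSmiles(head.smiles)
    tail_mol = Chem.MolFromSmiles(tail.smiles)
    acid_matches = tail_mol.GetSubstructMatches(_CARBOXYLIC_ACID)
    if len(acid_matches) != 1:
        raise ValueError(f"tail {tail.name!r} lacks a unique free carboxylic acid")
    amine_idx = _primary_amine_sites(head_mol)[site_index - 1]

    combo = Chem.RWMol(Chem.CombineMols(head_mol, tail_mol))
    offset = head_mol.GetNumAtoms()
    carbonyl_c, _carbonyl_o, hydroxyl_o = (i + offset for i in acid_matches[0])
    combo.AddBond(amine_idx, carbonyl_c, Chem.BondType.SINGLE)
    combo.RemoveAtom(hydroxyl_o)
    product = combo.GetMol()
    Chem.SanitizeMol(product)

    formula = subtract_formula(
        combine_formulas(head.formula, tail.formula), {"H": 2, "O": 1}
    )
    return ConjugateTarget(
        head=head,
        tail=tail,
        isomer_index=site_index,
        smiles=Chem.MolToSmiles(product),
        formula=formula,
        mono_mass=monoisotopic_mass(formula),
    )


def enumerate_conjugates(
    heads: Sequence[AmineHead], tails: Sequence[LipidTail]
) -> List[ConjugateTarget]:
    """All head x tail conjugates, one target per primary-amine site.

    Deterministic order: head table order, then tail table order, then
    isomer index. Distinct (head, tail) pairs number |heads| x |tails|;
    total targets number sum(n_primary_amines) x |tails|.
    """
    if not heads or not tails:
        raise ValueError("head and tail lists must be non-empty")
    for label, items in (("head", heads), ("tail", tails)):
        names = [item.name for item in items]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise TableError(f"duplicate {label} names: {dupes}")
    targets: List[ConjugateTarget] = []
    for head in heads:
        for tail in tails:
            for site in range(1, head.n_primary_amines + 1):
                targets.append(assemble_amide(head, tail, site))
    return targets


# ---------------------------------------------------------------------------
# Table I/O


def _parse_fragment_field(raw) -> tuple:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return ()
    return tuple(float(tok) for tok in str(raw).split(";") if tok.strip())


def parse_head_table(path) -> List[AmineHead]:
    """Read a head-group TSV (columns: name, smiles, diagnostic_fragments).

    Rows with malformed SMILES or no primary amine are rejected with a
    :class:`TableError` listing every offending row index; valid rows keep
    the file order.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "smiles"}
    if not required.issubset(frame.columns):
        raise TableError(f"head table must have columns {sorted(required)}")
    heads: List[AmineHead] = []
    problems: List[str] = []
    for idx, row in frame.iterrows():
        frags = _parse_fragment_field(row.get("diagnostic_fragments"))
        try:
            heads.append(AmineHead.from_smiles(row["name"], row["smiles"], frags))
        except ValueError as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise TableError("invalid head rows:\n" + "\n".join(problems))
    return heads


def parse_tail_table(path) -> List[LipidTail]:
    """Read a tail TSV (columns: name, smiles); order preserved."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "smiles"}.issubset(frame.columns):
        raise TableError("tail table must have columns ['name', 'smiles']")
    tails: List[LipidTail] = []
    problems: List[str] = []
    for idx, row in frame.iterrows():
        try:
            tails.append(LipidTail.from_smiles(row["name"], row["smiles"]))
        except ValueError as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise TableError("invalid tail rows:\n" + "\n".join(problems))
    return tails


def targets_to_frame(
    targets: Sequence[ConjugateTarget], adducts: Sequence[AdductSpec]
) -> pd.DataFrame:
    """Tabulate targets with one m/z column per requested adduct."""
    rows = []
    for t in targets:
        row = {
            "name": t.name,
            "head": t.head.name,
            "tail": t.tail.name,
            "isomer_index": t.isomer_index,
            "smiles": t.smiles,
            "formula": formula_to_string(t.formula),
            "mono_mass": round(t.mono_mass, 6),
        }
        for adduct in adducts:
            row[f"mz_{adduct.name}"] = round(t.adduct_mz(adduct), 6)
        rows.append(row)
    return pd.DataFrame(rows)


def write_targets(
    targets: Sequence[ConjugateTarget],
    adducts: Sequence[AdductSpec],
    path,
) -> None:
    targets_to_frame(targets, adducts).to_csv(path, sep="\t", index=False)
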