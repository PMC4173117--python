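"""Group compound IDs by a shared molecular scaffold key.

The core grouping is toolkit-free: it takes any deterministic function from
compound ID to a canonical scaffold key (or ``None`` when the structure
cannot be resolved) and partitions the compounds into groups of identical
keys, numbering scaffolds 1, 2, 3, ... in order of first appearance.  When
RDKit is available, :func:`murcko_key_from_smiles` supplies a Bemis-Murcko
scaffold key from a SMILES table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .tabular_io import TableFormatError, _read_rows

__all__ = [
    "ScaffoldGroups",
    "group_by_scaffold",
    "murcko_key_from_smiles",
    "read_smiles_table",
    "groups_to_json_array",
]


@dataclass
class ScaffoldGroups:
    """Ordered (scaffold_id, compound_ids) pairs plus unresolved compound IDs."""

    groups: list[tuple[int, list[str]]] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)


def group_by_scaffold(
    compound_ids: list[str],
    scaffold_key: Callable[[str], str | None],
) -> ScaffoldGroups:
    """Partition compounds into groups sharing an identical scaffold key.

    Scaffold IDs are 1, 2, 3, ... in order of first appearance in the input;
    within-group compound order is input order.  Compounds whose key is
    ``None`` (unparsable structures) are listed separately, never grouped.
    """
    order: list[str] = []
    by_key: dict[str, list[str]] = {}
    unresolved: list[str] = []
    for cid in compound_ids:
        key = scaffold_key(cid)
        if key is None:
            unresolved.append(cid)
            continue
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(cid)
    groups = [(i + 1, by_key[key]) for i, key in enumerate(order)]
    return ScaffoldGroups(groups, unresolved)


def read_smiles_table(text: str, delimiter: str = ",", has_header: bool = False) -> dict[str, str]:
    """Parse an ``ID,SMILES`` delimited table into an ID -> SMILES map."""
    rows = _read_rows(text, delimiter)
    if has_header:
        rows = rows[1:]
    out: dict[str, str] = {}
    for lineno, cells in rows:
        if len(cells) < 2:
            raise TableFormatError(f"line {lineno}: expected ID and SMILES columns")
        cid = cells[0].strip()
        if cid in out:
            raise TableFormatError(f"duplicate compound ID {cid!r}")
        out[cid] = cells[1].strip()
    return out


def murcko_key_from_smiles(smiles_by_id: dict[str, str]) -> Callable[[str], str | None]:
    """Build a scaffold-key function mapping compound ID -> canonical
    Bemis-Murcko scaffold SMILES (requires RDKit)."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem.Scaffolds import MurckoScaffold

    RDLogger.DisableLog("rdApp.error")

    def key(compound_id: str) -> str | None:
        smiles = smiles_by_id.get(compound_id)
        if smiles is None:
            return None
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return None
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
        return Chem.MolToSmiles(scaffold, canonical=True)

    return key


def groups_to_json_array(groups: ScaffoldGroups) -> list[list[object]]:
    """The wire shape consumed by a highlight callback: [[1, [ids...]], ...]."""
    return [[sid, list(ids)] for sid, ids in groups.groups]
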