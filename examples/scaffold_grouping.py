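"""Group compounds by their Bemis-Murcko scaffold (the ring-and-linker core).

A selection of compound IDs (as harvested from a dendrogram node click) is
grouped so that compounds sharing an identical scaffold fall together —
the server-side half of a scaffold-highlighting workflow.
"""

from dendroheat import (
    group_by_scaffold,
    groups_to_json_array,
    murcko_key_from_smiles,
    read_smiles_table,
)

smiles_csv = """id,smiles
CHEMBL_A,c1ccccc1O
CHEMBL_B,Cc1ccccc1
CHEMBL_C,c1ccccc1CC(=O)O
CHEMBL_D,OC1CCCCC1
CHEMBL_E,CCO
CHEMBL_F,this_is_not_a_molecule(
"""

table = read_smiles_table(smiles_csv, has_header=True)
key = murcko_key_from_smiles(table)
groups = group_by_scaffold(list(table), key)

print("scaffold groups:", groups_to_json_array(groups))
print("unresolved structures:", groups.unresolved)
# Phenol, toluene and phenylacetic acid share the benzene scaffold (group 1);
# cyclohexanol has its own ring (group 2); acyclic ethanol's empty scaffold
# is its own group; the unparsable SMILES is reported, not grouped.
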