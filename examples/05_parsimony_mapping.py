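"""Minimum evolutionary changes of sexual characters on the group cladogram.

Maps the built-in discrete characters (mating position, phallus shape, ...)
onto the cladogram with unit-cost parsimony, then enumerates the equally
parsimonious histories of a collapsed right-sided/symmetric mating-position
character: two independent gains, or one early gain lost again.
"""

from copasym import enumerate_scenarios, fitch_min_changes, read_newick, reference
from copasym.datatypes import CharacterOnTree

for char in reference.characters_on_cladogram():
    res = fitch_min_changes(char)
    roots = "/".join(sorted(res.root_states))
    print(f"{char.name:20s} min changes = {res.min_changes}  (root: {roots})")

print()
tree = read_newick("((nan,(aca,pac)),mac,bro,moj,buz);")
binary = CharacterOnTree(
    tree=tree,
    states={"nan": "right_sided", "pac": "right_sided", "aca": "symmetric",
            "mac": "symmetric", "bro": "symmetric", "moj": "symmetric",
            "buz": "symmetric"},
    name="mating_position_binary",
)
scenarios = enumerate_scenarios(binary, max_extra=0)
print(f"{len(scenarios)} equally parsimonious 2-change histories of right-sidedness:")
for cost, labeling in scenarios:
    internal = {k: v for k, v in labeling.items() if k.startswith("node")}
    print(f"  cost {cost}: {internal}")
print("-> at least two changes in mating position are required; the data cannot")
print("   distinguish independent gains from an early gain plus a later loss.")
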