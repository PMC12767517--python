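"""Build a residue contact graph for a two-chain complex.

Generates a small synthetic complex with a designed 3-residue interface
patch per chain, builds the contact graph at the 4.5 Å heavy-atom rule and
reports which residues form the binding interface.
"""

from edgetic import build_contact_graph, interface_nodes
from edgetic.synthetic import SynthComplexSpec, generate_complex

spec = SynthComplexSpec(n_interactor=12, n_partner=12, patch_size=3, seed=1)
complex_ = generate_complex(spec)
graph = build_contact_graph(complex_, threshold=4.5)

iface = sorted(interface_nodes(graph))
print(f"nodes: {graph.n_nodes} ({graph.n_interactor} interactor + "
      f"{graph.n_nodes - graph.n_interactor} partner)")
print(f"edges: {len(graph.edges)} "
      f"({len(graph.inter_chain_edges())} inter-chain)")
print("interface residues (0-based node index, chain, position):")
for idx in iface:
    print(f"  {idx:3d}  {graph.chain_role[idx]:<10s}  {graph.position[idx]}")

# The interface is exactly the designed patch: inter-chain contacts exist
# only where the generator placed side chains within 4.5 Å of the other
# chain. Intra-chain edges trace the backbone (consecutive residues).
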