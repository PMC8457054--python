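"""Topology preservation: a solid torus thins to a closed cycle.

The Euler characteristic chi = objects - tunnels + cavities is 0 for a torus
(one object, one tunnel).  Thinning must keep it at 0, and the cleaned graph
collapses to a single loop link on a cycle-anchor node.
"""

from netskel import CleaningParams, clean_graph, extract_graph, thin_volume
from netskel.phantoms import make_torus
from netskel.topology import count_components, euler_characteristic

volume, _ = make_torus(10, 2.5)
skeleton = thin_volume(volume)

print(f"solid torus:   chi = {euler_characteristic(volume.material)}, "
      f"components = {count_components(volume.material)}, "
      f"voxels = {volume.count()}")
print(f"skeleton:      chi = {euler_characteristic(skeleton.data)}, "
      f"components = {count_components(skeleton.data)}, "
      f"voxels = {skeleton.count()}")

graph = clean_graph(extract_graph(skeleton, sigma=1.0), CleaningParams(1.5, 0.9))
loop = next(iter(graph.links.values()))
print(f"cleaned graph: {graph.n_nodes} node "
      f"({next(iter(graph.nodes.values())).kind}), {graph.n_links} loop link, "
      f"Lambda = {loop.length:.1f} (circumference 2*pi*10 = 62.8)")
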