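"""Skeletonize a solid cylinder and measure its one link.

A 60-voxel-long cylinder of radius 3 is the simplest calibration target: its
skeleton must be a single straight path with two end nodes, a link length
close to the axis length, and tortuosity exactly 1.
"""

from netskel import CleaningParams, clean_graph, extract_graph, graph_to_skeleton
from netskel import thin_volume, tortuosity
from netskel.phantoms import make_tube

volume, truth = make_tube(60, 3.0)
skeleton = thin_volume(volume)
graph = clean_graph(extract_graph(skeleton, sigma=1.0), CleaningParams(1.5, 0.9))
link = next(iter(graph.links.values()))
t = tortuosity(graph, graph_to_skeleton(graph), face_depth=2.0)

print(f"nodes: {graph.n_nodes} (kinds: {sorted(n.kind for n in graph.nodes.values())})")
print(f"links: {graph.n_links}")
print(f"link length Lambda = {link.length:.1f} voxels (axis length {truth.links[0][2]:.0f})")
print(f"tortuosity xi = {t.xi_mean:.3f}  (straight strand: exactly 1)")
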