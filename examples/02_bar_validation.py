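"""Closed-form validation: uniaxial compression of a quadratic-tet bar.

A 100 mm bar with a 10 x 10 mm section under 1200 N of axial compression
must show sigma3 = -F/A = -12 MPa in every element and shorten by
FL/EA = 0.1 mm.  Any deviation indicates an assembly or recovery defect.
"""

import numpy as np

from flipperfea import BoundaryCondition, Material, assemble, solve_static, traction_loads
from flipperfea.mesh import to_quadratic
from flipperfea.synthetic import structured_box

mesh = to_quadratic(structured_box(100.0, 10.0, 10.0, 10, 2, 2))
mesh.node_sets["load_face"] = np.where(np.isclose(mesh.nodes[:, 0], 0.0))[0]
far = np.where(np.isclose(mesh.nodes[:, 0], 100.0))[0]

op = assemble(mesh, {"bone": Material(12_000.0, 0.3)})
# axial constraint on the far face + minimal rigid-body pins, so the bar
# may contract laterally (the textbook uniaxial state)
comps = [(int(n), 0) for n in far]
y0 = [int(n) for n in far if np.isclose(mesh.nodes[n, 1], 0.0)]
z0 = [int(n) for n in far if np.isclose(mesh.nodes[n, 2], 0.0)]
comps += [(y0[0], 1), (y0[1], 1), (z0[0], 2)]
bc = BoundaryCondition(
    fixed_components=comps,
    loads=traction_loads(mesh, "load_face", np.array([12.0, 0.0, 0.0])),
)
sol = solve_static(op, bc)

print(f"sigma3: min {sol.sigma3.min():.10f}, max {sol.sigma3.max():.10f} MPa (exact: -12)")
print(f"shortening: {sol.displacement[mesh.node_sets['load_face'], 0].mean():.10f} mm (exact: 0.1)")
print(f"max |sigma1|: {np.abs(sol.sigma1).max():.2e} MPa (exact: 0)")
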