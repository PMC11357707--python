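"""Voxelize the vertebral-body phantom and place the directional applicator.

Builds the default 8 x 4 x 4 cm phantom at 1 mm spacing, places the
14-gauge applicator through the lateral wall aimed ventrally, and prints the
per-class voxel volumes and the virtual probe positions.  Optionally exports
a VTK file for ParaView inspection (pass an output path as argv[1]).
"""

import sys

import dmwasim as d

spec = d.PhantomSpec()
pose = d.default_pose(spec)
grid = d.place_applicator(d.build_phantom(spec, spacing=1e-3), pose)

print(f"grid {grid.shape} voxels at {grid.spacing * 1e3:.1f} mm")
for name in ("cortical bone", "cancellous bone", "cartilage", "spinal cord",
             "applicator", "air"):
    v = grid.class_volume(name)
    print(f"  {name:<16} {v * 1e6:8.2f} cm^3")

print("\nvirtual probes (distances from the shaft axis):")
for probe in d.default_probes(pose):
    x, y, z = (c * 1e3 for c in probe.position)
    print(f"  {probe.name:<13} {probe.nominal_distance * 1e3:4.1f} mm at "
          f"({x:+.1f}, {y:+.1f}, {z:+.1f}) mm")

gap = (pose.tip[1] - pose.shaft_radius) - (spec.canal_center_y + spec.canal_diameter / 2)
print(f"\nshaft back surface to canal boundary: {gap * 1e3:.1f} mm")

if len(sys.argv) > 1:
    d.vtkio.export_vtk(sys.argv[1], grid,
                       {"label": grid.label_ids.astype(float)})
    print(f"wrote {sys.argv[1]}")
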