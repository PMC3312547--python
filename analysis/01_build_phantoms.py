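#!/usr/bin/env python
"""Build both electrode-arrangement phantoms and check their geometry.

Meshes the external-ring and internal-electrode cylinders at the forward
(fine) and inverse (coarse) densities, verifies volumes and electrode areas
against the analytic values, and exports the meshes as MSH/VTK for viewing.
"""

import argparse
from pathlib import Path
import sys

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from oeseit import PhantomSpec, build_phantom  # noqa: E402
from oeseit import io as oio  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("scratch/phantoms"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    disc = np.pi * 0.05**2
    for arrangement in ("external", "internal"):
        spec = PhantomSpec(arrangement=arrangement, target_offset=0.5)
        exact = np.pi * 0.8 - (np.pi * 0.05**2 * 0.8 if arrangement == "internal" else 0)
        for density in ("forward", "inverse"):
            mesh, electrodes = build_phantom(spec, density, seed=args.seed)
            areas = [e.area(mesh) for e in electrodes]
            print(
                f"{arrangement:8s} {density:8s}: {mesh.n_elements:6d} elements, "
                f"{mesh.n_vertices:5d} nodes, volume error "
                f"{(mesh.total_volume() - exact) / exact:+.3%}, electrode area error "
                f"[{min(areas)/disc - 1:+.1%}, {max(areas)/disc - 1:+.1%}]"
            )
            stem = args.out / f"{arrangement}_{density}"
            oio.write_msh(mesh, stem.with_suffix(".msh"), electrodes)
            oio.write_vtk(mesh, stem.with_suffix(".vtk"))
    print(f"meshes written under {args.out}")


if __name__ == "__main__":
    main()
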