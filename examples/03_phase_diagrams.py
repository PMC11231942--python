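"""Phase diagrams over the alpha1-alpha2 plane: lattice vs mean-field.

The mean-field diagram is exact and fast (closed-form equilibria). The
lattice sweep here is desk-scale (coarse grid, small lattice, few
replicates) so it runs in about two minutes; expect the same three-region
structure — emitters fix where alpha1 is small, vanish where alpha1
exceeds (p-c)/(p(1-c)), and coexist with cheaters in between.
"""

import numpy as np

from bvocgame import (ModelParams, SimConfig, phase_diagram_lattice,
                      phase_diagram_meanfield)
from bvocgame.viz import FigureSpec, render_heatmap

base = ModelParams(alpha1=0.5, alpha2=0.5, p=0.4, c=0.1, n=8, d=0.05)

fine = np.round(np.arange(0.02, 1.0, 0.02), 10)
mf = phase_diagram_meanfield(fine, fine, base)
mf.to_csv("meanfield_phase_diagram.csv")
render_heatmap(mf, FigureSpec("meanfield_phase_diagram.png",
                              title="mean-field stable emitter density",
                              overlay_boundaries=True))
counts = {r: int((mf.regime == r).sum()) for r in
          ("emitter-dominant", "coexistent", "nonemitter-dominant")}
print("mean-field regime cell counts:", counts)

coarse = np.round(np.arange(0.2, 1.0, 0.2), 10)
config = SimConfig(params=base, L=40, steps=1500, seed=0,
                   density_emitter=0.001, density_nonemitter=0.001,
                   record_every=1500)
lat = phase_diagram_lattice(coarse, coarse, config, n_replicates=3)
lat.to_csv("lattice_phase_diagram.csv")
render_heatmap(lat, FigureSpec("lattice_phase_diagram.png",
                               title="lattice mean emitter frequency",
                               annotate=True))
print("lattice mean frequencies (rows alpha2, cols alpha1):")
print(np.round(lat.cell_values, 2))
print("wrote meanfield_phase_diagram.{csv,png} and "
      "lattice_phase_diagram.{csv,png}")
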