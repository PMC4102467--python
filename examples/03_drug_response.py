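"""GI50 standardisation and per-line resistance:sensitivity profiling.

Standardises a tiny GI50 row by hand, then profiles a simulated z-score
matrix: for each cell line, how many compounds it resists (z <= -0.5) vs
responds to (z >= 0.5), and the fold range of those ratios across lines.
"""

import numpy as np

from varpharm import (
    SimulationConfig,
    gi50_to_zscores,
    ratio_fold_range,
    resistance_sensitivity_profile,
    simulate_panel,
)

gi50 = [1e-6, 1e-7, 1e-8]  # molar potencies a decade apart
z = gi50_to_zscores(gi50)
print(f"GI50 {gi50} -> z {np.round(z, 4)}  (z>0 = more sensitive than average)")

_, matrix, _ = simulate_panel(SimulationConfig(seed=1, n_drugs=40))
profiles = resistance_sensitivity_profile(matrix)
defined = [p for p in profiles if p.ratio]
most_resistant = max(defined, key=lambda p: p.ratio)
most_sensitive = min(defined, key=lambda p: p.ratio)
print(f"most resistant line: {most_resistant.cell_line} "
      f"(R:S = {most_resistant.n_resistant}:{most_resistant.n_sensitive})")
print(f"most sensitive line: {most_sensitive.cell_line} "
      f"(R:S = {most_sensitive.n_resistant}:{most_sensitive.n_sensitive})")
print(f"fold range of resistance:sensitivity ratios: "
      f"{ratio_fold_range(defined):.1f}x")
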