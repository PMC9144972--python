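"""Simulate microplate kill-curve panels under the two temperature-like
presets and write them as growth-panel CSVs.

The 37C-like preset (efficient adsorption, full burst, rare lysogeny)
collapses the culture at every MOI; the 30C-like preset (poor adsorption,
reduced burst, frequent lysogeny) barely dents growth.  Outputs feed
02_virulence_index.py.
"""

import sys
from dataclasses import replace
from pathlib import Path

from phagekit.io_tables import write_growth_panel
from phagekit.simulate import PRESET_30C, PRESET_37C, simulate_kill_curves

RESULTS = Path(__file__).resolve().parents[1] / "results"
MOIS = [10.0**k for k in range(-3, 4)]


def main(seed: int = 0) -> None:
    RESULTS.mkdir(exist_ok=True)
    for name, preset in (("37C", PRESET_37C), ("30C", PRESET_30C)):
        params = replace(preset, seed=seed)
        panel = simulate_kill_curves(params, MOIS, t_end=48.0, dt_out=1.0, cfu0=1e6,
                                     temperature=name)
        out = RESULTS / f"kill_curves_{name}.csv"
        write_growth_panel(panel, out)
        final = {moi: curve.od[-1] for moi, curve in panel.phage_curves}
        print(f"{name}: control OD48 = {panel.control.od[-1]:.2f}; "
              f"infected OD48 range {min(final.values()):.2f}-{max(final.values()):.2f} "
              f"-> {out.name}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
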