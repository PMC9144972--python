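"""Compute local virulence per MOI and the global virulence index (GVI)
for the simulated kill-curve panels from 01_simulate_kill_curves.py.

The analysis window runs from inoculation to the automatically detected
onset of stationary phase in the uninfected control.  Writes one profile
CSV per panel and prints the GVI contrast between the two presets.
"""

from pathlib import Path

import pandas as pd

from phagekit.io_tables import read_growth_panel
from phagekit.virulence import virulence_profile

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    gvis = {}
    for name in ("37C", "30C"):
        src = RESULTS / f"kill_curves_{name}.csv"
        if not src.exists():
            raise SystemExit(f"{src} missing - run 01_simulate_kill_curves.py first")
        panel = read_growth_panel(src, temperature=name)
        prof = virulence_profile(panel, onset="auto")
        gvis[name] = prof.gvi
        df = pd.DataFrame(prof.entries, columns=["log_moi", "local_virulence"])
        out = RESULTS / f"virulence_profile_{name}.csv"
        df.to_csv(out, index=False)
        print(f"{name}: window [{prof.window[0]:g}, {prof.window[1]:g}] h, "
              f"GVI = {prof.gvi:.3f} -> {out.name}")
    print(f"GVI contrast: 37C {gvis['37C']:.3f} vs 30C {gvis['30C']:.3f} "
          f"(more virulent at 37C: {gvis['37C'] > gvis['30C']})")


if __name__ == "__main__":
    main()
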