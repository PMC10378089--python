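"""Seeded fixture bundle: schematic profiles, a short simulation, and the
mouse/elephant timescale sets, written to disk for tests and docs.

All outputs are plain text (CSV/JSON) and byte-identical across re-runs
with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

from .allometry import build_timescales
from .profiles import write_profile
from .simulate import AgingSimConfig, generate_entropy_schematic, simulate

#: Printed mammalian anchors: (heartbeat period s, metabolic time s).
SPECIES_TIMESCALES = {"mouse": (0.1, 3.0), "elephant": (2.0, 60.0)}
BEATS_PER_LIFETIME = 1e9


def make_fixtures(seed: int = 0, out_dir="fixtures") -> dict[str, Path]:
    """Write the fixture bundle; returns a name -> path map.

    Contents: schematic young/old entropy profiles (``x,S`` CSV), young/old
    density profiles from a short default-parameter simulation
    (``position,value`` CSV), and a mouse/elephant timescale JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    young_S, old_S = generate_entropy_schematic(seed=seed)
    paths["entropy_young"] = out / "entropy_young.csv"
    paths["entropy_old"] = out / "entropy_old.csv"
    write_profile(young_S, paths["entropy_young"])
    write_profile(old_S, paths["entropy_old"])

    config = replace(AgingSimConfig(), n_iterations=200, seed=seed)
    traj = simulate(config)
    paths["density_young"] = out / "density_young.csv"
    paths["density_old"] = out / "density_old.csv"
    write_profile(traj.baseline, paths["density_young"])
    write_profile(traj.snapshots[-1], paths["density_old"])

    timescales = {
        name: build_timescales(t_H, tau, BEATS_PER_LIFETIME).to_dict()
        for name, (t_H, tau) in SPECIES_TIMESCALES.items()
    }
    paths["timescales"] = out / "timescales.json"
    paths["timescales"].write_text(
        json.dumps({"seed": seed, "species": timescales}, indent=2,
                   sort_keys=True) + "\n"
    )
    return paths
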