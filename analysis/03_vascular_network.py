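#!/usr/bin/env python
"""Prepare the microvascular network for the damage simulation.

Uses the published rat cortical network when a local copy exists at
data/brain99.txt (structured node/segment text format); otherwise generates
the synthetic stick-process network that emulates its statistical structure
(homogeneous Poisson midpoints, isotropic orientations, lognormal segment
lengths and diameters).  Either way the network summary statistics and a
canonical CSV copy are written for the downstream damage run.

Writes results/network.csv and results/network_stats.json.
"""

import dataclasses
import json
from pathlib import Path

from shuttlesim.vasculature import (
    SynthNetworkConfig,
    generate_synthetic,
    network_stats,
    read_network,
    write_network,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
BRAIN_FILE = ROOT / "data" / "brain99.txt"
SEED = 20260922


def load_or_generate():
    if BRAIN_FILE.exists():
        print(f"Using published network file {BRAIN_FILE}")
        return read_network(BRAIN_FILE, dialect="nodes-segments")
    print(
        "Published rat-brain network not present (data/brain99.txt); "
        "generating the synthetic stand-in network instead."
    )
    return generate_synthetic(SynthNetworkConfig(seed=SEED))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    net = load_or_generate()
    write_network(net, RESULTS / "network.csv")
    stats = network_stats(net)
    (RESULTS / "network_stats.json").write_text(
        json.dumps({"source": net.source, **dataclasses.asdict(stats)}, indent=2)
    )
    print(
        f"\n{stats.n_segments} segments, total length "
        f"{stats.total_length_um / 1000:.1f} mm in "
        f"{stats.box_volume_um3 / 1e9:.3f} mm³ "
        f"(length density {stats.length_density_um_per_um3:.2e} µm/µm³)."
    )
    print(
        f"Diameter median {stats.diameter_quantiles_um['q50']:.1f} µm "
        f"(5-95%: {stats.diameter_quantiles_um['q05']:.1f}-"
        f"{stats.diameter_quantiles_um['q95']:.1f} µm); "
        f"mean segment length {stats.mean_segment_length_um:.1f} µm."
    )


if __name__ == "__main__":
    main()
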