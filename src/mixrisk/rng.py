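"""Deterministic per-(region, component) random substreams.

One master seed drives the whole analysis. Every stochastic pipeline
component draws from its own child stream keyed by (region id, component
name), so re-running a single component — as the one-at-a-time sensitivity
analysis does — reproduces exactly the draws it made in the full run,
independent of which other components ran or in what order regions were
simulated.
"""

from __future__ import annotations

import zlib

import numpy as np

#: stable component indices; order is part of the reproducibility contract
COMPONENTS = {
    "age": 0,
    "obesity": 1,
    "inhalation": 2,
    "exposure": 3,
    "css": 4,
    "fit_params": 5,
}


def _region_key(region_id: str) -> int:
    # crc32 keeps the key in [0, 2^32): valid SeedSequence spawn-key word
    return zlib.crc32(str(region_id).encode("utf-8"))


def substream(seed: int, region_id: str, component: str) -> np.random.Generator:
    """Return the dedicated generator for one (region, component) pair."""
    if component not in COMPONENTS:
        raise ValueError(
            f"unknown component {component!r}; expected one of {sorted(COMPONENTS)}"
        )
    ss = np.random.SeedSequence(
        int(seed), spawn_key=(_region_key(region_id), COMPONENTS[component])
    )
    return np.random.Generator(np.random.PCG64(ss))
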