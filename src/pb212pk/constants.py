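"""Pinned physical constants for the ²¹²Pb decay series.

Half-lives, branching fractions and the 238 keV γ-emission yield are
standard evaluated nuclear data, shipped as one versioned YAML table
(``data/nuclear_data.yaml``) so that every number the package produces is
reproducible from a single source.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

#: unit → hours
_HOURS_PER_UNIT = {
    "h": 1.0,
    "min": 1.0 / 60.0,
    "s": 1.0 / 3600.0,
    "ms": 1e-3 / 3600.0,
    "us": 1e-6 / 3600.0,
    "d": 24.0,
}


@lru_cache(maxsize=1)
def load_nuclear_data() -> dict:
    """Parse the shipped nuclear-data table (cached)."""
    with resources.files("pb212pk.data").joinpath("nuclear_data.yaml").open() as fh:
        return yaml.safe_load(fh)


def half_life_hours(name: str) -> float:
    """Half-life of a nuclide in hours, from the pinned constants table."""
    for nuc in load_nuclear_data()["nuclides"]:
        if nuc["name"] == name:
            if nuc.get("stable"):
                raise ValueError(f"{name} is stable; it has no half-life")
            return nuc["half_life_value"] * _HOURS_PER_UNIT[nuc["half_life_unit"]]
    raise KeyError(f"unknown nuclide {name!r}")


#: ²¹²Pb half-life in hours — used throughout for decay correction.
PB212_HALF_LIFE_H: float = 10.64

#: Photons per decay at the 238.6 keV ²¹²Pb γ line.
GAMMA_YIELD_238KEV: float = 0.436
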