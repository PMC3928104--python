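"""Text I/O for decay curves and dye-pair photophysics registries.

Decays are two-column whitespace or comma separated text (time_ns, counts),
with an optional third column holding a measured instrument response.  Dye
pairs live in a TOML registry, either with R0 given directly or with the
quantities needed to compute it.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np

from .fret_model import DecayCurve, DyePairPhotophysics


def read_decay(path: str | Path) -> DecayCurve:
    data = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
    if data.shape[1] == 1:
        # counts only: commas as delimiter?
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_ns counts [irf]")
    irf = data[:, 2] if data.shape[1] >= 3 else None
    return DecayCurve(time=data[:, 0], counts=data[:, 1], irf=irf)


def write_decay(curve: DecayCurve, path: str | Path) -> None:
    cols = [curve.time, curve.counts]
    header = "time_ns counts"
    if curve.irf is not None:
        cols.append(curve.irf)
        header += " irf"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.9g")


def load_photophysics(path: str | Path) -> dict[str, DyePairPhotophysics]:
    """Read a dye-pair registry.

    TOML layout::

        [pairs.AEDANS-DABM]
        r0 = 40.0

        [pairs.MIANS-DDPM]
        quantum_yield = 0.35
        overlap_integral = 1.1e14
        kappa2 = 0.6667
        refractive_index = 1.4
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    pairs = cfg.get("pairs", cfg)
    out: dict[str, DyePairPhotophysics] = {}
    for name, entry in pairs.items():
        if not isinstance(entry, dict):
            continue
        out[name] = DyePairPhotophysics(
            r0=entry.get("r0"),
            quantum_yield=entry.get("quantum_yield"),
            overlap_integral=entry.get("overlap_integral"),
            kappa2=entry.get("kappa2", 2.0 / 3.0),
            refractive_index=entry.get("refractive_index", 1.4),
        )
    if not out:
        raise ValueError(f"{path}: no dye pairs found")
    return out
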