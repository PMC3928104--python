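"""FRET distance tables -> flat-bottom Calpha–Calpha distance restraints.

Each measured distance distribution (mean ``rbar``, half-width ``hw``) becomes
one restraint between the Calpha atoms of the labelled residues.  The default
bound scheme places the flat bottom between the measured FRET distance and the
FRET distance plus 7 Å — the 7 Å absorbs the probe linker, which folds
randomly rather than pointing along the inter-site vector.  The half-width
sets the restraint stiffness through a Boltzmann-consistent harmonic width,
``k = k_B T / sigma**2`` with ``sigma = hw / 2.35``.

Restraint files are written in the GROMACS ``[ distance_restraints ]`` dialect
(distances in nm) with enough metadata in trailing comments to round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fret_model import HW_PER_SIGMA
from .sitemap import SiteMap, SiteRef

#: Boltzmann constant in kJ mol^-1 K^-1.
K_B = 0.0083144621

#: Default width of the linear-penalty onset beyond up1 (Å), required by the
#: GROMACS restraint dialect.
UP2_PAD = 2.0

#: Default linker allowance added to the measured distance for the upper
#: bound (Å).
LINKER_ALLOWANCE = 7.0

BOUND_SCHEMES = ("paper-default", "symmetric", "point")

STATES = ("ca_free", "ca_saturated")


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class FretTableRow:
    """One measured donor–acceptor distance distribution."""

    donor_site: tuple[str, int]  # (subunit, residue)
    acceptor_site: tuple[str, int]
    state: str  # ca_free | ca_saturated
    rbar: float  # Å
    hw: float  # Å

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise RestraintError(f"unknown state {self.state!r}")
        if self.donor_site[1] < 1 or self.acceptor_site[1] < 1:
            raise RestraintError("residue numbers must be >= 1")
        if self.rbar <= 0 or self.hw <= 0:
            raise RestraintError("rbar and hw must be positive")


@dataclass(frozen=True)
class RestraintRecord:
    """Flat-bottom Calpha–Calpha distance restraint."""

    site_i: SiteRef
    site_j: SiteRef
    low: float  # Å
    up1: float  # Å
    up2: float  # Å
    force_constant: float  # kJ mol^-1 nm^-2
    label: str

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.up1 <= self.up2):
            raise RestraintError(
                f"bounds must satisfy 0 < low <= up1 <= up2 "
                f"(got {self.low}, {self.up1}, {self.up2})"
            )
        if self.force_constant <= 0:
            raise RestraintError("force constant must be positive")


def read_fret_table(path: str | Path) -> list[FretTableRow]:
    """Read a TSV with columns subunit_d, res_d, subunit_a, res_a, state, rbar_A, hw_A."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"subunit_d", "res_d", "subunit_a", "res_a", "state", "rbar_A", "hw_A"}
    missing = required - set(df.columns)
    if missing:
        raise RestraintError(f"{path}: missing columns {sorted(missing)}")
    return [
        FretTableRow(
            donor_site=(str(r.subunit_d), int(r.res_d)),
            acceptor_site=(str(r.subunit_a), int(r.res_a)),
            state=str(r.state),
            rbar=float(r.rbar_A),
            hw=float(r.hw_A),
        )
        for r in df.itertuples(index=False)
    ]


def write_fret_table(rows: list[FretTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subunit_d": [r.donor_site[0] for r in rows],
            "res_d": [r.donor_site[1] for r in rows],
            "subunit_a": [r.acceptor_site[0] for r in rows],
            "res_a": [r.acceptor_site[1] for r in rows],
            "state": [r.state for r in rows],
            "rbar_A": [r.rbar for r in rows],
            "hw_A": [r.hw for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def force_constant_from_hw(hw: float, temperature: float = 300.0) -> float:
    """Harmonic force constant k = k_B T / sigma**2 in kJ mol^-1 nm^-2.

    ``sigma = hw / 2.35`` converted from Å to nm: a broad distribution is an
    uninformative (soft) restraint, a narrow one a stiff restraint.
    """
    if hw <= 0:
        raise RestraintError("half-width must be positive")
    if temperature <= 0:
        raise RestraintError("temperature must be positive")
    sigma_nm = hw / HW_PER_SIGMA / 10.0
    return K_B * temperature / sigma_nm**2


def _bounds(rbar: float, scheme: str) -> tuple[float, float, float]:
    if scheme == "paper-default":
        low, up1 = rbar, rbar + LINKER_ALLOWANCE
    elif scheme == "symmetric":
        low, up1 = max(rbar - LINKER_ALLOWANCE, 1e-3), rbar + LINKER_ALLOWANCE
    elif scheme == "point":
        low = up1 = rbar
    else:
        raise RestraintError(
            f"unknown bound scheme {scheme!r}; choose from {BOUND_SCHEMES}"
        )
    return low, up1, up1 + UP2_PAD


def build_restraints(
    rows: list[FretTableRow],
    state: str,
    site_map: SiteMap,
    scheme: str = "paper-default",
    temperature: float = 300.0,
    structure=None,
    copy: int = 0,
) -> list[RestraintRecord]:
    """One restraint per table row of the requested Ca2+ state.

    Site references get stable serial numbers: atom indices when a structure
    is supplied, else a deterministic enumeration of the distinct sites in
    (subunit, residue) order.
    """
    if state not in STATES:
        raise RestraintError(f"unknown state {state!r}")
    selected = [r for r in rows if r.state == state]
    unresolved: list[str] = []
    refs: dict[tuple[str, int], SiteRef] = {}
    for row in selected:
        for subunit, residue in (row.donor_site, row.acceptor_site):
            if (subunit, residue) in refs:
                continue
            try:
                ref = site_map.resolve(subunit, residue, copy=copy)
                if structure is not None:
                    serial = structure.atom_index(ref.chain, ref.resnum, ref.atom)
                    ref = replace(ref, serial=serial + 1)
                refs[(subunit, residue)] = ref
            except KeyError as exc:
                unresolved.append(f"{subunit} {residue}: {exc}")
    if unresolved:
        raise RestraintError(
            "unresolvable sites:\n  " + "\n  ".join(sorted(set(unresolved)))
        )
    if structure is None:
        for n, key in enumerate(sorted(refs), start=1):
            refs[key] = replace(refs[key], serial=n)

    records = []
    for row in selected:
        low, up1, up2 = _bounds(row.rbar, scheme)
        records.append(
            RestraintRecord(
                site_i=refs[row.donor_site],
                site_j=refs[row.acceptor_site],
                low=low,
                up1=up1,
                up2=up2,
                force_constant=force_constant_from_hw(row.hw, temperature),
                label=(
                    f"{row.donor_site[0]}{row.donor_site[1]}-"
                    f"{row.acceptor_site[0]}{row.acceptor_site[1]}/{row.state}"
                ),
            )
        )
    return records


def _fmt_ref(ref: SiteRef) -> str:
    return f"{ref.subunit}:{ref.residue}:{ref.chain}:{ref.resnum}:{ref.atom}"


def _parse_ref(token: str, serial: int) -> SiteRef:
    subunit, residue, chain, resnum, atom = token.split(":")
    return SiteRef(subunit, int(residue), chain, int(resnum), atom, serial)


def write_distance_restraints(
    records: list[RestraintRecord], path: str | Path
) -> list[str]:
    """Write the GROMACS distance-restraint dialect (nm); returns warnings.

    Columns: ai aj funct index type' low up1 up2 kfac, one line per record in
    input order with the restraint index running from 0.  Duplicate (ai, aj)
    pairs are warned about but both written.
    """
    lines = ["[ distance_restraints ]",
             ";  ai   aj type index type' low up1 up2 kfac ; label site_i site_j"]
    warnings: list[str] = []
    seen: set[tuple[int, int]] = set()
    for idx, rec in enumerate(records):
        ai = rec.site_i.serial or 0
        aj = rec.site_j.serial or 0
        pair = (min(ai, aj), max(ai, aj))
        if pair in seen:
            warnings.append(f"duplicate atom pair {pair} at restraint {idx}")
        seen.add(pair)
        lines.append(
            f"{ai:5d} {aj:5d} 1 {idx:4d} 1 "
            f"{rec.low / 10.0:.10g} {rec.up1 / 10.0:.10g} {rec.up2 / 10.0:.10g} "
            f"{rec.force_constant:.10g} "
            f"; {rec.label} {_fmt_ref(rec.site_i)} {_fmt_ref(rec.site_j)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return warnings


def read_distance_restraints(path: str | Path) -> list[RestraintRecord]:
    """Inverse of :func:`write_distance_restraints`."""
    records: list[RestraintRecord] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("[", ";")):
            continue
        fields, _, comment = line.partition(";")
        nums = fields.split()
        label, tok_i, tok_j = comment.split()
        records.append(
            RestraintRecord(
                site_i=_parse_ref(tok_i, int(nums[0])),
                site_j=_parse_ref(tok_j, int(nums[1])),
                low=float(nums[5]) * 10.0,
                up1=float(nums[6]) * 10.0,
                up2=float(nums[7]) * 10.0,
                force_constant=float(nums[8]),
                label=label,
            )
        )
    return records


@dataclass
class RestraintScore:
    """Per-restraint satisfaction on a structure."""

    report: pd.DataFrame  # label, distance_A, low_A, up1_A, violation_A
    fraction_satisfied: float
    total_violation: float


def score_restraints(structure, records: list[RestraintRecord]) -> RestraintScore:
    """Actual Calpha distances vs restraint bounds.

    violation = max(0, low - d, d - up1): zero anywhere inside the flat
    bottom, linear outside.
    """
    rows = []
    for rec in records:
        d = float(
            np.linalg.norm(
                structure.position(rec.site_i) - structure.position(rec.site_j)
            )
        )
        violation = max(0.0, rec.low - d, d - rec.up1)
        rows.append(
            {
                "label": rec.label,
                "distance_A": d,
                "low_A": rec.low,
                "up1_A": rec.up1,
                "violation_A": violation,
            }
        )
    report = pd.DataFrame(rows)
    n = len(rows)
    satisfied = int((report["violation_A"] == 0).sum()) if n else 0
    return RestraintScore(
        report=report,
        fraction_satisfied=satisfied / n if n else float("nan"),
        total_violation=float(report["violation_A"].sum()) if n else 0.0,
    )
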