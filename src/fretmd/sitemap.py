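"""Mapping from paper-style labelling sites (subunit, residue) to file atoms.

FRET tables label sites as e.g. ``cTnI 131``; deposited structures address the
same residue as (chain id, author residue number, atom name).  A
:class:`SiteMap` holds that translation, including the choice of
crystallographic copy when a deposited entry contains several copies of the
complex.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path


class SiteMappingError(KeyError):
    """A labelled site cannot be resolved to a file atom."""


@dataclass(frozen=True)
class SiteRef:
    """A resolved atom reference."""

    subunit: str
    residue: int
    chain: str
    resnum: int
    atom: str = "CA"
    serial: int | None = None

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.atom)


@dataclass
class SiteMap:
    """Translate (subunit, paper residue) into (chain, file residue, atom).

    Parameters
    ----------
    copies
        One dict per crystallographic copy, mapping subunit name to chain id.
    offsets
        Additive offset from paper residue number to file residue number,
        per subunit (default 0: author numbering matches the paper).
    overrides
        Per-site explicit mappings keyed ``"subunit:residue"``, each a dict
        with ``chain``/``resnum`` and optional ``atom``.
    """

    copies: list[dict[str, str]]
    offsets: dict[str, int] = field(default_factory=dict)
    overrides: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.copies:
            raise ValueError("site map needs at least one copy")

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def resolve(
        self, subunit: str, residue: int, copy: int = 0, atom: str = "CA"
    ) -> SiteRef:
        key = f"{subunit}:{residue}"
        if key in self.overrides:
            ov = self.overrides[key]
            return SiteRef(
                subunit, residue, ov["chain"], int(ov["resnum"]),
                ov.get("atom", atom),
            )
        try:
            chains = self.copies[copy]
        except IndexError:
            raise SiteMappingError(f"no crystallographic copy {copy}") from None
        if subunit not in chains:
            raise SiteMappingError(
                f"subunit {subunit!r} not mapped in copy {copy} "
                f"(have {sorted(chains)})"
            )
        resnum = residue + self.offsets.get(subunit, 0)
        return SiteRef(subunit, residue, chains[subunit], resnum, atom)

    @classmethod
    def from_toml(cls, path: str | Path) -> "SiteMap":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        copies_cfg = cfg.get("copies", {})
        # copies may be a table of numbered tables or a single mapping
        if copies_cfg and all(isinstance(v, dict) for v in copies_cfg.values()):
            copies = [copies_cfg[k] for k in sorted(copies_cfg)]
        elif copies_cfg:
            copies = [copies_cfg]
        else:
            raise ValueError(f"{path}: no [copies] section")
        return cls(
            copies=copies,
            offsets={k: int(v) for k, v in cfg.get("offsets", {}).items()},
            overrides=cfg.get("overrides", {}),
        )
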