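"""Structure and trajectory container with PDB/mmCIF readers.

:class:`StructureModel` is a flat atom table (chain, residue number, residue
name, atom name) plus one or more coordinate frames sharing that table.
Reading standard files goes through gemmi (PDB and mmCIF dialects, author
numbering); multi-model PDB files (MODEL/ENDMDL) become trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .sitemap import SiteMappingError, SiteRef


@dataclass
class StructureModel:
    """Coordinates plus a flat atom table.

    ``frames`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom; ``coords``
    is the first frame.
    """

    chains: np.ndarray  # str per atom
    resnums: np.ndarray  # int per atom (author numbering)
    resnames: np.ndarray  # str per atom
    names: np.ndarray  # atom name per atom
    frames: np.ndarray  # (n_frames, n_atoms, 3) float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, :, :]
        n = self.chains.shape[0]
        for arr in (self.resnums, self.resnames, self.names):
            if arr.shape[0] != n:
                raise ValueError("atom table arrays must have equal length")
        if self.frames.shape[1] != n or self.frames.shape[2] != 3:
            raise ValueError("frames not conformable with the atom table")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("coordinates must be finite")
        self._index: dict[tuple[str, int, str], int] = {}
        for i in range(n):
            key = (str(self.chains[i]), int(self.resnums[i]), str(self.names[i]))
            self._index.setdefault(key, i)

    # -- accessors ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return int(self.chains.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def coords(self) -> np.ndarray:
        return self.frames[0]

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chains:
            seen.setdefault(str(c), None)
        return list(seen)

    def atom_index(self, chain: str, resnum: int, atom: str = "CA") -> int:
        try:
            return self._index[(chain, int(resnum), atom)]
        except KeyError:
            raise SiteMappingError(
                f"atom {atom} of residue {resnum} in chain {chain} "
                "not present in the structure"
            ) from None

    def position(self, ref: SiteRef, frame: int = 0) -> np.ndarray:
        return self.frames[frame, self.atom_index(ref.chain, ref.resnum, ref.atom)]

    def select(
        self,
        chains: list[str] | None = None,
        names: list[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chains is not None:
            mask &= np.isin(self.chains, chains)
        if names is not None:
            mask &= np.isin(self.names, names)
        return mask

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            chains=self.chains[mask],
            resnums=self.resnums[mask],
            resnames=self.resnames[mask],
            names=self.names[mask],
            frames=self.frames[:, mask, :],
        )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "StructureModel":
        """Read a PDB or mmCIF file; multiple models become frames."""
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        if len(st) == 0:
            raise ValueError(f"{path}: no models")
        chains: list[str] = []
        resnums: list[int] = []
        resnames: list[str] = []
        names: list[str] = []
        first = st[0]
        for chain in first:
            for res in chain:
                for atom in res:
                    chains.append(chain.name)
                    resnums.append(res.seqid.num)
                    resnames.append(res.name)
                    names.append(atom.name)
        frames = np.empty((len(st), len(chains), 3))
        for m, model in enumerate(st):
            i = 0
            for chain in model:
                for res in chain:
                    for atom in res:
                        if i >= frames.shape[1]:
                            raise ValueError(
                                f"{path}: model {m} atom count differs from model 0"
                            )
                        frames[m, i] = (atom.pos.x, atom.pos.y, atom.pos.z)
                        i += 1
            if i != frames.shape[1]:
                raise ValueError(
                    f"{path}: model {m} atom count differs from model 0"
                )
        return cls(
            chains=np.array(chains),
            resnums=np.array(resnums, dtype=int),
            resnames=np.array(resnames),
            names=np.array(names),
            frames=frames,
        )

    def to_pdb(self, path: str | Path) -> None:
        """Write all frames as a (multi-model) PDB file."""
        lines: list[str] = []
        multi = self.n_frames > 1
        for m in range(self.n_frames):
            if multi:
                lines.append(f"MODEL     {m + 1:4d}")
            serial = 0
            for i in range(self.n_atoms):
                serial += 1
                x, y, z = self.frames[m, i]
                name = str(self.names[i])
                # PDB atom-name column convention: pad short names from col 14
                name_f = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {name_f}{'':1s}{str(self.resnames[i]):>3s} "
                    f"{str(self.chains[i])[:1]:1s}{int(self.resnums[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                )
            if multi:
                lines.append("ENDMDL")
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")
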