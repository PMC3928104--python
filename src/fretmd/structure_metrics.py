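"""Structure and trajectory analytics for FRET-based model validation.

Covers the validation toolbox used around restrained simulations of the
troponin complex: Calpha site distances, N-domain pocket openness via the
TnC 13–51 distance, geometric hydrogen-bond detection, helix assignment from
the i -> i+4 backbone H-bond pattern, helix-axis angles, Kabsch-superposition
RMSD, per-residue RMSF, and agreement reports against measured FRET tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .restraints import FretTableRow
from .sitemap import SiteMap, SiteMappingError
from .structures import StructureModel

#: Default heavy-atom donor...acceptor distance cutoff (Å) and D-H...A angle
#: cutoff (degrees), Ligplot-like defaults.
HBOND_DIST_CUT = 3.5
HBOND_ANGLE_CUT = 120.0
#: Donor-angle proxy cutoff used when no hydrogen can be inferred.
HBOND_PROXY_ANGLE_CUT = 90.0

#: Default open/closed threshold for the TnC N-domain pocket: midpoint of the
#: closed (19.21 Å) and open (29.06 Å) crystal anchors of the 13–51 distance.
POCKET_THRESHOLD = 24.0

#: Calpha-Calpha distance beyond which consecutive residues are treated as a
#: chain break.
CHAIN_BREAK_CUT = 4.5


class DegenerateAxisError(ValueError):
    pass


@dataclass(frozen=True)
class PocketState:
    """Openness of the TnC N-domain hydrophobic pocket."""

    d_13_51: float
    state: str  # "open" | "closed"
    threshold: float


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str]  # (chain, resnum, atom name)
    acceptor: tuple[str, int, str]
    distance: float  # heavy-atom D...A, Å
    angle: float  # D-H...A (or proxy) in degrees


# ---------------------------------------------------------------------------
# distances and pocket openness


def ca_distance(
    structure: StructureModel,
    site_a: tuple[str, int],
    site_b: tuple[str, int],
    site_map: SiteMap,
    copy: int = 0,
) -> float:
    """Euclidean Calpha–Calpha distance between two labelled sites (Å)."""
    ref_a = site_map.resolve(*site_a, copy=copy)
    ref_b = site_map.resolve(*site_b, copy=copy)
    return float(np.linalg.norm(structure.position(ref_a) - structure.position(ref_b)))


def scan_pair_distances(
    structure: StructureModel,
    res_a: int,
    res_b: int,
    atom: str = "CA",
    same_chain: bool | None = None,
) -> list[tuple[str, str, float]]:
    """Distances between residue ``res_a`` and ``res_b`` over all chain pairs.

    Deposited entries often hold several crystallographic copies of a complex
    and publications rarely say which copy a distance was measured on; this
    scans every chain combination holding both residues.  ``same_chain``
    restricts to intra-chain (True) or inter-chain (False) pairs.
    """
    out = []
    chains = structure.chain_ids()
    for ca in chains:
        for cb in chains:
            if same_chain is True and ca != cb:
                continue
            if same_chain is False and ca == cb:
                continue
            try:
                pa = structure.coords[structure.atom_index(ca, res_a, atom)]
                pb = structure.coords[structure.atom_index(cb, res_b, atom)]
            except SiteMappingError:
                continue
            if ca == cb and res_a == res_b:
                continue
            out.append((ca, cb, float(np.linalg.norm(pa - pb))))
    return out


def pocket_openness(
    structure: StructureModel,
    site_map: SiteMap,
    threshold: float = POCKET_THRESHOLD,
    subunit: str = "cTnC",
    residues: tuple[int, int] = (13, 51),
    copy: int = 0,
) -> PocketState:
    """Open/closed call on the TnC N-domain from the 13–51 Calpha distance.

    ``open`` when the distance is >= threshold (boundary counts as open).
    """
    d = ca_distance(
        structure, (subunit, residues[0]), (subunit, residues[1]), site_map, copy
    )
    return PocketState(d, "open" if d >= threshold else "closed", threshold)


# ---------------------------------------------------------------------------
# hydrogen bonds and helices


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    u, v = _unit(a - b), _unit(c - b)
    return math.degrees(math.acos(float(np.clip(np.dot(u, v), -1.0, 1.0))))


def _infer_amide_h(
    structure: StructureModel, idx_n: int
) -> np.ndarray | None:
    """Place the backbone amide hydrogen for atom index ``idx_n`` (an N).

    H lies 1.0 Å from N, opposite the bisector of the N->CA and N->C(prev)
    bonds.  Returns None when the flanking atoms are missing (chain start).
    """
    chain = str(structure.chains[idx_n])
    resnum = int(structure.resnums[idx_n])
    try:
        ca = structure.coords[structure.atom_index(chain, resnum, "CA")]
        c_prev = structure.coords[structure.atom_index(chain, resnum - 1, "C")]
    except SiteMappingError:
        return None
    n = structure.coords[idx_n]
    direction = -(_unit(ca - n) + _unit(c_prev - n))
    norm = np.linalg.norm(direction)
    if norm == 0:
        return None
    return n + direction / norm


def _antecedent(structure: StructureModel, idx: int) -> np.ndarray | None:
    """A heavy atom covalently attached to the donor, for the angle proxy."""
    chain = str(structure.chains[idx])
    resnum = int(structure.resnums[idx])
    name = str(structure.names[idx])
    for cand in ("CA", "C", "CB"):
        if cand == name:
            continue
        try:
            return structure.coords[structure.atom_index(chain, resnum, cand)]
        except SiteMappingError:
            continue
    return None


def detect_hbonds(
    structure: StructureModel,
    donor_mask: np.ndarray | None = None,
    acceptor_mask: np.ndarray | None = None,
    d_cut: float = HBOND_DIST_CUT,
    angle_cut: float = HBOND_ANGLE_CUT,
) -> list[HBond]:
    """Geometric hydrogen-bond detection.

    Donors default to nitrogen heavy atoms, acceptors to oxygens (plus
    nitrogens not acting as the donor).  A pair is a hydrogen bond when the
    heavy-atom D...A distance is <= ``d_cut`` and the D-H...A angle at an
    explicit or inferred amide hydrogen is >= ``angle_cut``; when no hydrogen
    can be placed, a donor-angle proxy (antecedent-D...A >= 90 deg) is used.
    Pairs within the same residue or sequence-adjacent residues of one chain
    are excluded.  Output is deterministically ordered by donor then acceptor.
    """
    names = np.array([str(n) for n in structure.names])
    if donor_mask is None:
        donor_mask = np.char.startswith(names, "N")
    if acceptor_mask is None:
        acceptor_mask = np.char.startswith(names, "O") | np.char.startswith(names, "N")

    donors = np.nonzero(donor_mask)[0]
    acceptors = np.nonzero(acceptor_mask)[0]
    if donors.size == 0 or acceptors.size == 0:
        return []

    coords = structure.coords
    tree = cKDTree(coords[acceptors])
    bonds: list[HBond] = []
    for di in donors:
        d_pos = coords[di]
        d_chain = str(structure.chains[di])
        d_resnum = int(structure.resnums[di])
        # hydrogen: explicit H in the same residue, else inferred amide H
        h_pos = None
        try:
            h_pos = coords[structure.atom_index(d_chain, d_resnum, "H")]
        except SiteMappingError:
            if str(structure.names[di]) == "N":
                h_pos = _infer_amide_h(structure, di)
        for aj_local in tree.query_ball_point(d_pos, d_cut):
            aj = int(acceptors[aj_local])
            if aj == di:
                continue
            a_chain = str(structure.chains[aj])
            a_resnum = int(structure.resnums[aj])
            if a_chain == d_chain and abs(a_resnum - d_resnum) <= 1:
                continue
            a_pos = coords[aj]
            dist = float(np.linalg.norm(a_pos - d_pos))
            if dist > d_cut:
                continue
            if h_pos is not None:
                angle = _angle_deg(d_pos, h_pos, a_pos)
                if angle < angle_cut:
                    continue
            else:
                ante = _antecedent(structure, di)
                if ante is None:
                    continue
                angle = _angle_deg(ante, d_pos, a_pos)
                if angle < HBOND_PROXY_ANGLE_CUT:
                    continue
            bonds.append(
                HBond(
                    donor=(d_chain, d_resnum, str(structure.names[di])),
                    acceptor=(a_chain, a_resnum, str(structure.names[aj])),
                    distance=dist,
                    angle=angle,
                )
            )
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


@dataclass
class HelixAssignment:
    """Per-residue H/C labels and contiguous helical segments."""

    labels: dict[tuple[str, int], str]  # (chain, resnum) -> "H" | "C"
    segments: list[tuple[str, int, int]]  # (chain, start resnum, end resnum)

    def n_helical(self) -> int:
        return sum(1 for v in self.labels.values() if v == "H")


def assign_helices(
    structure: StructureModel,
    d_cut: float = HBOND_DIST_CUT,
    angle_cut: float = HBOND_ANGLE_CUT,
) -> HelixAssignment:
    """Helix assignment from the i -> i+4 backbone hydrogen-bond pattern.

    A backbone H-bond from the carbonyl O of residue i to the amide N of
    residue i+4 marks residues i+1..i+4 as helical; contiguous helical runs
    of >= 4 residues are reported as segments.  Chain breaks (consecutive
    Calpha separation > 4.5 Å or a gap in numbering) split segments.
    """
    names = np.array([str(n) for n in structure.names])
    donor_mask = names == "N"
    acceptor_mask = names == "O"
    bonds = detect_hbonds(structure, donor_mask, acceptor_mask, d_cut, angle_cut)
    turn_bonds = {
        (b.acceptor[0], b.acceptor[1])
        for b in bonds
        if b.donor[0] == b.acceptor[0] and b.donor[1] - b.acceptor[1] == 4
    }

    labels: dict[tuple[str, int], str] = {}
    residues: dict[str, list[int]] = {}
    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    for i in np.nonzero(names == "CA")[0]:
        chain = str(structure.chains[i])
        resnum = int(structure.resnums[i])
        residues.setdefault(chain, []).append(resnum)
        ca_pos[(chain, resnum)] = structure.coords[i]
        labels[(chain, resnum)] = "C"

    for chain, start in turn_bonds:
        for r in range(start + 1, start + 5):
            if (chain, r) in labels:
                labels[(chain, r)] = "H"

    segments: list[tuple[str, int, int]] = []
    for chain, resnums in residues.items():
        resnums = sorted(resnums)
        run: list[int] = []
        prev: int | None = None
        for r in resnums:
            broken = (
                prev is not None
                and (
                    r != prev + 1
                    or np.linalg.norm(ca_pos[(chain, r)] - ca_pos[(chain, prev)])
                    > CHAIN_BREAK_CUT
                )
            )
            if labels[(chain, r)] == "H" and not broken and run:
                run.append(r)
            elif labels[(chain, r)] == "H":
                if len(run) >= 4:
                    segments.append((chain, run[0], run[-1]))
                run = [r]
            else:
                if len(run) >= 4:
                    segments.append((chain, run[0], run[-1]))
                run = []
            prev = r
        if len(run) >= 4:
            segments.append((chain, run[0], run[-1]))
    # residues in sub-threshold runs revert to coil
    in_segment = {
        (chain, r)
        for chain, start, end in segments
        for r in range(start, end + 1)
    }
    for key, lab in labels.items():
        if lab == "H" and key not in in_segment:
            labels[key] = "C"
    segments.sort()
    return HelixAssignment(labels=labels, segments=segments)


def _segment_axis(
    structure: StructureModel, segment: tuple[str, int, int]
) -> np.ndarray:
    """Least-squares axis (unit vector) of a helical segment's Calphas.

    First principal component of the centered Calpha coordinates, oriented
    from the segment's first toward its last residue.
    """
    chain, start, end = segment
    coords = []
    for r in range(start, end + 1):
        try:
            coords.append(structure.coords[structure.atom_index(chain, r, "CA")])
        except SiteMappingError:
            continue
    if len(coords) < 5:
        raise DegenerateAxisError(
            f"segment {segment} has {len(coords)} Calphas; need >= 5"
        )
    x = np.asarray(coords)
    centered = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, x[-1] - x[0]) < 0:
        axis = -axis
    return axis


def helix_axis_angle(
    structure: StructureModel,
    segment_1: tuple[str, int, int],
    segment_2: tuple[str, int, int] | None = None,
    reference_axis: np.ndarray | None = None,
) -> float:
    """Angle (degrees, in [0, 180]) between two helix axes.

    Axes point along the chain direction, so antiparallel helices read near
    180 deg rather than 0.  The second axis may be given explicitly as
    ``reference_axis``.
    """
    u = _segment_axis(structure, segment_1)
    if segment_2 is not None:
        v = _segment_axis(structure, segment_2)
    elif reference_axis is not None:
        v = _unit(np.asarray(reference_axis, dtype=float))
    else:
        raise ValueError("need segment_2 or reference_axis")
    return math.degrees(math.acos(float(np.clip(np.dot(u, v), -1.0, 1.0))))


# ---------------------------------------------------------------------------
# superposition, RMSD, RMSF


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered ``mobile`` onto ``target``."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def kabsch_rmsd(
    frames: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Optimal-superposition RMSD of each frame against a reference (Å).

    ``frames`` has shape (n_frames, n_atoms, 3); ``selection`` is an optional
    boolean/index mask over atoms.  The superposition is computed on (and the
    RMSD reported over) the selected atoms.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        frames = frames[:, selection, :]
        reference = reference[selection]
    if reference.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ref_c = reference - reference.mean(axis=0)
    out = np.empty(frames.shape[0])
    for i, frame in enumerate(frames):
        mob = frame - frame.mean(axis=0)
        rot = kabsch_rotation(mob, ref_c)
        diff = mob @ rot - ref_c
        out[i] = np.sqrt((diff**2).sum() / reference.shape[0])
    return out


def rmsf(
    frames: np.ndarray,
    selection: np.ndarray | None = None,
    equilibration_frames: int = 0,
    align: bool = False,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time mean (Å).

    ``sqrt(<|x - <x>|^2>)`` over the post-equilibration frames.  Frames are
    assumed pre-superposed; pass ``align=True`` to Kabsch-align each frame to
    the first post-equilibration frame on the selection first.
    """
    frames = np.asarray(frames, dtype=float)
    frames = frames[equilibration_frames:]
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 post-equilibration frames")
    if selection is not None:
        frames = frames[:, selection, :]
    if align:
        ref = frames[0] - frames[0].mean(axis=0)
        aligned = np.empty_like(frames)
        for i, frame in enumerate(frames):
            mob = frame - frame.mean(axis=0)
            aligned[i] = mob @ kabsch_rotation(mob, ref)
        frames = aligned
    mean = frames.mean(axis=0)
    return np.sqrt(((frames - mean) ** 2).sum(axis=-1).mean(axis=0))


def rmsf_per_residue(
    structure: StructureModel,
    equilibration_frames: int = 0,
    align: bool = False,
) -> pd.DataFrame:
    """Calpha RMSF per residue across a trajectory."""
    mask = structure.select(names=["CA"])
    values = rmsf(structure.frames, mask, equilibration_frames, align)
    return pd.DataFrame(
        {
            "chain": structure.chains[mask],
            "resnum": structure.resnums[mask],
            "rmsf_A": values,
        }
    )


# ---------------------------------------------------------------------------
# FRET agreement


def compare_to_fret(
    rows: list[FretTableRow],
    structure: StructureModel,
    site_map: SiteMap,
    tolerance_frac: float = 0.10,
    linker_allowance: float = 7.0,
    state: str | None = None,
    copy: int = 0,
) -> pd.DataFrame:
    """Model Calpha distances against measured FRET distances, row by row.

    A row agrees when ``|d_model - rbar| <= tolerance_frac * rbar +
    linker_allowance`` — the +-10% FRET distance uncertainty plus the random
    folding of the ~10 Å probe linker (effective ~7 Å).  Unmapped rows are
    reported with NaN distance, not fatal.
    """
    out = []
    for row in rows:
        if state is not None and row.state != state:
            continue
        try:
            d = ca_distance(structure, row.donor_site, row.acceptor_site,
                            site_map, copy)
            deviation = d - row.rbar
            agrees = abs(deviation) <= tolerance_frac * row.rbar + linker_allowance
        except KeyError as exc:
            d, deviation, agrees = float("nan"), float("nan"), False
        out.append(
            {
                "donor": f"{row.donor_site[0]}{row.donor_site[1]}",
                "acceptor": f"{row.acceptor_site[0]}{row.acceptor_site[1]}",
                "state": row.state,
                "fret_A": row.rbar,
                "hw_A": row.hw,
                "model_A": d,
                "deviation_A": deviation,
                "fractional_deviation": deviation / row.rbar,
                "within_tolerance": agrees,
            }
        )
    return pd.DataFrame(out)
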