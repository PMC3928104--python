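"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's inputs end to end: Poisson-noise TCSPC
decay pairs from a chosen donor model and Gaussian distance distribution; toy
structures (ideal helices, extended chains, two-domain dumbbells with
prescribed inter-site distances) with full backbone geometry; and jittered
multi-frame trajectories with prescribed per-residue fluctuation amplitudes.

The decay defaults emulate the measurement setup the fitting stage expects:
1024 channels and a window spanning at least five donor lifetimes (0.055 ns
channels for an AEDANS-like ~11 ns donor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fret_model import (
    DecayCurve,
    DistanceDistribution,
    DonorModel,
    InvalidModelError,
    convolve_irf,
    donor_intensity,
    ensemble_decay,
)
from .structures import StructureModel

#: AEDANS-like donor used as the default in examples and calibration.
DEFAULT_DONOR = DonorModel(components=((1.0, 11.0),))

_BACKBONE = {
    # bond lengths (Å) and angles (deg) of standard peptide geometry
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ang_n_ca_c": 111.2,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
}

#: Ideal alpha-helix dihedrals: ~1.5 Å rise and ~100 deg twist per residue.
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = 180.0, 180.0


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class DecaySimSpec:
    """Specification of one simulated TCSPC decay."""

    donor: DonorModel
    r0: float = 40.0
    dist: DistanceDistribution | None = None  # None -> donor-only decay
    total_counts: int = 1_000_000
    n_channels: int = 1024
    channel_width: float = 0.055  # ns
    irf: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_counts <= 0:
            raise InvalidModelError("total_counts must be positive")
        if self.n_channels < 64:
            raise InvalidModelError("need at least 64 channels")
        if self.channel_width <= 0:
            raise InvalidModelError("channel width must be positive")


def expected_decay(spec: DecaySimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected counts per channel for a simulation spec."""
    t = np.arange(spec.n_channels) * spec.channel_width
    if spec.dist is None:
        model = donor_intensity(t, spec.donor)
    else:
        model = ensemble_decay(t, spec.donor, spec.r0, spec.dist)
        model = model + spec.donor.baseline
    if spec.irf is not None:
        model = convolve_irf(model, np.asarray(spec.irf, dtype=float))
    total = model.sum()
    if total <= 0:
        raise InvalidModelError("expected decay has no intensity")
    expected = model * (spec.total_counts / total)
    if not np.all(np.isfinite(expected)) or expected.max() >= 2**53:
        raise InvalidModelError("expected counts overflow")
    return t, expected


def simulate_decay(spec: DecaySimSpec) -> DecayCurve:
    """Poisson-sample the expected decay; reproducible per seed."""
    t, expected = expected_decay(spec)
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(expected).astype(float)
    return DecayCurve(time=t, counts=counts)


def simulate_decay_pair(
    donor: DonorModel,
    r0: float,
    dist: DistanceDistribution,
    total_counts: int = 1_000_000,
    seed: int = 0,
    **kwargs,
) -> tuple[DecayCurve, DecayCurve]:
    """Matched donor-only and donor–acceptor decays (independent noise)."""
    d_only = simulate_decay(
        DecaySimSpec(donor=donor, r0=r0, dist=None,
                     total_counts=total_counts, seed=seed, **kwargs)
    )
    da = simulate_decay(
        DecaySimSpec(donor=donor, r0=r0, dist=dist,
                     total_counts=total_counts, seed=seed + 1_000_003, **kwargs)
    )
    return d_only, da


# ---------------------------------------------------------------------------
# toy structures


@dataclass(frozen=True)
class ToyStructureSpec:
    """Specification of a toy structure with known geometry."""

    kind: str  # ideal_helix | extended_chain | two_domain_dumbbell
    n_residues: int = 12
    inter_site_distances: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ideal_helix", "extended_chain", "two_domain_dumbbell"):
            raise GeometryError(f"unknown toy structure kind {self.kind!r}")
        if self.n_residues < 2:
            raise GeometryError("need at least 2 residues")


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom d bonded to c."""
    angle = math.radians(angle_deg)
    torsion = -math.radians(torsion_deg)  # IUPAC dihedral sign
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(
    n_residues: int, phi: float, psi: float, chain_id: str = "A"
) -> dict[str, list]:
    """Backbone (N, CA, C, O) chain with constant (phi, psi), omega = 180."""
    g = _BACKBONE
    atoms = {"chain": [], "resnum": [], "resname": [], "name": [], "xyz": []}

    def add(resnum: int, name: str, pos: np.ndarray) -> None:
        atoms["chain"].append(chain_id)
        atoms["resnum"].append(resnum)
        atoms["resname"].append("ALA")
        atoms["name"].append(name)
        atoms["xyz"].append(np.asarray(pos, dtype=float))

    # seed residue 1
    n1 = np.zeros(3)
    ca1 = np.array([g["n_ca"], 0.0, 0.0])
    ang = math.radians(g["ang_n_ca_c"])
    c1 = ca1 + g["ca_c"] * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    add(1, "N", n1)
    add(1, "CA", ca1)
    add(1, "C", c1)

    prev_n, prev_ca, prev_c = n1, ca1, c1
    for res in range(2, n_residues + 1):
        n = _place_atom(prev_n, prev_ca, prev_c, g["c_n"], g["ang_ca_c_n"], psi)
        ca = _place_atom(prev_ca, prev_c, n, g["n_ca"], g["ang_c_n_ca"], 180.0)
        c = _place_atom(prev_c, n, ca, g["ca_c"], g["ang_n_ca_c"], phi)
        # carbonyl O of the previous residue: in the peptide plane, opposite
        # the bisector of the C->N(next) and C->CA bonds (trans to N)
        u1 = (n - prev_c) / np.linalg.norm(n - prev_c)
        u2 = (prev_ca - prev_c) / np.linalg.norm(prev_ca - prev_c)
        bis = -(u1 + u2)
        o_prev = prev_c + g["c_o"] * bis / np.linalg.norm(bis)
        # insert O right after the previous residue's C for a tidy atom order
        add(res - 1, "O", o_prev)
        add(res, "N", n)
        add(res, "CA", ca)
        add(res, "C", c)
        prev_n, prev_ca, prev_c = n, ca, c
    # terminal carbonyl O, placed trans to the last CA-N direction
    o_last = _place_atom(prev_n, prev_ca, prev_c, g["c_o"], g["ang_ca_c_o"], psi + 180.0)
    add(n_residues, "O", o_last)
    return atoms


def _atoms_to_structure(atoms: dict[str, list]) -> StructureModel:
    return StructureModel(
        chains=np.array(atoms["chain"]),
        resnums=np.array(atoms["resnum"], dtype=int),
        resnames=np.array(atoms["resname"]),
        names=np.array(atoms["name"]),
        frames=np.array(atoms["xyz"])[None, :, :],
    )


def make_structure(spec: ToyStructureSpec) -> StructureModel:
    """Build a toy structure with known inter-site geometry.

    ``ideal_helix``: alpha-helical backbone (1.5 Å rise, 100 deg twist per
    residue).  ``extended_chain``: fully extended backbone.
    ``two_domain_dumbbell``: two rigid 5-residue helical clusters (chains A
    and B); ``inter_site_distances`` entries ``(res_a, res_b, d)`` prescribe
    the Calpha separation between chain A residue ``res_a`` and chain B
    residue ``res_b`` — the first entry is satisfied exactly by construction,
    the rest must be consistent with rigid-body placement.
    """
    if spec.kind == "ideal_helix":
        return _atoms_to_structure(
            _build_chain(spec.n_residues, HELIX_PHI, HELIX_PSI)
        )
    if spec.kind == "extended_chain":
        return _atoms_to_structure(
            _build_chain(spec.n_residues, EXTENDED_PHI, EXTENDED_PSI)
        )

    # two_domain_dumbbell
    n_per = max(spec.n_residues // 2, 2)
    a = _build_chain(n_per, HELIX_PHI, HELIX_PSI, chain_id="A")
    b = _build_chain(n_per, HELIX_PHI, HELIX_PSI, chain_id="B")
    pairs = spec.inter_site_distances or ((1, 1, 20.0),)
    res_a, res_b, d0 = pairs[0]
    if d0 <= 0:
        raise GeometryError("prescribed distances must be positive")

    def ca_of(atoms: dict[str, list], resnum: int) -> np.ndarray:
        for rn, name, xyz in zip(atoms["resnum"], atoms["name"], atoms["xyz"]):
            if rn == resnum and name == "CA":
                return xyz
        raise GeometryError(f"no CA for residue {resnum}")

    shift = ca_of(a, res_a) + np.array([d0, 0.0, 0.0]) - ca_of(b, res_b)
    b["xyz"] = [xyz + shift for xyz in b["xyz"]]

    for res_a2, res_b2, d in pairs[1:]:
        actual = float(np.linalg.norm(ca_of(a, res_a2) - ca_of(b, res_b2)))
        if abs(actual - d) > 1e-6:
            raise GeometryError(
                f"prescribed distance A{res_a2}-B{res_b2}={d} Å not realizable "
                f"with rigid clusters (got {actual:.3f} Å)"
            )
    merged = {k: a[k] + b[k] for k in a}
    return _atoms_to_structure(merged)


def make_trajectory(
    base: StructureModel,
    per_residue_sigma: np.ndarray,
    n_frames: int,
    seed: int = 0,
) -> StructureModel:
    """Isotropic Gaussian jitter trajectory around a base structure.

    ``per_residue_sigma`` gives the per-coordinate displacement standard
    deviation (Å) for each residue in order of first appearance; every atom
    of a residue moves independently.  Frame 0 is the unperturbed base.
    """
    sigma = np.asarray(per_residue_sigma, dtype=float)
    if np.any(sigma < 0):
        raise GeometryError("sigma must be nonnegative")
    if n_frames < 1:
        raise GeometryError("need at least one frame")
    # map residues (chain, resnum) to sigma in order of first appearance
    order: dict[tuple[str, int], int] = {}
    for c, r in zip(base.chains, base.resnums):
        order.setdefault((str(c), int(r)), len(order))
    if sigma.size != len(order):
        raise GeometryError(
            f"sigma has {sigma.size} entries for {len(order)} residues"
        )
    atom_sigma = np.array(
        [sigma[order[(str(c), int(r))]] for c, r in zip(base.chains, base.resnums)]
    )
    rng = np.random.default_rng(seed)
    frames = np.repeat(base.coords[None, :, :], n_frames, axis=0)
    noise = rng.normal(size=(n_frames - 1, base.n_atoms, 3))
    frames[1:] += noise * atom_sigma[None, :, None]
    return StructureModel(
        chains=base.chains.copy(),
        resnums=base.resnums.copy(),
        resnames=base.resnames.copy(),
        names=base.names.copy(),
        frames=frames,
    )
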