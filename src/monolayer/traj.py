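"""Descriptors of monolayer molecular-configuration frames.

From-scratch implementations of the standard single/multi-frame
analyses used for monolayer simulations:

* in-plane (xy) 2D radial distribution function between molecular
  centers of mass,
* geometric hydrogen-bond counting (donor–acceptor distance and
  hydrogen–donor–acceptor angle cutoffs),
* per-carbon acyl order parameter ``S_CH = ⟨(3cos²θ − 1)/2⟩`` of C–H
  vectors against the monolayer normal (z),
* mass-density profile along z.

Coordinates are in nm.  The minimal-image convention is applied in x
and y; z is treated as non-periodic by default, matching a monolayer
with water below and vacuum above (``wrap_z=True`` re-enables it).

Atom-name conventions tie annotations to plain coordinate files:
``C<k>`` is chain carbon ``k`` with hydrogens ``H<k>a``/``H<k>b``;
``OD<i>``/``HD<i>`` is a donor oxygen/hydrogen pair and ``OA<i>`` an
acceptor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "RDFResult",
    "HBondStats",
    "OrderProfile",
    "DensityProfile",
    "DEFAULT_MASSES",
    "rdf_2d",
    "hbond_count",
    "order_parameter",
    "density_profile",
]

#: atomic masses (u) keyed by leading element letter of the atom name
DEFAULT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}

_CARBON = re.compile(r"^C(\d+)$")
_HYDROGEN = re.compile(r"^H(\d+)[a-z]$")
_DONOR_O = re.compile(r"^OD(\d+)$")
_DONOR_H = re.compile(r"^HD(\d+)$")
_ACCEPTOR = re.compile(r"^OA(\d+)$")


@dataclass
class Frame:
    """Annotated particle coordinates with a periodic box.

    ``positions`` is (N, 3) in nm; ``box`` the (Lx, Ly, Lz) lengths;
    ``mol_ids`` and ``mol_types`` assign every particle to a molecule.
    """

    positions: np.ndarray
    box: np.ndarray
    mol_ids: np.ndarray
    mol_types: np.ndarray
    atom_names: np.ndarray
    masses: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.mol_types = np.asarray(self.mol_types, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        n = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        for arr, name in ((self.mol_ids, "mol_ids"), (self.mol_types, "mol_types"),
                          (self.atom_names, "atom_names")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per particle")
        if self.masses is None:
            self.masses = self.default_masses()
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise ValueError("masses must have one entry per particle")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def default_masses(self) -> np.ndarray:
        out = np.empty(len(self.atom_names))
        for i, name in enumerate(self.atom_names):
            element = str(name)[0].upper()
            if element not in DEFAULT_MASSES:
                raise ValueError(f"no default mass for atom {name!r}")
            out[i] = DEFAULT_MASSES[element]
        return out

    def molecules(self, mol_type: str | None = None) -> list[np.ndarray]:
        """Index arrays of each molecule, optionally filtered by type."""
        out = []
        for mid in np.unique(self.mol_ids):
            idx = np.nonzero(self.mol_ids == mid)[0]
            if mol_type is None or self.mol_types[idx[0]] == mol_type:
                out.append(idx)
        return out

    def centers_of_mass(self, mol_type: str) -> np.ndarray:
        groups = self.molecules(mol_type)
        if not groups:
            raise ValueError(f"no molecules of type {mol_type!r}")
        return np.array(
            [np.average(self.positions[g], axis=0, weights=self.masses[g]) for g in groups]
        )

    def ch_pairs(self) -> list[tuple[int, int, int]]:
        """(carbon_atom, hydrogen_atom, carbon_index) triples per molecule."""
        pairs = []
        for idx in self.molecules():
            carbons = {}
            for i in idx:
                m = _CARBON.match(str(self.atom_names[i]))
                if m:
                    carbons[int(m.group(1))] = i
            for i in idx:
                m = _HYDROGEN.match(str(self.atom_names[i]))
                if m:
                    k = int(m.group(1))
                    if k in carbons:
                        pairs.append((carbons[k], i, k))
        return pairs

    def donors(self) -> list[tuple[int, int]]:
        """(donor_heavy_atom, bonded_hydrogen) pairs.

        Raises when a donor hydrogen has no matching heavy atom in its
        molecule.
        """
        out = []
        for idx in self.molecules():
            d_heavy = {}
            d_hydro = {}
            for i in idx:
                m = _DONOR_O.match(str(self.atom_names[i]))
                if m:
                    d_heavy[int(m.group(1))] = i
                m = _DONOR_H.match(str(self.atom_names[i]))
                if m:
                    d_hydro[int(m.group(1))] = i
            for k, h in d_hydro.items():
                if k not in d_heavy:
                    raise ValueError(
                        f"donor hydrogen HD{k} has no bonded donor atom in molecule "
                        f"{self.mol_ids[h]}"
                    )
                out.append((d_heavy[k], h))
        return out

    def acceptors(self) -> np.ndarray:
        return np.array(
            [i for i in range(len(self)) if _ACCEPTOR.match(str(self.atom_names[i]))],
            dtype=int,
        )


def minimal_image(vec: np.ndarray, box: np.ndarray, wrap_z: bool = False) -> np.ndarray:
    """Apply the minimal-image convention in x, y (and optionally z)."""
    out = np.array(vec, dtype=float, copy=True)
    dims = (0, 1, 2) if wrap_z else (0, 1)
    for d in dims:
        out[..., d] -= box[d] * np.round(out[..., d] / box[d])
    return out


@dataclass
class RDFResult:
    r: np.ndarray            # bin centers, nm
    g: np.ndarray            # dimensionless
    reference: str
    target: str
    dimensionality: str = "2D-xy"
    bin_width: float = 0.0


def rdf_2d(
    frames: list[Frame],
    reference: str,
    target: str,
    r_max: float = 3.0,
    bin_width: float = 0.02,
) -> RDFResult:
    """In-plane radial distribution function between molecular COMs.

    Pair separations use minimal-image xy distances of the centers of
    mass; g(r) is normalised by the ideal two-dimensional annulus count
    ``N_ref · ρ_target · π(r₂² − r₁²)`` per frame, where
    ``ρ_target = (N_target − δ_same)/(Lx·Ly)`` (the self particle is
    excluded when reference and target selections coincide).
    """
    if not frames:
        raise ValueError("need at least one frame")
    if r_max > min(frames[0].box[0], frames[0].box[1]) / 2:
        raise ValueError("r_max exceeds half the smallest in-plane box length")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    hist = np.zeros(edges.size - 1)
    ideal = np.zeros_like(hist)
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    for fr in frames:
        com_ref = fr.centers_of_mass(reference)
        com_tgt = fr.centers_of_mass(target)
        same = reference == target
        delta = com_tgt[None, :, :2] - com_ref[:, None, :2]
        delta = minimal_image(delta, fr.box)
        dist = np.sqrt((delta**2).sum(axis=-1))
        if same:
            np.fill_diagonal(dist, np.inf)
        hist += np.histogram(dist, bins=edges)[0]
        rho = (com_tgt.shape[0] - (1 if same else 0)) / (fr.box[0] * fr.box[1])
        ideal += com_ref.shape[0] * rho * shell
    centers = 0.5 * (edges[1:] + edges[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    return RDFResult(centers, g, reference, target, bin_width=bin_width)


@dataclass
class HBondStats:
    pair_class: str
    count: int
    per_molecule: float
    d_cut: float
    angle_cut: float
    convention: str = "hda"


def hbond_count(
    frame: Frame,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
    donor_type: str | None = None,
    acceptor_type: str | None = None,
    convention: str = "hda",
    wrap_z: bool = False,
) -> HBondStats:
    """Count geometric hydrogen bonds in one frame.

    A bond is counted when the minimal-image donor–acceptor distance is
    below ``d_cut`` (nm) and the angle criterion is met.  With the
    default ``convention="hda"`` the hydrogen–donor–acceptor angle at
    the donor must be below ``angle_cut`` degrees; ``convention="dha"``
    instead bounds the deviation from linearity of donor–H–acceptor.
    Donor/acceptor selections may be restricted to molecule types; the
    per-molecule mean divides by the number of donor-class molecules.
    """
    if convention not in ("hda", "dha"):
        raise ValueError("convention must be 'hda' or 'dha'")
    donors = frame.donors()
    acceptors = frame.acceptors()
    if donor_type is not None:
        donors = [(d, h) for d, h in donors if frame.mol_types[d] == donor_type]
    if acceptor_type is not None:
        acceptors = acceptors[
            [frame.mol_types[a] == acceptor_type for a in acceptors]
        ] if acceptors.size else acceptors
    count = 0
    cos_cut = np.cos(np.radians(angle_cut))
    for d, h in donors:
        if acceptors.size == 0:
            break
        mask = acceptors != d
        acc = acceptors[mask]
        da = minimal_image(frame.positions[acc] - frame.positions[d], frame.box, wrap_z)
        dist = np.sqrt((da**2).sum(axis=1))
        ok = dist < d_cut
        if not ok.any():
            continue
        if convention == "hda":
            dh = minimal_image(frame.positions[h] - frame.positions[d], frame.box, wrap_z)
            cosang = (da[ok] @ dh) / (dist[ok] * np.linalg.norm(dh))
        else:  # deviation from linear D–H···A at the hydrogen
            ha = minimal_image(frame.positions[acc[ok]] - frame.positions[h], frame.box, wrap_z)
            hd = minimal_image(frame.positions[d] - frame.positions[h], frame.box, wrap_z)
            cos_dev = -(ha @ hd) / (
                np.sqrt((ha**2).sum(axis=1)) * np.linalg.norm(hd)
            )
            cosang = cos_dev
        count += int(np.sum(cosang > cos_cut))
    if donor_type is not None:
        n_ref = len(frame.molecules(donor_type))
    else:
        n_ref = len({frame.mol_ids[d] for d, _ in donors}) or 1
    label = f"{donor_type or 'any'}-{acceptor_type or 'any'}"
    return HBondStats(label, count, count / max(n_ref, 1), d_cut, angle_cut, convention)


@dataclass
class OrderProfile:
    carbon_index: np.ndarray
    s_ch: np.ndarray
    s_ch_abs: np.ndarray   # magnitude, for comparison with |S| conventions
    lipid_type: str


def order_parameter(frames: list[Frame], lipid_type: str) -> OrderProfile:
    """Per-carbon C–H order parameter vs the monolayer normal (z).

    ``S_CH(k) = ⟨(3cos²θ − 1)/2⟩`` over every C–H vector of carbon k in
    every molecule of ``lipid_type`` and every frame.  An all-trans
    chain standing along z has its C–H bonds in the xy plane, giving
    S_CH = −0.5; isotropic orientations give 0.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for fr in frames:
        type_of_mol = {mid: fr.mol_types[np.nonzero(fr.mol_ids == mid)[0][0]]
                       for mid in np.unique(fr.mol_ids)}
        for c, h, k in fr.ch_pairs():
            if type_of_mol[fr.mol_ids[c]] != lipid_type:
                continue
            v = fr.positions[h] - fr.positions[c]
            cos2 = v[2] ** 2 / (v @ v)
            sums[k] = sums.get(k, 0.0) + (3 * cos2 - 1) / 2
            counts[k] = counts.get(k, 0) + 1
    if not sums:
        raise ValueError(f"no C–H pairs found for lipid type {lipid_type!r}")
    ks = np.array(sorted(sums))
    s = np.array([sums[k] / counts[k] for k in ks])
    return OrderProfile(ks, s, np.abs(s), lipid_type)


@dataclass
class DensityProfile:
    z: np.ndarray                    # bin centers, nm
    densities: dict[str, np.ndarray]  # species -> kg/m³
    bin_width: float

#: kg/m³ per (u / nm³)
U_PER_NM3_TO_KG_M3 = 1.66053906660


def density_profile(
    frames: list[Frame], species: list[str], bin_width: float = 0.1
) -> DensityProfile:
    """Mass density along z per species, averaged over frames (kg/m³).

    Bins span [0, Lz]; each particle's mass lands in the bin of its z
    coordinate, divided by the slab volume Lx·Ly·bin and the frame
    count, so the profile integrates back to the species mass in the
    box.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not frames:
        raise ValueError("need at least one frame")
    lz = frames[0].box[2]
    edges = np.arange(0.0, lz + bin_width / 2, bin_width)
    if edges[-1] < lz:
        edges = np.append(edges, lz)
    centers = 0.5 * (edges[1:] + edges[:-1])
    slab_volumes = frames[0].box[0] * frames[0].box[1] * np.diff(edges)
    out = {}
    for sp in species:
        acc = np.zeros(edges.size - 1)
        for fr in frames:
            sel = np.array([t == sp for t in fr.mol_types], dtype=bool)
            if sel.any():
                acc += np.histogram(
                    fr.positions[sel, 2], bins=edges, weights=fr.masses[sel]
                )[0]
        out[sp] = acc / (slab_volumes * len(frames)) * U_PER_NM3_TO_KG_M3
    return DensityProfile(centers, out, bin_width)
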