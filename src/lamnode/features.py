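"""Per-residue structural context: the measurable correlates of mutation effect.

Detectors implemented here are deliberately geometric (no energies):

* disulfide bridges — CYS SG pairs within a distance cutoff, greedily matched
  nearest-first so each cysteine joins at most one bond;
* hydrogen bonds — heavy-atom donor–acceptor distance <= 3.5 Å, with an
  angular check at the donor (D–H···A >= 120° when a hydrogen is present,
  otherwise antecedent–D···A >= 90°);
* inter-chain interfaces — any heavy atom within a contact cutoff (5 Å
  default) of the partner chain;
* solvent accessibility — Shrake–Rupley with a deterministic golden-section
  sphere-point set, relative accessibility against Tien-style maxima;
* N-glycosylation sequons — N-X-[S/T] with X != P, plus heavy-atom proximity
  of any residue to the nearest sequon asparagine;
* hydrophobic-core membership — buried (low relative SASA) apolar residues.

Minimal synthetic scaffolds may lack full side chains, so no detector assumes
one; missing atoms degrade a check gracefully rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model_io import Chain, Residue, StructureModel

__all__ = [
    "HBond",
    "DisulfideBond",
    "Sequon",
    "ResidueFeatureProfile",
    "SasaResult",
    "detect_disulfides",
    "detect_hbonds",
    "interface_residues",
    "sasa",
    "relative_sasa",
    "hydrophobic_core_membership",
    "detect_sequons",
    "sequon_proximity",
    "FeatureExtractor",
    "profile_residue",
    "sphere_points",
    "VDW_RADII",
    "MAX_ASA",
    "HYDROPHOBIC",
]

# ---------------------------------------------------------------------------
# chemistry tables
# ---------------------------------------------------------------------------

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

# Theoretical maximal accessibilities (Tien et al. convention), Å².
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

HYDROPHOBIC = frozenset("AVLIMFWYC")

# Donor atoms: atom name -> antecedent (base) atom used for the angular
# fallback when no hydrogen is present.  Backbone N applies to all residues.
_SIDECHAIN_DONORS = {
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "TRP": {"NE1": "CD1"},
    "CYS": {"SG": "CB"},
}
_BACKBONE_DONOR = {"N": "CA"}

_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
    "CYS": ("SG",),
}
_BACKBONE_ACCEPTORS = ("O", "OXT")

AtomRef = tuple[str, tuple[int, str], str]  # (chain id, residue ref, atom name)
ResRef = tuple[str, tuple[int, str]]  # (chain id, residue ref)


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    angle: Optional[float] = None  # degrees at the donor

    @property
    def donor_residue(self) -> ResRef:
        return (self.donor[0], self.donor[1])

    @property
    def acceptor_residue(self) -> ResRef:
        return (self.acceptor[0], self.acceptor[1])

    @property
    def is_inter_chain(self) -> bool:
        return self.donor[0] != self.acceptor[0]

    def residue_key(self) -> tuple[ResRef, ResRef]:
        """Identity key ignoring exact atoms (donor residue, acceptor residue)."""
        return (self.donor_residue, self.acceptor_residue)


@dataclass(frozen=True)
class DisulfideBond:
    cys_a: ResRef
    cys_b: ResRef
    sg_distance: float

    def involves(self, ref: ResRef) -> bool:
        return ref in (self.cys_a, self.cys_b)


@dataclass(frozen=True)
class Sequon:
    chain_id: str
    asn_position: int
    triplet: str  # 1-letter window, e.g. "NLT"


@dataclass
class ResidueFeatureProfile:
    residue: ResRef
    residue_name: str
    rsa: Optional[float]
    is_interface: bool
    interface_partners: tuple[str, ...]
    inter_chain_hbonds: list[HBond]
    in_disulfide: Optional[DisulfideBond]
    sequon_distance: float  # Å, inf when the chain has no sequon
    is_hydrophobic_core: bool
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _iter_residues(model: StructureModel):
    for chain in model.chains:
        for res in chain.residues:
            yield chain, res


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return 180.0
    cosv = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosv))


# ---------------------------------------------------------------------------
# disulfides
# ---------------------------------------------------------------------------


def detect_disulfides(model: StructureModel, sg_cutoff: float = 2.5) -> list[DisulfideBond]:
    """CYS SG pairs within ``sg_cutoff`` Å, each cysteine in at most one bond.

    Candidate pairs are matched greedily by increasing SG–SG distance, which
    resolves the rare ambiguous cluster deterministically.  Cysteines without
    an SG atom are skipped.
    """
    sgs: list[tuple[ResRef, np.ndarray]] = []
    for chain, res in _iter_residues(model):
        if res.name != "CYS":
            continue
        sg = res.atom("SG")
        if sg is None:
            continue
        sgs.append(((chain.id, res.ref), sg.position))
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= sg_cutoff:
                candidates.append((d, sgs[i][0], sgs[j][0]))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used: set[ResRef] = set()
    bonds = []
    for d, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        bonds.append(DisulfideBond(cys_a=a, cys_b=b, sg_distance=d))
    return bonds


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _donor_atoms(res: Residue) -> list[tuple[str, Optional[str]]]:
    """(donor atom name, base atom name) pairs present in this residue."""
    table = dict(_BACKBONE_DONOR)
    if res.name == "PRO":
        table.pop("N", None)  # proline backbone nitrogen has no H
    table.update(_SIDECHAIN_DONORS.get(res.name, {}))
    out = []
    for donor, base in table.items():
        if res.atom(donor) is not None:
            out.append((donor, base if res.atom(base) is not None else None))
    return out


def _acceptor_atoms(res: Residue) -> list[str]:
    names = [n for n in _BACKBONE_ACCEPTORS if res.atom(n) is not None]
    names += [n for n in _SIDECHAIN_ACCEPTORS.get(res.name, ()) if res.atom(n) is not None]
    return names


def detect_hbonds(
    model: StructureModel,
    max_distance: float = 3.5,
    min_clash_distance: float = 2.4,
    min_angle_with_h: float = 120.0,
    min_base_angle: float = 90.0,
) -> list[HBond]:
    """Geometric hydrogen-bond detection over the whole model.

    Donor and acceptor atoms come from a packaged chemistry table (backbone N
    donates except in proline; backbone O accepts; polar side-chain atoms per
    residue type).  A candidate within ``max_distance`` is accepted when:

    * a hydrogen bound to the donor exists → max D–H···A angle >= 120°;
    * otherwise, if the donor's antecedent heavy atom exists → angle
      antecedent–D···A >= 90°;
    * otherwise (minimal scaffolds) the distance criterion alone decides.

    Pairs closer than ``min_clash_distance`` are treated as covalent/clash
    geometry, and donor/acceptor in the same residue are skipped.
    """
    donors = []  # (atomref, pos, base pos or None, list of H positions, residue index)
    acceptors = []  # (atomref, pos)
    for chain, res in _iter_residues(model):
        if res.is_hetero:
            continue
        hydrogens = [a for a in res.atoms if a.is_hydrogen]
        for donor_name, base_name in _donor_atoms(res):
            datom = res.atom(donor_name)
            attached_h = [
                h.position
                for h in hydrogens
                if np.linalg.norm(h.position - datom.position) <= 1.3
            ]
            base = res.atom(base_name) if base_name else None
            donors.append(
                (
                    (chain.id, res.ref, donor_name),
                    datom.position,
                    base.position if base is not None else None,
                    attached_h,
                )
            )
        for acc_name in _acceptor_atoms(res):
            acceptors.append(((chain.id, res.ref, acc_name), res.atom(acc_name).position))
    if not donors or not acceptors:
        return []
    acc_pos = np.array([p for _, p in acceptors])
    tree = cKDTree(acc_pos)
    bonds = []
    for dref, dpos, bpos, hpositions in donors:
        for j in tree.query_ball_point(dpos, max_distance):
            aref, apos = acceptors[j]
            if (aref[0], aref[1]) == (dref[0], dref[1]):
                continue  # same residue
            dist = float(np.linalg.norm(apos - dpos))
            if dist < min_clash_distance:
                continue
            angle: Optional[float] = None
            if hpositions:
                angle = max(_angle(dpos, h, apos) for h in hpositions)
                if angle < min_angle_with_h:
                    continue
            elif bpos is not None:
                angle = _angle(bpos, dpos, apos)
                if angle < min_base_angle:
                    continue
            bonds.append(HBond(donor=dref, acceptor=aref, distance=dist, angle=angle))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


# ---------------------------------------------------------------------------
# interfaces
# ---------------------------------------------------------------------------


def interface_residues(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    contact_cutoff: float = 5.0,
) -> dict[str, set[tuple[int, str]]]:
    """Residues of each chain with any heavy atom within ``contact_cutoff``
    of the partner chain.  Returns ``{chain_a: set of residue refs, chain_b: ...}``."""
    ca, cb = model.chain(chain_a), model.chain(chain_b)

    def flat(chain: Chain):
        pos, refs = [], []
        for res in chain.residues:
            for atom in res.heavy_atoms():
                pos.append(atom.position)
                refs.append(res.ref)
        return np.array(pos).reshape(-1, 3), refs

    pos_a, refs_a = flat(ca)
    pos_b, refs_b = flat(cb)
    out: dict[str, set[tuple[int, str]]] = {chain_a: set(), chain_b: set()}
    if len(pos_a) == 0 or len(pos_b) == 0:
        return out
    tree_b = cKDTree(pos_b)
    pairs = tree_b.query_ball_point(pos_a, contact_cutoff)
    for ia, hits in enumerate(pairs):
        if hits:
            out[chain_a].add(refs_a[ia])
            for ib in hits:
                out[chain_b].add(refs_b[ib])
    return out


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of ``n`` unit vectors."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    atom_areas: np.ndarray  # Å², aligned with atom_refs
    atom_refs: list[AtomRef]
    residue_areas: dict[ResRef, float]

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's probe-extended sphere is sampled at ``n_points`` deterministic
    golden-section points; the accessible fraction is the share of points not
    buried inside any neighbour's extended sphere.  Hydrogens are excluded by
    default (the maximal-accessibility reference is heavy-atom based).
    Unknown elements fall back to a default radius and are flagged.
    """
    refs: list[AtomRef] = []
    pos: list[np.ndarray] = []
    radii: list[float] = []
    res_of: list[ResRef] = []
    for chain, res in _iter_residues(model):
        for atom in res.atoms:
            if atom.is_hydrogen and not include_hydrogens:
                continue
            refs.append((chain.id, res.ref, atom.name))
            pos.append(atom.position)
            radii.append(VDW_RADII.get(atom.element.upper(), DEFAULT_VDW) + probe_radius)
            res_of.append((chain.id, res.ref))
    if not refs:
        return SasaResult(np.zeros(0), [], {})
    P = np.array(pos)
    R = np.array(radii)
    unit = sphere_points(n_points)
    tree = cKDTree(P)
    areas = np.zeros(len(refs))
    for i in range(len(refs)):
        surf = P[i] + R[i] * unit
        neighbours = [j for j in tree.query_ball_point(P[i], R[i] + R.max()) if j != i]
        if neighbours:
            nb = np.array(neighbours, dtype=int)
            close = nb[np.linalg.norm(P[nb] - P[i], axis=1) < R[i] + R[nb]]
            accessible = np.ones(n_points, dtype=bool)
            for j in close:
                d = np.linalg.norm(surf - P[j], axis=1)
                accessible &= d >= R[j]
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * R[i] ** 2
    residue_areas: dict[ResRef, float] = {}
    for rref, a in zip(res_of, areas):
        residue_areas[rref] = residue_areas.get(rref, 0.0) + float(a)
    return SasaResult(atom_areas=areas, atom_refs=refs, residue_areas=residue_areas)


def relative_sasa(model: StructureModel, sasa_result: Optional[SasaResult] = None) -> dict[ResRef, float]:
    """Per-residue relative accessibility (area / maximal reference area).

    Residues without a tabulated maximum (non-standard) are omitted.  Values
    slightly above 1 occur for extended conformations and are kept as-is.
    """
    sr = sasa_result if sasa_result is not None else sasa(model)
    name_of = {(c.id, r.ref): r.name for c, r in _iter_residues(model)}
    out = {}
    for rref, area in sr.residue_areas.items():
        maxa = MAX_ASA.get(name_of[rref])
        if maxa:
            out[rref] = area / maxa
    return out


def hydrophobic_core_membership(
    model: StructureModel,
    rsa_threshold: float = 0.10,
    residue_set: frozenset[str] = HYDROPHOBIC,
    rsa: Optional[dict[ResRef, float]] = None,
) -> set[ResRef]:
    """Buried apolar residues: relative SASA below threshold, type in set."""
    values = rsa if rsa is not None else relative_sasa(model)
    name_of = {(c.id, r.ref): r for c, r in _iter_residues(model)}
    return {
        rref
        for rref, v in values.items()
        if v < rsa_threshold and name_of[rref].one_letter in residue_set
    }


# ---------------------------------------------------------------------------
# sequons
# ---------------------------------------------------------------------------


def detect_sequons(chain: Chain) -> list[Sequon]:
    """Scan a chain for N-X-[S/T] (X != P) glycosylation sequons.

    The window slides over consecutively numbered residues (author numbering,
    no insertion codes), so chain breaks never yield spurious sequons.
    """
    sequons = []
    res = chain.residues
    for i in range(len(res) - 2):
        r1, r2, r3 = res[i], res[i + 1], res[i + 2]
        if r1.insertion_code or r2.insertion_code or r3.insertion_code:
            continue
        if r2.number != r1.number + 1 or r3.number != r2.number + 1:
            continue
        trip = r1.one_letter + r2.one_letter + r3.one_letter
        if trip[0] == "N" and trip[1] != "P" and trip[2] in "ST":
            sequons.append(Sequon(chain_id=chain.id, asn_position=r1.number, triplet=trip))
    return sequons


def sequon_proximity(
    model: StructureModel,
    residue_ref: ResRef,
    sequons: Optional[Sequence[Sequon]] = None,
) -> float:
    """Minimum heavy-atom distance from a residue to any sequon asparagine
    on the same chain.  The residue being a sequon Asn itself gives 0.
    Returns ``inf`` when the chain carries no sequon."""
    chain_id, (number, icode) = residue_ref
    chain = model.chain(chain_id)
    target = chain.residue(number, icode)
    if target is None:
        raise KeyError(f"chain {chain_id}: no residue {number}{icode}")
    if sequons is None:
        sequons = detect_sequons(chain)
    sequons = [s for s in sequons if s.chain_id == chain_id]
    if not sequons:
        return math.inf
    tc = target.heavy_coords()
    best = math.inf
    for s in sequons:
        asn = chain.residue(s.asn_position)
        if asn is None:
            continue
        ac = asn.heavy_coords()
        if len(tc) == 0 or len(ac) == 0:
            continue
        d = np.linalg.norm(tc[:, None, :] - ac[None, :, :], axis=2).min()
        best = min(best, float(d))
    return best


# ---------------------------------------------------------------------------
# consolidated profiles
# ---------------------------------------------------------------------------


class FeatureExtractor:
    """Computes model-wide feature maps once; per-residue profiles are cheap.

    Thresholds mirror the package defaults: 5 Å interface contact, 3.5 Å
    H-bond, 2.5 Å SG–SG, relative-SASA 0.10 core burial.
    """

    def __init__(
        self,
        model: StructureModel,
        contact_cutoff: float = 5.0,
        hbond_max_distance: float = 3.5,
        sg_cutoff: float = 2.5,
        rsa_core_threshold: float = 0.10,
        sasa_points: int = 960,
    ) -> None:
        self.model = model
        self.contact_cutoff = contact_cutoff
        self.hbonds = detect_hbonds(model, max_distance=hbond_max_distance)
        self.disulfides = detect_disulfides(model, sg_cutoff=sg_cutoff)
        self.sasa = sasa(model, n_points=sasa_points)
        self.rsa = relative_sasa(model, self.sasa)
        self.core = hydrophobic_core_membership(
            model, rsa_threshold=rsa_core_threshold, rsa=self.rsa
        )
        self.sequons = {c.id: detect_sequons(c) for c in model.chains}
        self._interfaces: dict[tuple[str, str], dict[str, set]] = {}
        for i, ca in enumerate(model.chains):
            for cb in model.chains[i + 1:]:
                self._interfaces[(ca.id, cb.id)] = interface_residues(
                    model, ca.id, cb.id, contact_cutoff=contact_cutoff
                )

    def interface_partners(self, ref: ResRef) -> tuple[str, ...]:
        chain_id, rref = ref
        partners = []
        for (a, b), sets in self._interfaces.items():
            if chain_id == a and rref in sets[a]:
                partners.append(b)
            elif chain_id == b and rref in sets[b]:
                partners.append(a)
        return tuple(sorted(partners))

    def profile(self, residue_ref: ResRef) -> ResidueFeatureProfile:
        chain_id, (number, icode) = residue_ref
        chain = self.model.chain(chain_id)
        res = chain.residue(number, icode)
        if res is None:
            raise KeyError(f"chain {chain_id}: no residue {number}{icode}")
        rref = (chain_id, res.ref)
        partners = self.interface_partners(rref)
        inter_hbonds = [
            b
            for b in self.hbonds
            if b.is_inter_chain and rref in (b.donor_residue, b.acceptor_residue)
        ]
        ss = next((b for b in self.disulfides if b.involves(rref)), None)
        seq_dist = sequon_proximity(self.model, rref, self.sequons.get(chain_id, []))
        rsa = self.rsa.get(rref)
        flags = []
        if rsa is not None and rsa > 1.2:
            flags.append("rsa>1.2 (extended conformation)")
        return ResidueFeatureProfile(
            residue=rref,
            residue_name=res.name,
            rsa=rsa,
            is_interface=bool(partners),
            interface_partners=partners,
            inter_chain_hbonds=inter_hbonds,
            in_disulfide=ss,
            sequon_distance=seq_dist,
            is_hydrophobic_core=rref in self.core,
            flags=flags,
        )


def profile_residue(model: StructureModel, residue_ref: ResRef, **kwargs) -> ResidueFeatureProfile:
    """One consolidated profile; convenience wrapper over :class:`FeatureExtractor`."""
    return FeatureExtractor(model, **kwargs).profile(residue_ref)
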