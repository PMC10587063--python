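"""Synthetic multi-chain coordinate fixtures with planted, labeled features.

Every detector in :mod:`lamnode.features` and the four-class rules in
:mod:`lamnode.classifier` are exercised against toy "polymer nodes" built
here: three ideal-geometry chains with a planted inter-chain contact window
and hydrogen bond, a disulfide pair at a set SG–SG distance, an N-X-T sequon
with a nearby probe residue, and a hydrophobic cluster buried under a shell
of glycines.  The scaffolds are chemically implausible by design — no
side-chain rotamers beyond CB, broken covalent continuity where a window is
shifted — which is exactly why detectors must not assume full side chains.

Generation is self-validating: a fixture is audited against its own truth
labels (features re-detected must equal the plants) before it is returned,
and a failed audit raises instead of emitting a misleading fixture.  All
randomness flows from the single recorded seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model_io import Atom, Chain, MutationSpec, Residue, StructureModel

__all__ = [
    "BuildError",
    "SyntheticNodeSpec",
    "make_fragment",
    "build_toy_node",
    "perturb",
    "mutate_fixture",
    "random_rotation",
    "write_fixture",
    "detected_feature_sets",
    "truth_feature_sets",
    "FEATURE_KINDS",
]

# ideal backbone geometry (lengths Å, angles degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}


class BuildError(RuntimeError):
    """An infeasible spec or a fixture that failed its own truth audit."""


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
           angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d given three predecessors, a bond length, the b-c-d
    angle and the a-b-c-d torsion (NeRF construction)."""
    theta, phi = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise BuildError("collinear predecessors in fragment construction")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_fragment(
    kind: str,
    length: int,
    chain_id: str = "A",
    residue_names: Optional[Sequence[str]] = None,
    start_number: int = 1,
) -> Chain:
    """Ideal-geometry backbone fragment (N, CA, C, O, and CB except glycine).

    ``kind`` selects canonical dihedrals: helix (φ=−57°, ψ=−47°) or strand
    (φ=−139°, ψ=135°); ω is trans throughout.
    """
    if length < 3:
        raise BuildError("fragment length must be >= 3")
    if kind not in PHI_PSI:
        raise BuildError(f"unknown fragment kind {kind!r}")
    phi, psi = PHI_PSI[kind]
    names = list(residue_names) if residue_names else ["GLY"] * length
    if len(names) != length:
        raise BuildError("residue_names length mismatch")

    n_pos = [np.zeros(3)]
    ca_pos = [np.array([_B_N_CA, 0.0, 0.0])]
    a0 = math.radians(180.0 - _A_N_CA_C)
    c_pos = [ca_pos[0] + _B_CA_C * np.array([math.cos(a0), math.sin(a0), 0.0])]
    for i in range(1, length):
        n_i = _place(n_pos[-1], ca_pos[-1], c_pos[-1], _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(ca_pos[-1], c_pos[-1], n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = _place(c_pos[-1], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)

    residues = []
    for i in range(length):
        atoms = [
            Atom("N", "N", n_pos[i]),
            Atom("CA", "C", ca_pos[i]),
            Atom("C", "C", c_pos[i]),
            Atom("O", "O", _place(n_pos[i], ca_pos[i], c_pos[i], _B_C_O, _A_CA_C_O, psi - 180.0)),
        ]
        if names[i] != "GLY":
            atoms.append(
                Atom("CB", "C", _place(n_pos[i], c_pos[i], ca_pos[i], _B_CA_CB, 110.6, 122.6))
            )
        residues.append(Residue(number=start_number + i, name=names[i], atoms=atoms))
    chain = Chain(id=chain_id, residues=residues)
    _canonicalize(chain)
    return chain


def _canonicalize(chain: Chain) -> None:
    """Rotate/translate so the CA axis runs along +x through the origin."""
    ca = np.array([r.atom("CA").position for r in chain.residues])
    center = ca.mean(axis=0)
    u, _, _ = np.linalg.svd((ca - center).T @ (ca - center))
    axis = u[:, 0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    # build a right-handed frame with the axis as +x
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    y = np.cross(ref, axis)
    y /= np.linalg.norm(y)
    z = np.cross(axis, y)
    R = np.vstack([axis, y, z])
    for res in chain.residues:
        for atom in res.atoms:
            atom.position = R @ (atom.position - center)


def _translate(residues: Sequence[Residue], shift: np.ndarray) -> None:
    for res in residues:
        for atom in res.atoms:
            atom.position = atom.position + shift


def _all_heavy(chain_or_res) -> np.ndarray:
    if isinstance(chain_or_res, Chain):
        pts = [a.position for r in chain_or_res.residues for a in r.heavy_atoms()]
    else:
        pts = [a.position for a in chain_or_res.heavy_atoms()]
    return np.array(pts).reshape(-1, 3)


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2).min()))


def _residue_template() -> dict[str, np.ndarray]:
    """CA-centred backbone offsets taken from the middle of an ideal strand."""
    frag = make_fragment("strand", 5, residue_names=["ALA"] * 5)
    mid = frag.residues[2]
    ca = mid.atom("CA").position
    return {a.name: a.position - ca for a in mid.atoms}


def _blob_residue(name: str, number: int, ca_position: np.ndarray,
                  rotation: Optional[np.ndarray] = None) -> Residue:
    tmpl = _residue_template()
    atoms = []
    for atom_name, offset in tmpl.items():
        if name == "GLY" and atom_name == "CB":
            continue
        vec = offset if rotation is None else rotation @ offset
        element = atom_name[0]
        atoms.append(Atom(atom_name, element, ca_position + vec))
    return Residue(number=number, name=name, atoms=atoms)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, det corrected)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# the toy polymer node
# ---------------------------------------------------------------------------


@dataclass
class SyntheticNodeSpec:
    """Recipe for one toy node; defaults realise every planted feature.

    Distances are Å.  ``noise_sigma`` jitters all coordinates (per-axis
    Gaussian) to diversify fixtures across seeds; the default plants keep
    >= 0.4 Å margin to every detection threshold so small jitter never flips
    a label.
    """

    seed: int = 0
    n_chains: int = 3
    composition: tuple[str, ...] = ("alpha1", "beta1", "gamma1")
    chain_length: int = 30
    interface_window: tuple[int, int] = (5, 8)  # residue numbers, inclusive
    interface_gap: float = 4.5  # target min heavy-atom distance A<->B window
    far_gap: float = 12.0
    disulfide_pair: tuple[int, int] = (12, 14)
    sg_distance: float = 2.05
    sequon_start: int = 20  # N-X-T at 20..22
    sequon_probe: int = 18
    hbond_length: float = 2.9
    core_residues: tuple[int, ...] = (41, 42, 43, 44)
    core_radius: float = 2.2
    shell_count: int = 48
    shell_radius: float = 6.2
    noise_sigma: float = 0.0
    rigid_transform: Optional[tuple[np.ndarray, np.ndarray]] = None
    audit: bool = True

    def validate(self) -> None:
        w0, w1 = self.interface_window
        strand = set(range(1, self.chain_length + 1))
        planted = [w0, w1, *self.disulfide_pair, self.sequon_probe,
                   self.sequon_start, self.sequon_start + 2]
        if not all(p in strand for p in planted):
            raise BuildError("planted strand positions fall outside the chain")
        regions = [
            set(range(w0, w1 + 1)),
            set(self.disulfide_pair),
            set(range(self.sequon_probe, self.sequon_start + 3)),
        ]
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if regions[i] & regions[j]:
                    raise BuildError("planted features overlap on the chain")
        if set(self.core_residues) & strand:
            raise BuildError("core residue numbers must sit outside the strand range")
        if self.n_chains not in (2, 3):
            raise BuildError("n_chains must be 2 or 3")
        if len(self.composition) < self.n_chains:
            raise BuildError("composition must name every chain")


def build_toy_node(spec: SyntheticNodeSpec) -> tuple[StructureModel, dict]:
    """Build the toy node and its truth labels; audits itself before returning.

    Truth labels record the planted interface residues (both chains, computed
    from the realised coordinates with the 5 Å convention), the disulfide
    pair, sequon position, probe distance, buried core members, the planted
    inter-chain H-bond, and one intended mutation per mechanistic class.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w0, w1 = spec.interface_window
    L = spec.chain_length

    names_a = ["GLY"] * L
    names_a[w0 - 1] = "TYR"  # class-1 site, inter-chain H-bond donor
    for p in spec.disulfide_pair:
        names_a[p - 1] = "CYS"
    names_a[spec.sequon_probe - 1] = "SER"  # class-2 site
    names_a[spec.sequon_start - 1] = "ASN"
    names_a[spec.sequon_start + 1] = "THR"

    chain_a = make_fragment("strand", L, chain_id="A", residue_names=names_a)
    chain_b = make_fragment("strand", L, chain_id="B", residue_names=["GLY"] * L)
    _translate(chain_b.residues, np.array([0.0, spec.far_gap, 0.0]))

    # bring the window residues of B to the target minimum distance from A
    window_res = [r for r in chain_b.residues if w0 <= r.number <= w1]
    pts_a = _all_heavy(chain_a)
    pts_w = np.vstack([_all_heavy(r) for r in window_res])

    def min_at(dy: float) -> float:
        return _min_dist(pts_w + np.array([0.0, dy, 0.0]), pts_a)

    lo, hi = -spec.far_gap, 0.0
    if not (min_at(lo) <= spec.interface_gap <= min_at(hi)):
        raise BuildError("interface gap not bracketed; adjust far_gap")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_at(mid) < spec.interface_gap:
            lo = mid
        else:
            hi = mid
    _translate(window_res, np.array([0.0, 0.5 * (lo + hi), 0.0]))

    # disulfide: SG atoms midway between the two CB atoms, sg_distance apart
    r1 = chain_a.residue(spec.disulfide_pair[0])
    r2 = chain_a.residue(spec.disulfide_pair[1])
    cb1, cb2 = r1.atom("CB").position, r2.atom("CB").position
    axis = (cb2 - cb1) / np.linalg.norm(cb2 - cb1)
    midpoint = 0.5 * (cb1 + cb2)
    r1.atoms.append(Atom("SG", "S", midpoint - 0.5 * spec.sg_distance * axis))
    r2.atoms.append(Atom("SG", "S", midpoint + 0.5 * spec.sg_distance * axis))

    # planted inter-chain hydrogen bond: TYR OH pointing at a window O of B.
    # The OH must stay clear (> 3.6 Å) of every other B heavy atom so the
    # bond to the chosen acceptor is the only inter-chain bond; search a few
    # deterministic directions in the gap for a placement that satisfies it.
    donor_res = chain_a.residue(w0)
    acceptor_res = chain_b.residue(w0)
    o_acc = acceptor_res.atom("O").position
    cb_don = donor_res.atom("CB").position
    other_b = np.array([
        a.position
        for r in chain_b.residues
        for a in r.heavy_atoms()
        if not (r.number == w0 and a.name == "O")
    ])

    def _unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    u0 = _unit(cb_don - o_acc)
    nearest_other = other_b[np.linalg.norm(other_b - o_acc, axis=1).argmin()]
    v0 = _unit(o_acc - nearest_other)
    oh = None
    for a_w, b_w in ((1.0, 0.0), (1.0, 0.5), (1.0, 1.0), (0.5, 1.0), (1.0, 2.0)):
        cand = o_acc + spec.hbond_length * _unit(a_w * u0 + b_w * v0)
        if np.linalg.norm(other_b - cand, axis=1).min() > 3.6:
            oh = cand
            break
    if oh is None:
        raise BuildError("cannot place the planted H-bond donor clear of chain B")
    donor_res.atoms.append(Atom("OH", "O", oh))

    # buried hydrophobic cluster under a glycine shell, hung off chain A
    span = pts_a[:, 0]
    center = np.array([0.5 * (span.min() + span.max()), -(spec.shell_radius + 12.0), 0.0])
    tetra = np.array([
        [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
    ]) / math.sqrt(3.0)
    core_rot = random_rotation(rng)
    for k, number in enumerate(spec.core_residues):
        ca = center + spec.core_radius * (core_rot @ tetra[k % 4])
        chain_a.residues.append(_blob_residue("LEU", number, ca, rotation=core_rot))
    shell_start = max(spec.core_residues) + 7
    from .features import sphere_points

    for k, u in enumerate(sphere_points(spec.shell_count)):
        ca = center + spec.shell_radius * u
        chain_a.residues.append(
            _blob_residue("GLY", shell_start + k, ca, rotation=random_rotation(rng))
        )

    chains = [chain_a, chain_b]
    if spec.n_chains == 3:
        chain_c = make_fragment("strand", max(3, L - 10), chain_id="C",
                                residue_names=["GLY"] * max(3, L - 10))
        _translate(chain_c.residues, np.array([0.0, spec.far_gap + 16.0, 0.0]))
        chains.append(chain_c)
    for chain, label in zip(chains, spec.composition):
        chain.subunit_label = label

    model = StructureModel(
        model_id=f"toy-node-seed{spec.seed}", chains=chains, source_kind="synthetic"
    )
    if spec.noise_sigma > 0:
        _jitter(model, spec.noise_sigma, rng)
    if spec.rigid_transform is not None:
        R, t = spec.rigid_transform
        for _, res in _iter_model(model):
            for atom in res.atoms:
                atom.position = R @ atom.position + t

    truth = _truth_labels(model, spec)
    if spec.audit:
        _audit(model, spec, truth)
    return model, truth


def _iter_model(model: StructureModel):
    for chain in model.chains:
        for res in chain.residues:
            yield chain, res


def _jitter(model: StructureModel, sigma: float, rng: np.random.Generator) -> None:
    for _, res in _iter_model(model):
        for atom in res.atoms:
            atom.position = atom.position + rng.normal(0.0, sigma, 3)


def _truth_labels(model: StructureModel, spec: SyntheticNodeSpec) -> dict:
    """Planted truth, with the realised interface sets recomputed by direct
    O(n²) distance arithmetic (independent of the detectors' spatial index)."""
    w0, w1 = spec.interface_window
    chain_a, chain_b = model.chain("A"), model.chain("B")
    contact = 5.0
    pts_b = np.vstack([
        _all_heavy(r) for r in chain_b.residues if w0 <= r.number <= w1
    ])
    iface_a = sorted(
        r.number for r in chain_a.residues if _min_dist(_all_heavy(r), pts_b) <= contact
    )
    pts_a = _all_heavy(chain_a)
    iface_b = sorted(
        r.number for r in chain_b.residues if _min_dist(_all_heavy(r), pts_a) <= contact
    )
    probe = chain_a.residue(spec.sequon_probe)
    asn = chain_a.residue(spec.sequon_start)
    probe_distance = _min_dist(_all_heavy(probe), _all_heavy(asn))
    label = spec.composition[0]
    comp3 = tuple(spec.composition[:3]) if len(spec.composition) >= 3 else ()
    mutations = {
        1: MutationSpec(label, w0, "Y", "H", comp3),
        2: MutationSpec(label, spec.sequon_probe, "S", "F", comp3),
        3: MutationSpec(label, spec.disulfide_pair[0], "C", "R", comp3),
        4: MutationSpec(label, spec.core_residues[0], "L", "P", comp3),
    }
    return {
        "seed": spec.seed,
        "model_id": model.model_id,
        "interface": {"chains": ["A", "B"], "A": iface_a, "B": iface_b},
        "disulfides": [[["A", spec.disulfide_pair[0]], ["A", spec.disulfide_pair[1]]]],
        "sequons": [["A", spec.sequon_start]],
        "sequon_probe": {"residue": ["A", spec.sequon_probe], "distance": probe_distance},
        "core": [["A", n] for n in spec.core_residues],
        "inter_chain_hbonds": [[["A", w0], ["B", w0]]],
        "class_sites": {str(k): ["A", m.position] for k, m in mutations.items()},
        "mutations": mutations,
    }


FEATURE_KINDS = ("interface", "disulfide", "sequon", "core", "inter_chain_hbond")


def detected_feature_sets(model: StructureModel, extractor=None) -> dict[str, set]:
    """Run every detector and collapse the results to comparable key sets.

    Keys: interface residues as (chain, number); disulfides and inter-chain
    H-bonds as order-free residue pairs; sequons as (chain, Asn number);
    core members as (chain, number).
    """
    from . import features as F

    ex = extractor if extractor is not None else F.FeatureExtractor(model)
    sets: dict[str, set] = {k: set() for k in FEATURE_KINDS}
    for i, ca in enumerate(model.chains):
        for cb in model.chains[i + 1:]:
            iface = F.interface_residues(model, ca.id, cb.id)
            for cid in (ca.id, cb.id):
                sets["interface"].update((cid, n) for n, _ in iface[cid])
    sets["disulfide"] = {
        tuple(sorted(((b.cys_a[0], b.cys_a[1][0]), (b.cys_b[0], b.cys_b[1][0]))))
        for b in ex.disulfides
    }
    sets["sequon"] = {
        (s.chain_id, s.asn_position) for c in model.chains for s in ex.sequons[c.id]
    }
    sets["core"] = {(c, n) for c, (n, _) in ex.core}
    sets["inter_chain_hbond"] = {
        tuple(sorted(((b.donor[0], b.donor[1][0]), (b.acceptor[0], b.acceptor[1][0]))))
        for b in ex.hbonds
        if b.is_inter_chain
    }
    return sets


def truth_feature_sets(truth: dict) -> dict[str, set]:
    """The planted truth in the same key convention as the detectors."""
    sets: dict[str, set] = {k: set() for k in FEATURE_KINDS}
    for cid in truth["interface"]["chains"]:
        sets["interface"].update((cid, n) for n in truth["interface"][cid])
    sets["disulfide"] = {
        tuple(sorted(((c1, n1), (c2, n2)))) for (c1, n1), (c2, n2) in truth["disulfides"]
    }
    sets["sequon"] = {(c, n) for c, n in truth["sequons"]}
    sets["core"] = {(c, n) for c, n in truth["core"]}
    sets["inter_chain_hbond"] = {
        tuple(sorted(((c1, n1), (c2, n2))))
        for (c1, n1), (c2, n2) in truth["inter_chain_hbonds"]
    }
    return sets


def _audit(model: StructureModel, spec: SyntheticNodeSpec, truth: dict) -> None:
    from . import features as F
    from .classifier import assign_class

    ex = F.FeatureExtractor(model)
    detected = detected_feature_sets(model, extractor=ex)
    planted = truth_feature_sets(truth)
    for kind in FEATURE_KINDS:
        if detected[kind] != planted[kind]:
            raise BuildError(
                f"{kind} audit failed: detected {detected[kind]} != planted {planted[kind]}"
            )
    for klass, mutation in truth["mutations"].items():
        chain = model.chain_by_subunit(mutation.subunit_label)
        profile = ex.profile((chain.id, (mutation.position, "")))
        got = assign_class(profile, mutation).assigned_class
        if got != klass:
            raise BuildError(
                f"class audit failed at {mutation.label}: assigned {got}, planted {klass}"
            )


# ---------------------------------------------------------------------------
# perturbation and mutant fixtures
# ---------------------------------------------------------------------------


def perturb(model: StructureModel, noise_sigma: float, seed: int) -> StructureModel:
    """I.i.d. Gaussian displacement of every atom coordinate; seed-reproducible."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    out = model.copy()
    out.model_id = f"{model.model_id}-perturbed"
    if noise_sigma == 0:
        return out
    _jitter(out, noise_sigma, np.random.default_rng(seed))
    return out


_STRIP_KEEP = {"N", "CA", "C", "O", "CB", "OXT"}


def mutate_fixture(model: StructureModel, mutation: MutationSpec,
                   mode: str = "rename_strip") -> StructureModel:
    """Mutant counterpart of a fixture: rename the residue, strip beyond CB.

    No rotamer is built — the mutant fixture only needs to *lack* whatever
    the wild-type side chain provided (an SG, a donor OH, ...).
    """
    if mode != "rename_strip":
        raise ValueError(f"unknown mode {mode!r}")
    out = model.copy()
    out.model_id = f"{model.model_id}-{mutation.label}"
    chain = out.chain_by_subunit(mutation.subunit_label)
    res = chain.residue(mutation.position)
    if res is None:
        raise ValueError(f"no residue {mutation.position} on {mutation.subunit_label}")
    if res.one_letter != mutation.wt_aa:
        raise ValueError(
            f"wild-type mismatch: fixture has {res.name}, mutation expects {mutation.wt_aa}"
        )
    from .model_io import _ONE_TO_THREE  # standard 1->3 table

    res.name = _ONE_TO_THREE.get(mutation.mut_aa, "UNK")
    res.atoms = [a for a in res.atoms if a.name in _STRIP_KEEP]
    if res.name == "GLY":
        res.atoms = [a for a in res.atoms if a.name != "CB"]
    return out


def write_fixture(model: StructureModel, truth: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write fixture coordinates (PDB) and truth labels (sidecar JSON).

    Labels stay out of the coordinate file so classification code remains
    blind to them.
    """
    from .model_io import write_pdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_path = out / f"{model.model_id}.pdb"
    json_path = out / f"{model.model_id}.truth.json"
    write_pdb(model, pdb_path)
    serializable = {
        k: (
            {c: asdict(m) for c, m in v.items()} if k == "mutations" else v
        )
        for k, v in truth.items()
    }
    json_path.write_text(json.dumps(serializable, indent=2, default=str))
    return pdb_path, json_path
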