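"""Coordinate-file I/O, mutation-catalog parsing and the study manifest.

Atomic models come in as PDB or mmCIF (parsed with :mod:`gemmi`) and are held
in a small chain/residue/atom hierarchy that downstream geometry code can
consume without caring about the source format.  Laminin-specific metadata —
which laminin subunit a chain corresponds to (alpha1 ... gamma1), whether a
model is experimental or computed, the per-atom confidence channel that
predicted-structure deposits store in the B-factor column — lives on the same
objects.

The mutation catalog uses the compact construct notation of the laminin
literature, e.g. ``α2(C83R)β1γ1``: a trimeric polymer node of one alpha, one
beta and one gamma short arm, with the parenthesised substitution sitting on
whichever subunit precedes it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "MutationSpec",
    "CatalogEntry",
    "NodeManifest",
    "PLDDTProfile",
    "ParseError",
    "PairingError",
    "SUBUNIT_LABELS",
    "parse_structure",
    "write_pdb",
    "write_mmcif",
    "parse_mutation_notation",
    "format_mutation",
    "load_catalog",
    "build_manifest",
    "map_residues",
    "plddt_profile",
    "tag_subunits",
    "three_to_one",
]

SUBUNIT_LABELS = (
    "alpha1",
    "alpha2",
    "alpha5",
    "beta1",
    "beta2",
    "beta3",
    "gamma1",
)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

_ONE_TO_THREE = {v: k for k, v in reversed(list(_THREE_TO_ONE.items()))}


class ParseError(ValueError):
    """Raised when a coordinate file or a mutation token cannot be parsed."""


class PairingError(ValueError):
    """Raised when two models cannot be brought into residue correspondence."""


def three_to_one(name: str) -> str:
    """1-letter code for a 3-letter residue name; ``X`` for non-standard."""
    return _THREE_TO_ONE.get(name.upper(), "X")


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    confidence: float = 0.0  # B-factor channel; pLDDT for computed models
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        self.is_hydrogen = self.element.upper() in ("H", "D")


@dataclass
class Residue:
    number: int
    name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)

    @property
    def ref(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.heavy_atoms()], dtype=float).reshape(-1, 3)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    subunit_label: Optional[str] = None

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue(self, number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    model_id: str
    chains: list[Chain] = field(default_factory=list)
    source_kind: str = "experimental"  # experimental | computed | synthetic

    def __post_init__(self) -> None:
        if self.source_kind not in ("experimental", "computed", "synthetic"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"model {self.model_id}: no chain {chain_id!r}")

    def chain_by_subunit(self, label: str) -> Chain:
        for c in self.chains:
            if c.subunit_label == label:
                return c
        raise KeyError(f"model {self.model_id}: no chain tagged {label!r}")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def copy(self) -> "StructureModel":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# structure parsing / writing
# ---------------------------------------------------------------------------

_WATERS = {"HOH", "WAT", "DOD", "H2O"}


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter, alphabetically
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def _from_gemmi(st: gemmi.Structure, model_id: str, source_kind: str) -> StructureModel:
    if len(st) == 0:
        raise ParseError(f"{model_id}: no atoms (empty coordinate section)")
    st.setup_entities()
    gm = st[0]  # multi-model files: first model
    chains: list[Chain] = []
    for gchain in gm:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in _WATERS:
                continue
            is_het = gres.het_flag == "H" and gres.name not in _THREE_TO_ONE
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, alts in by_name.items():
                ga = _best_altloc(alts)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name or "X",
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        confidence=ga.b_iso,
                    )
                )
            if not atoms:
                continue
            residues.append(
                Residue(
                    number=gres.seqid.num,
                    name=gres.name,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    atoms=atoms,
                    is_hetero=is_het,
                )
            )
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    model = StructureModel(model_id=model_id, chains=chains, source_kind=source_kind)
    if model.n_atoms() == 0:
        raise ParseError(f"{model_id}: no atoms (empty coordinate section)")
    return model


def _sniff_format(text: str) -> str:
    head = text.lstrip()[:4000]
    if head.startswith("data_") or "_atom_site." in head or "loop_" in head.split("\n", 1)[0]:
        return "mmcif"
    return "pdb"


def parse_structure(
    source: str | Path,
    fmt: str = "auto",
    model_id: Optional[str] = None,
    source_kind: str = "experimental",
) -> StructureModel:
    """Parse a PDB or mmCIF file (or raw text) into a :class:`StructureModel`.

    ``source`` may be a path or the file content itself.  Waters are dropped;
    other heteroatoms are kept with ``Residue.is_hetero`` set.  Alternate
    locations collapse to the highest-occupancy conformer (ties: alphabetical
    altloc).  Multi-model files yield the first model.
    """
    path: Optional[Path] = None
    text: Optional[str] = None
    src = str(source)
    if "\n" in src or src.lstrip().startswith(("ATOM", "HETATM", "data_", "HEADER", "CRYST1", "MODEL")):
        text = src
    else:
        path = Path(src)
        if not path.exists():
            raise ParseError(f"no such coordinate file: {path}")
        text = path.read_text()
    if fmt == "auto":
        if path is not None and path.suffix.lower() in (".cif", ".mmcif"):
            fmt = "mmcif"
        elif path is not None and path.suffix.lower() in (".pdb", ".ent"):
            fmt = "pdb"
        else:
            fmt = _sniff_format(text)
    name = model_id or (path.stem if path is not None else "model")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{name}: cannot parse as {fmt}: {exc}") from exc
    return _from_gemmi(st, name, source_kind)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gr.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.confidence
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path: str | Path) -> None:
    _to_gemmi(model).write_pdb(str(path))


def write_mmcif(model: StructureModel, path: str | Path) -> None:
    _to_gemmi(model).make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# mutation notation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationSpec:
    subunit_label: str
    position: int
    wt_aa: str
    mut_aa: str
    node_composition: tuple[str, str, str] = ()
    ddg_annotation: Optional[float] = None  # kcal/mol, carried only

    def __post_init__(self) -> None:
        if self.subunit_label not in SUBUNIT_LABELS:
            raise ValueError(f"unknown subunit {self.subunit_label!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.wt_aa == self.mut_aa:
            raise ValueError("wild-type and mutant residue must differ")
        if self.node_composition:
            classes = sorted(s[0] for s in self.node_composition)
            if len(self.node_composition) != 3 or classes != ["a", "b", "g"]:
                raise ValueError(
                    "node composition must contain exactly one alpha, one beta, one gamma"
                )

    @property
    def label(self) -> str:
        return f"{self.subunit_label}({self.wt_aa}{self.position}{self.mut_aa})"


_GREEK = {"α": "alpha", "β": "beta", "γ": "gamma", "a": "alpha", "b": "beta", "g": "gamma"}
_TO_GREEK = {"alpha": "α", "beta": "β", "gamma": "γ"}

_SLOT_RE = re.compile(
    r"(?P<class>α|β|γ|alpha|beta|gamma|[abg])"
    r"(?P<iso>\d)"
    r"(?:\((?P<wt>[A-Z])(?P<pos>\d+)/?(?P<mut>[A-Z])\))?",
)


def parse_mutation_notation(text: str) -> tuple[tuple[str, str, str], Optional[MutationSpec]]:
    """Parse a construct token like ``α2(C83R)β1γ1`` or ``a5b2(Y48S)g1``.

    Returns the node composition (three subunit tags, in the order written)
    and the :class:`MutationSpec`, or ``None`` for a wild-type node.  The
    altered subunit may sit in any of the three slots; a slash form like
    ``S179/F`` is tolerated.
    """
    compact = re.sub(r"\s+", "", text)
    slots: list[tuple[str, Optional[tuple[str, int, str]]]] = []
    pos = 0
    while pos < len(compact):
        m = _SLOT_RE.match(compact, pos)
        if m is None:
            raise ParseError(
                f"malformed construct token {text!r}: cannot parse at {compact[pos:]!r}"
            )
        label = _GREEK[m.group("class")] + m.group("iso")
        if label not in SUBUNIT_LABELS:
            raise ParseError(f"unknown subunit {label!r} in {text!r}")
        sub = None
        if m.group("wt") is not None:
            sub = (m.group("wt"), int(m.group("pos")), m.group("mut"))
        slots.append((label, sub))
        pos = m.end()
    if len(slots) != 3:
        raise ParseError(f"expected three subunits in {text!r}, found {len(slots)}")
    composition = tuple(label for label, _ in slots)
    mutated = [(label, sub) for label, sub in slots if sub is not None]
    if len(mutated) > 1:
        raise ParseError(f"multiple parenthesised mutations in {text!r} are unsupported")
    if not mutated:
        return composition, None
    label, (wt, position, mut) = mutated[0]
    spec = MutationSpec(
        subunit_label=label,
        position=position,
        wt_aa=wt,
        mut_aa=mut,
        node_composition=composition,
    )
    return composition, spec


def format_mutation(spec: MutationSpec, greek: bool = True) -> str:
    """Inverse of :func:`parse_mutation_notation` for a mutant trimer."""
    parts = []
    for label in spec.node_composition or (spec.subunit_label,):
        stem, iso = label[:-1], label[-1]
        name = (_TO_GREEK[stem] if greek else stem[0]) + iso
        if label == spec.subunit_label:
            name += f"({spec.wt_aa}{spec.position}{spec.mut_aa})"
        parts.append(name)
    return "".join(parts)


# ---------------------------------------------------------------------------
# catalog and manifest
# ---------------------------------------------------------------------------


@dataclass
class CatalogEntry:
    """One catalog row: the spec plus evaluation-only annotations.

    ``paper_class`` is the transcribed literature label; it is consumed
    exclusively by the evaluation harness, never by the classifier.
    """

    spec: MutationSpec
    disease: str = ""
    paper_class: Optional[int] = None
    model_key: Optional[str] = None


def load_catalog(path: str | Path) -> list[CatalogEntry]:
    """Read the mutation catalog TSV (subunit, position, wt, mut, node, ...)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        composition, _ = parse_mutation_notation(row["node"])
        spec = MutationSpec(
            subunit_label=row["subunit"],
            position=int(row["position"]),
            wt_aa=row["wt"],
            mut_aa=row["mut"],
            node_composition=composition,
        )
        label = row.get("class_label_from_paper", "")
        entries.append(
            CatalogEntry(
                spec=spec,
                disease=row.get("disease", ""),
                paper_class=int(label) if label else None,
            )
        )
    return entries


@dataclass
class NodeManifest:
    wt_monomers: list[str]
    mutant_monomers: list[MutationSpec]
    wt_trimers: list[tuple[str, str, str]]
    mutant_trimers: list[MutationSpec]

    @property
    def n_monomers(self) -> int:
        return len(self.wt_monomers) + len(self.mutant_monomers)

    @property
    def n_trimers(self) -> int:
        return len(self.wt_trimers) + len(self.mutant_trimers)

    @property
    def total(self) -> int:
        return self.n_monomers + self.n_trimers

    def counts(self) -> dict[str, int]:
        return {
            "wt_monomers": len(self.wt_monomers),
            "mutant_monomers": len(self.mutant_monomers),
            "wt_trimers": len(self.wt_trimers),
            "mutant_trimers": len(self.mutant_trimers),
            "monomers": self.n_monomers,
            "trimers": self.n_trimers,
            "total": self.total,
        }


def build_manifest(
    catalog: Sequence[MutationSpec | CatalogEntry],
    wt_subunits: Sequence[str],
    wt_trimers: Sequence[tuple[str, str, str] | str],
) -> NodeManifest:
    """Enumerate the modelling campaign implied by a catalog.

    Each catalog mutation contributes one mutant monomer and one mutant
    trimer; wild-type subunits and trimer compositions are modelled once.
    """
    specs = [e.spec if isinstance(e, CatalogEntry) else e for e in catalog]
    seen: set[tuple] = set()
    for s in specs:
        key = (s.subunit_label, s.position, s.wt_aa, s.mut_aa, s.node_composition)
        if key in seen:
            raise ValueError(f"duplicate catalog mutation {s.label}")
        seen.add(key)
    trimers = []
    for t in wt_trimers:
        comp = parse_mutation_notation(t)[0] if isinstance(t, str) else tuple(t)
        trimers.append(comp)
    return NodeManifest(
        wt_monomers=list(wt_subunits),
        mutant_monomers=list(specs),
        wt_trimers=trimers,
        mutant_trimers=list(specs),
    )


# ---------------------------------------------------------------------------
# residue correspondence
# ---------------------------------------------------------------------------

ResiduePair = tuple[tuple[str, Residue], tuple[str, Residue]]


def _chain_pairs(model_a: StructureModel, model_b: StructureModel) -> list[tuple[Chain, Chain]]:
    pairs = []
    labelled_a = {c.subunit_label: c for c in model_a.chains if c.subunit_label}
    labelled_b = {c.subunit_label: c for c in model_b.chains if c.subunit_label}
    shared = [k for k in labelled_a if k in labelled_b]
    if shared:
        return [(labelled_a[k], labelled_b[k]) for k in shared]
    by_id_b = {c.id: c for c in model_b.chains}
    pairs = [(c, by_id_b[c.id]) for c in model_a.chains if c.id in by_id_b]
    if not pairs:
        raise PairingError(
            f"{model_a.model_id} vs {model_b.model_id}: no chains share a subunit label or id"
        )
    return pairs


def map_residues(
    model_a: StructureModel,
    model_b: StructureModel,
    pairing: str = "by_number",
) -> tuple[list[ResiduePair], list[tuple[str, Residue]], list[tuple[str, Residue]]]:
    """1:1 residue correspondences between two models.

    Chains are matched by subunit label when both models are tagged, else by
    chain id.  ``by_number`` pairs residues sharing (number, insertion code);
    ``by_alignment`` pairs them through a global sequence alignment, which
    tolerates numbering offsets.  Returns (pairs, unpaired_a, unpaired_b).
    """
    pairs: list[ResiduePair] = []
    un_a: list[tuple[str, Residue]] = []
    un_b: list[tuple[str, Residue]] = []
    for ca, cb in _chain_pairs(model_a, model_b):
        if pairing == "by_number":
            index_b = {r.ref: r for r in cb.residues}
            matched_b = set()
            for ra in ca.residues:
                rb = index_b.get(ra.ref)
                if rb is not None:
                    pairs.append(((ca.id, ra), (cb.id, rb)))
                    matched_b.add(rb.ref)
                else:
                    un_a.append((ca.id, ra))
            un_b.extend((cb.id, r) for r in cb.residues if r.ref not in matched_b)
        elif pairing == "by_alignment":
            from .conservation import global_align

            aln = global_align(ca.sequence, cb.sequence)
            ia = ib = 0
            matched_a: set[tuple[int, str]] = set()
            matched_b = set()
            for col_a, col_b in zip(aln.aligned_a, aln.aligned_b):
                if col_a != "-" and col_b != "-":
                    ra, rb = ca.residues[ia], cb.residues[ib]
                    pairs.append(((ca.id, ra), (cb.id, rb)))
                    matched_a.add(ra.ref)
                    matched_b.add(rb.ref)
                if col_a != "-":
                    ia += 1
                if col_b != "-":
                    ib += 1
            un_a.extend((ca.id, r) for r in ca.residues if r.ref not in matched_a)
            un_b.extend((cb.id, r) for r in cb.residues if r.ref not in matched_b)
        else:
            raise ValueError(f"unknown pairing mode {pairing!r}")
    return pairs, un_a, un_b


# ---------------------------------------------------------------------------
# pLDDT
# ---------------------------------------------------------------------------


@dataclass
class PLDDTProfile:
    chain_id: str
    values: np.ndarray  # per residue, 0-100

    @property
    def baseline(self) -> float:
        return float(np.median(self.values))


def plddt_profile(model: StructureModel) -> list[PLDDTProfile]:
    """Per-residue confidence profiles for a computed (predicted) model.

    The representative value is the CA confidence (first atom if no CA).
    Experimental models are refused: their B-factor column holds atomic
    displacement parameters, not pLDDT.
    """
    if model.source_kind == "experimental":
        raise ValueError(
            f"{model.model_id} is experimental: its B-factor column is not a pLDDT channel"
        )
    profiles = []
    for chain in model.chains:
        values = []
        for res in chain.residues:
            rep = res.atom("CA") or res.atoms[0]
            values.append(rep.confidence)
        arr = np.asarray(values, dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 100):
            raise ValueError(f"chain {chain.id}: confidence values outside [0, 100]")
        profiles.append(PLDDTProfile(chain_id=chain.id, values=arr))
    return profiles


# ---------------------------------------------------------------------------
# subunit tagging
# ---------------------------------------------------------------------------


def tag_subunits(
    model: StructureModel,
    mapping: Optional[Mapping[str, str]] = None,
    reference_fasta: Optional[str | Path] = None,
    min_identity: float = 60.0,
) -> StructureModel:
    """Attach laminin subunit labels to chains, in place.

    Either give an explicit ``mapping`` (chain id -> subunit label), or a
    reference FASTA whose record ids are subunit labels; each chain is then
    tagged with the best-identity reference at >= ``min_identity`` percent.
    """
    if mapping:
        for cid, label in mapping.items():
            if label not in SUBUNIT_LABELS:
                raise ValueError(f"unknown subunit label {label!r}")
            model.chain(cid).subunit_label = label
        return model
    if reference_fasta is None:
        raise ValueError("need either an explicit mapping or a reference FASTA")
    from Bio import SeqIO

    from .conservation import global_align

    refs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(reference_fasta), "fasta")]
    if not refs:
        raise ValueError(f"no records in {reference_fasta}")
    for chain in model.chains:
        best_label, best_ident = None, -math.inf
        for label, seq in refs:
            ident = global_align(chain.sequence, seq).identity_pct
            if ident > best_ident:
                best_label, best_ident = label, ident
        if best_ident >= min_identity:
            if best_label not in SUBUNIT_LABELS:
                raise ValueError(f"reference record id {best_label!r} is not a subunit label")
            chain.subunit_label = best_label
    return model
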