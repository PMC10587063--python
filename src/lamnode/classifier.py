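"""Mechanistic four-class assignment of pathogenic LN-domain mutations.

Missense mutations that block laminin polymerization fall into four
structural classes when examined in the wild-type polymer-node context:

1. interface — the residue sits at an inter-subunit binding interface or
   donates/accepts an inter-chain hydrogen bond;
2. glycosylation-adjacent — surface-exposed residue close to an invariant
   N-glycosylation sequon on the back face of the jelly-roll sheet;
3. disulfide — a cysteine engaged in a disulfide bridge;
4. hydrophobic core — a buried apolar residue of the jelly-roll core.

Rules are evaluated in the fixed precedence 3 → 1 → 2 → 4 (disulfide
membership is unambiguous; interface loss is the primary polymerization
failure mechanism and outranks the surface/core descriptions).  A mutation
matching no rule is reported as class 0 with diagnostics, never forced.

The classifier reads only wild-type structural context; transcribed
literature labels live in the evaluation harness and are compared after the
fact, never consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureExtractor, HBond, ResidueFeatureProfile, ResRef
from .model_io import CatalogEntry, MutationSpec, StructureModel, three_to_one

__all__ = [
    "ClassAssignment",
    "HBondDiff",
    "CLASS_NAMES",
    "assign_class",
    "hbond_diff",
    "classify_catalog",
]

CLASS_NAMES = {
    0: "unclassified",
    1: "interface",
    2: "glycosylation-adjacent",
    3: "disulfide",
    4: "hydrophobic-core",
}


@dataclass
class ClassAssignment:
    mutation: MutationSpec
    assigned_class: int
    evidence: list[str]
    precedence_trace: list[tuple[str, bool]]
    flags: list[str] = field(default_factory=list)

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.assigned_class]


def assign_class(
    profile: ResidueFeatureProfile,
    mutation: MutationSpec,
    sequon_max_distance: float = 10.0,
    min_exposed_rsa: float = 0.2,
    near_threshold_frac: float = 0.10,
) -> ClassAssignment:
    """Assign one mutation to a mechanistic class from its WT-node profile.

    The profile must describe the mutated position on the wild-type node; a
    disagreement between the model residue and the catalog wild-type residue
    is a hard error (it means the position was profiled on the wrong chain,
    numbering offset, or isoform).
    """
    model_aa = three_to_one(profile.residue_name)
    if model_aa != mutation.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {profile.residue[0]}:{profile.residue[1][0]}: "
            f"model has {profile.residue_name} ({model_aa}), catalog says {mutation.wt_aa}"
        )
    trace: list[tuple[str, bool]] = []
    evidence: list[str] = []
    flags = list(profile.flags)

    rule3 = profile.residue_name == "CYS" and profile.in_disulfide is not None
    trace.append(("disulfide cysteine (class 3)", rule3))

    rule1 = profile.is_interface or bool(profile.inter_chain_hbonds)
    trace.append(("interface contact or inter-chain H-bond (class 1)", rule1))

    exposed = profile.rsa is not None and profile.rsa >= min_exposed_rsa
    near_sequon = profile.sequon_distance <= sequon_max_distance
    rule2 = near_sequon and exposed
    trace.append(("surface-exposed near glycosylation sequon (class 2)", rule2))

    rule4 = profile.is_hydrophobic_core
    trace.append(("buried hydrophobic-core residue (class 4)", rule4))

    # flag calls sitting within 10% of a threshold: borderline evidence
    if profile.sequon_distance != np.inf and abs(
        profile.sequon_distance - sequon_max_distance
    ) <= near_threshold_frac * sequon_max_distance:
        flags.append(f"sequon distance {profile.sequon_distance:.2f} Å near threshold")
    if profile.rsa is not None and abs(profile.rsa - min_exposed_rsa) <= (
        near_threshold_frac * min_exposed_rsa
    ):
        flags.append(f"rsa {profile.rsa:.3f} near exposure threshold")

    if rule3:
        assigned = 3
        b = profile.in_disulfide
        evidence.append(
            f"disulfide {b.cys_a[0]}:Cys{b.cys_a[1][0]} - {b.cys_b[0]}:Cys{b.cys_b[1][0]} "
            f"(SG-SG {b.sg_distance:.2f} Å)"
        )
    elif rule1:
        assigned = 1
        if profile.interface_partners:
            evidence.append(f"interface with chain(s) {', '.join(profile.interface_partners)}")
        for hb in profile.inter_chain_hbonds:
            evidence.append(
                f"inter-chain H-bond {hb.donor[0]}:{hb.donor[1][0]}:{hb.donor[2]} -> "
                f"{hb.acceptor[0]}:{hb.acceptor[1][0]}:{hb.acceptor[2]} ({hb.distance:.2f} Å)"
            )
    elif rule2:
        assigned = 2
        evidence.append(
            f"sequon Asn within {profile.sequon_distance:.2f} Å, rsa {profile.rsa:.2f}"
        )
    elif rule4:
        assigned = 4
        evidence.append(f"buried hydrophobic residue (rsa {profile.rsa:.3f})")
    else:
        assigned = 0
        evidence = []
        flags.append(
            "no structural rule fired: "
            + (f"rsa={profile.rsa:.2f}, " if profile.rsa is not None else "")
            + f"sequon_distance={profile.sequon_distance:.1f} Å"
        )
    return ClassAssignment(
        mutation=mutation,
        assigned_class=assigned,
        evidence=evidence,
        precedence_trace=trace,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# WT-vs-mutant hydrogen-bond differences
# ---------------------------------------------------------------------------


@dataclass
class HBondDiff:
    site: ResRef
    radius: float
    lost: list[HBond]
    gained: list[HBond]


def _site_distance(model: StructureModel, site: ResRef, residue: ResRef) -> float:
    chain = model.chain(site[0])
    target = chain.residue(*site[1])
    if target is None:
        raise ValueError(f"site {site} unmappable in model {model.model_id}")
    other = model.chain(residue[0]).residue(*residue[1])
    if other is None:
        return np.inf
    tc, oc = target.heavy_coords(), other.heavy_coords()
    if len(tc) == 0 or len(oc) == 0:
        return np.inf
    return float(np.linalg.norm(tc[:, None, :] - oc[None, :, :], axis=2).min())


def hbond_diff(
    wt_node: StructureModel,
    mut_node: StructureModel,
    site: ResRef,
    radius: float = 8.0,
    hbond_max_distance: float = 3.5,
) -> HBondDiff:
    """Hydrogen bonds lost and gained around a mutation site.

    Bond identity is keyed on (donor residue, acceptor residue), ignoring the
    exact atoms, so a bond that merely shifts between equivalent side-chain
    atoms does not register.  Only bonds with at least one endpoint residue
    within ``radius`` Å (heavy-atom minimum) of the site are compared;
    ``radius=0`` restricts to bonds touching the site residue itself.
    """
    from .features import detect_hbonds

    def near_bonds(model: StructureModel) -> dict[tuple, HBond]:
        chain = model.chain(site[0])
        if chain.residue(*site[1]) is None:
            raise ValueError(f"site {site} unmappable in model {model.model_id}")
        bonds = detect_hbonds(model, max_distance=hbond_max_distance)
        out: dict[tuple, HBond] = {}
        cache: dict[ResRef, float] = {}

        def dist(ref: ResRef) -> float:
            if ref not in cache:
                cache[ref] = _site_distance(model, site, ref)
            return cache[ref]

        for b in bonds:
            refs = (b.donor_residue, b.acceptor_residue)
            if radius == 0:
                keep = site in refs
            else:
                keep = any(dist(r) <= radius for r in refs)
            if keep:
                out.setdefault(b.residue_key(), b)
        return out

    wt_bonds = near_bonds(wt_node)
    mut_bonds = near_bonds(mut_node)
    lost = [b for k, b in sorted(wt_bonds.items()) if k not in mut_bonds]
    gained = [b for k, b in sorted(mut_bonds.items()) if k not in wt_bonds]
    return HBondDiff(site=site, radius=radius, lost=lost, gained=gained)


# ---------------------------------------------------------------------------
# catalog-level classification
# ---------------------------------------------------------------------------


def classify_catalog(
    entries: Sequence[CatalogEntry],
    model_store: Mapping[str, StructureModel],
    sequon_max_distance: float = 10.0,
    min_exposed_rsa: float = 0.2,
    evaluation: bool = False,
    extractor_factory=FeatureExtractor,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Classify every catalog mutation on its wild-type node model.

    ``model_store`` maps a node key to a wild-type :class:`StructureModel`;
    the key is ``entry.model_key`` when set, else the concatenated node
    composition (e.g. ``"alpha2beta1gamma1"``).  Missing models mark the row
    unevaluated and the run continues.  With ``evaluation=True`` the
    transcribed literature class is compared post hoc and disagreements are
    flagged; the classifier itself never sees the label.
    """
    extractors: dict[str, FeatureExtractor] = {}
    rows = []
    counts = {1: 0, 2: 0, 3: 0, 4: 0, 0: 0}
    for entry in entries:
        spec = entry.spec
        key = entry.model_key or "".join(spec.node_composition)
        row: dict = {
            "mutation": spec.label,
            "node": "".join(spec.node_composition),
            "status": "ok",
            "assigned_class": None,
            "class_name": None,
            "evidence": "",
            "flags": "",
        }
        model = model_store.get(key)
        if model is None:
            row["status"] = "unevaluated (no model)"
            rows.append(row)
            continue
        try:
            if key not in extractors:
                extractors[key] = extractor_factory(model)
            chain = model.chain_by_subunit(spec.subunit_label)
            profile = extractors[key].profile((chain.id, (spec.position, "")))
            assignment = assign_class(
                profile,
                spec,
                sequon_max_distance=sequon_max_distance,
                min_exposed_rsa=min_exposed_rsa,
            )
        except (KeyError, ValueError) as exc:
            row["status"] = f"unevaluated ({exc})"
            rows.append(row)
            continue
        counts[assignment.assigned_class] += 1
        row["assigned_class"] = assignment.assigned_class
        row["class_name"] = assignment.class_name
        row["evidence"] = "; ".join(assignment.evidence)
        row["flags"] = "; ".join(assignment.flags)
        if evaluation and entry.paper_class is not None:
            row["paper_class"] = entry.paper_class
            row["agrees"] = assignment.assigned_class == entry.paper_class
        rows.append(row)
    table = pd.DataFrame(rows)
    return table, counts
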