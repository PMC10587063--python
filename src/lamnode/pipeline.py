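"""End-to-end orchestration: catalog in, classified report bundle out."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .classifier import classify_catalog
from .config import RunConfig
from .features import FeatureExtractor
from .model_io import CatalogEntry, StructureModel, load_catalog, parse_structure
from .superposition import pairwise_rmsd_table

__all__ = ["ReportBundle", "run_pipeline", "load_model_store"]


@dataclass
class ReportBundle:
    config_digest: str
    assignments: pd.DataFrame
    class_counts: dict[int, int]
    n_evaluated: int
    n_unevaluated: int
    rmsd_table: Optional[pd.DataFrame] = None
    conservation: Optional[dict] = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
        summary = {
            "tool": f"lamnode {__version__}",
            "config_digest": self.config_digest,
            "class_counts": {str(k): v for k, v in sorted(self.class_counts.items())},
            "n_evaluated": self.n_evaluated,
            "n_unevaluated": self.n_unevaluated,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        if self.rmsd_table is not None:
            self.rmsd_table.to_csv(out / "rmsd_matrix.tsv", sep="\t")


def _composition_of_stem(stem: str) -> Optional[tuple[str, ...]]:
    from .model_io import SUBUNIT_LABELS

    rest, labels = stem.lower(), []
    while rest:
        for label in SUBUNIT_LABELS:
            if rest.startswith(label):
                labels.append(label)
                rest = rest[len(label):]
                break
        else:
            return None
    return tuple(labels) if labels else None


def load_model_store(model_dir: str | Path, source_kind: str = "computed") -> dict[str, StructureModel]:
    """Load every coordinate file in a directory, keyed by file stem.

    Stems are expected to name node compositions (e.g. ``alpha2beta1gamma1``)
    or to match the catalog's ``model_key`` values.  When a stem spells out a
    composition and the chain count matches, chains are tagged with the
    subunit labels in file order (the deposit convention: α, β, γ).
    """
    store = {}
    for path in sorted(Path(model_dir).glob("*")):
        if path.suffix.lower() in (".pdb", ".cif", ".mmcif", ".ent"):
            model = parse_structure(path, source_kind=source_kind)
            comp = _composition_of_stem(path.stem)
            if comp and len(comp) == len(model.chains):
                for chain, label in zip(model.chains, comp):
                    chain.subunit_label = label
            store[path.stem] = model
    return store


def run_pipeline(
    config: RunConfig,
    catalog: Sequence[CatalogEntry] | str | Path,
    model_store: Mapping[str, StructureModel],
    superpose: bool = False,
    evaluation: bool = True,
) -> ReportBundle:
    """Classify a mutation catalog against wild-type node models.

    Emits per-mutation assignments with evidence, per-class counts, and an
    optional all-vs-all RMSD table over the supplied models.  Rows whose
    model is missing are marked unevaluated; the run only fails when nothing
    at all is evaluable.
    """
    entries = load_catalog(catalog) if isinstance(catalog, (str, Path)) else list(catalog)
    if not entries:
        return ReportBundle(
            config_digest=config.digest(),
            assignments=pd.DataFrame(),
            class_counts={0: 0, 1: 0, 2: 0, 3: 0, 4: 0},
            n_evaluated=0,
            n_unevaluated=0,
        )

    def factory(model: StructureModel) -> FeatureExtractor:
        return FeatureExtractor(
            model,
            contact_cutoff=config.interface_contact,
            hbond_max_distance=config.hbond_max_distance,
            sg_cutoff=config.sg_cutoff,
            rsa_core_threshold=config.rsa_core_threshold,
            sasa_points=config.sasa_points,
        )

    table, counts = classify_catalog(
        entries,
        model_store,
        sequon_max_distance=config.sequon_max_distance,
        min_exposed_rsa=config.min_exposed_rsa,
        evaluation=evaluation,
        extractor_factory=factory,
    )
    n_eval = int((table["status"] == "ok").sum()) if len(table) else 0
    rmsd_df = None
    if superpose and len(model_store) >= 2:
        models = list(model_store.values())
        mat, labels = pairwise_rmsd_table(models)
        rmsd_df = pd.DataFrame(mat, index=labels, columns=labels)
    return ReportBundle(
        config_digest=config.digest(),
        assignments=table,
        class_counts=counts,
        n_evaluated=n_eval,
        n_unevaluated=len(table) - n_eval,
        rmsd_table=rmsd_df,
    )
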