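"""lamnode: structural analysis of pathogenic laminin LN-domain mutations.

Laminin heterotrimers polymerize through trimeric "polymer nodes" formed by
the N-terminal LN domains of one α, one β and one γ short arm.  Missense
mutations in these domains cause LN-lamininopathies by blocking node
assembly.  This package measures the structural context of such mutations on
polymer-node models — superposition quality between predicted and
experimental coordinates, inter-subunit interfaces, hydrogen bonds,
disulfide bridges, N-glycosylation sequons, solvent burial — and assigns
each mutation to one of four mechanistic classes.
"""

__version__ = "0.1.0"

from .model_io import (  # noqa: F401
    Atom,
    CatalogEntry,
    Chain,
    MutationSpec,
    NodeManifest,
    Residue,
    StructureModel,
    build_manifest,
    load_catalog,
    map_residues,
    parse_mutation_notation,
    parse_structure,
    plddt_profile,
)
from .superposition import SuperpositionResult, kabsch_superpose, pruned_rmsd  # noqa: F401
from .features import FeatureExtractor, profile_residue  # noqa: F401
from .classifier import assign_class, classify_catalog, hbond_diff  # noqa: F401
from .conservation import global_align, identity_matrix  # noqa: F401
from .config import RunConfig  # noqa: F401


def packaged_catalog_path() -> str:
    """Path to the shipped 23-mutation pathogenic catalog TSV."""
    from importlib.resources import files

    return str(files("lamnode").joinpath("data/catalog.tsv"))
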