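#!/usr/bin/env python
"""Enumerate the modelling campaign implied by the pathogenic-mutation catalog.

The catalog lists 23 LN-domain missense mutations across five laminin
subunits.  Modelling each mutation as a monomer and in its trimeric node
context, on top of the wild-type subunits and the three wild-type nodes,
yields the study manifest.  Finding: 29 monomers + 26 trimers = 55 models.

Writes results/manifest.json and results/catalog_summary.tsv.
"""

import json
import sys
from collections import Counter
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

import lamnode
from lamnode.model_io import build_manifest, format_mutation, load_catalog

OUT = REPO / "results"
OUT.mkdir(exist_ok=True)

catalog = load_catalog(lamnode.packaged_catalog_path())
manifest = build_manifest(
    catalog,
    wt_subunits=["alpha1", "alpha2", "alpha5", "beta1", "beta2", "gamma1"],
    wt_trimers=["a1b1g1", "a2b1g1", "a5b2g1"],
)

counts = manifest.counts()
per_subunit = Counter(e.spec.subunit_label for e in catalog)
per_label = Counter(e.paper_class for e in catalog)

print(f"catalog: {len(catalog)} pathogenic mutations")
print(f"  by subunit: {dict(sorted(per_subunit.items()))}")
print(f"  literature class labels: {dict(sorted(per_label.items()))}")
print(f"manifest: {counts['monomers']} monomers + {counts['trimers']} trimers "
      f"= {counts['total']} models")

(OUT / "manifest.json").write_text(json.dumps(counts, indent=2))
rows = ["mutation\tconstruct\tdisease\tliterature_class"]
for e in catalog:
    rows.append(f"{e.spec.label}\t{format_mutation(e.spec, greek=False)}"
                f"\t{e.disease}\t{e.paper_class}")
(OUT / "catalog_summary.tsv").write_text("\n".join(rows) + "\n")
print(f"wrote {OUT / 'manifest.json'} and {OUT / 'catalog_summary.tsv'}")
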