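# lamnode — structural analysis of pathogenic laminin LN-domain mutations

Laminins (Lm) are heterotrimeric basement-membrane proteins that polymerize
into a lattice through trimeric **polymer nodes**: one α, one β and one γ
short arm meeting through their N-terminal LN domains. Missense mutations in
these LN domains cause LN-lamininopathies (LAMA2-CMD, Pierson syndrome, LGMD
and related disorders) by blocking node assembly. `lamnode` is an analysis
pipeline that measures the *structural context* of such mutations on
polymer-node coordinate models and assigns each mutation to one of four
mechanistic classes:

1. **interface** — the wild-type residue sits at an inter-subunit interface
   (any heavy atom within 5 Å of a partner chain) or engages in an
   inter-chain hydrogen bond;
2. **glycosylation-adjacent** — surface-exposed residue (rSASA ≥ 0.2) within
   10 Å of the Asn of an N-X-[S/T] (X ≠ P) glycosylation sequon;
3. **disulfide** — a cysteine engaged in a disulfide bridge (SG–SG ≤ 2.5 Å);
4. **hydrophobic core** — a buried apolar residue (rSASA < 0.10).

Rules are evaluated on the **wild-type** node in fixed precedence
3 → 1 → 2 → 4; every assignment carries its evidence and the full rule
trace. Around the classifier the package provides the supporting
machinery: PDB/mmCIF parsing (via gemmi), Kabsch superposition with
backbone/all-heavy/iteratively-pruned RMSD (RMSD = √(Σ‖xᵢ−yᵢ‖²/N) after the
optimal proper rotation), Shrake–Rupley solvent accessibility, geometric
hydrogen-bond and disulfide detection, sequon scanning, pairwise global
alignment and percent-identity matrices, per-residue pLDDT profiles for
predicted models, and a self-validating synthetic-fixture generator that
plants every feature with known truth labels.

## Worked example

```python
from lamnode import RunConfig, load_catalog, packaged_catalog_path
from lamnode.pipeline import run_pipeline
from lamnode.synthetic import SyntheticNodeSpec, build_toy_node
from lamnode.model_io import CatalogEntry

model, truth = build_toy_node(SyntheticNodeSpec(seed=21, noise_sigma=0.05))
entries = [CatalogEntry(spec=m, paper_class=k, model_key="toy")
           for k, m in truth["mutations"].items()]
bundle = run_pipeline(RunConfig(), entries, {"toy": model})
print(bundle.class_counts)   # {1: 1, 2: 1, 3: 1, 4: 1, 0: 0}
print(bundle.n_evaluated)    # 4
```

The fixture plants one mutation site per mechanism — a tyrosine donating an
inter-chain hydrogen bond at the planted interface, a serine next to an
N-L-T sequon, a disulfide cysteine, and a buried leucine — and the pipeline
recovers exactly one mutation in each class. The same flow runs from the
shell:

```bash
lamnode simulate --out fixtures/ --seed 7
lamnode superpose --ref fixtures/toy-node-seed7.pdb --mob other.pdb --prune 2.0
lamnode classify --catalog mutations.tsv --models models/ --out report/
```

A run of `analysis/03_feature_recovery.py` prints, over 50 seeded fixtures:

```
interface          precision 1.000 recall 1.000
disulfide          precision 1.000 recall 1.000
sequon             precision 1.000 recall 1.000
core               precision 1.000 recall 1.000
inter_chain_hbond  precision 1.000 recall 1.000
planted-class accuracy: 100.0% (counts {1: 50, 2: 50, 3: 50, 4: 50})
```

i.e. every planted feature is recovered exactly and every planted mutation
lands in its intended class.

## The analysis scripts

Numbered drivers under `analysis/` walk the full study; each prints what it
found and writes tables under `results/`:

| script | what it does |
|---|---|
| `01_build_manifest.py` | enumerates the modelling campaign from the shipped 23-mutation catalog: 29 monomers + 26 trimers = 55 models |
| `02_superposition_validation.py` | rigid-recovery, σ√3 noise expectation, pruning on planted outliers |
| `03_feature_recovery.py` | detector precision/recall on 50 planted fixtures |
| `04_classify_catalog.py` | four-class catalog classification (deposited nodes when present, synthetic demonstration otherwise) |
| `05_deposited_benchmarks.py` | disulfide census, predicted-vs-experimental RMSDs, pLDDT baselines on deposited files |

## Deposited-structure benchmarks

The published reference values (per-chain disulfide counts of the cryo-EM
trimeric node, backbone RMSDs of predicted deposits against PDB 8DMK / 2Y38
/ 4AQT, the 11/4/4/4 class partition of the 23-mutation catalog) are
computed on deposited coordinate sets that are too large to ship. On a
networked machine:

```bash
python scripts/fetch_structures.py --out data/structures
```

after which `analysis/05_deposited_benchmarks.py` and the corresponding
acceptance tests run against the local copies.

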