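#!/usr/bin/env python
"""Validate the superposition metrics on synthetic rigid/noisy model pairs.

Checks, on toy polymer-node fixtures: (1) a rigid-transformed copy
superposes back to zero RMSD; (2) Gaussian coordinate noise of σ per axis
recovers the closed-form expectation RMSD ≈ σ√3; (3) iterative pruning
isolates a planted set of displaced atoms.  Writes results/superposition.tsv.
"""

import sys
from pathlib import Path

import numpy as np

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from lamnode.superposition import pruned_rmsd, superpose_models
from lamnode.synthetic import (
    SyntheticNodeSpec,
    build_toy_node,
    perturb,
    random_rotation,
)

OUT = REPO / "results"
OUT.mkdir(exist_ok=True)
rows = ["check\tvalue_angstrom\texpectation_angstrom\tn_atoms"]

rng = np.random.default_rng(2024)
base, _ = build_toy_node(SyntheticNodeSpec(seed=42, audit=False))
moved, _ = build_toy_node(SyntheticNodeSpec(
    seed=42, audit=False,
    rigid_transform=(random_rotation(rng), rng.normal(size=3) * 10),
))
res = superpose_models(moved, base, atom_mode="all_heavy")
print(f"rigid-transform recovery: RMSD {res.rmsd_all:.2e} Å over {res.n_pairs} atoms")
rows.append(f"rigid_recovery\t{res.rmsd_all:.6e}\t0\t{res.n_pairs}")

for sigma in (0.25, 0.5, 1.0):
    noisy = perturb(base, sigma, seed=7)
    res = superpose_models(noisy, base, atom_mode="all_heavy")
    expect = sigma * np.sqrt(3)
    print(f"noise σ={sigma} Å: RMSD {res.rmsd_all:.3f} Å (expectation {expect:.3f})")
    rows.append(f"noise_sigma_{sigma}\t{res.rmsd_all:.4f}\t{expect:.4f}\t{res.n_pairs}")

A = rng.normal(size=(200, 3)) * 20
B = A.copy()
B[:20] += rng.normal(0, 8.0, size=(20, 3))
res = pruned_rmsd(A, B, cutoff=2.0)
print(f"pruning: {res.pruned_pairs}/200 pairs retained, "
      f"pruned RMSD {res.rmsd_pruned:.3f} Å vs all-pair {res.rmsd_all:.3f} Å")
rows.append(f"pruned_retained\t{res.pruned_pairs}\t180\t200")

(OUT / "superposition.tsv").write_text("\n".join(rows) + "\n")
print(f"wrote {OUT / 'superposition.tsv'}")
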