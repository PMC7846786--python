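# dutafab

A toolkit for engineering **dual-paratope Fab fragments (DutaFabs)** —
antibody Fv domains that carry two independent, spatially separated binding
sites on a single VH3–Vk1 scaffold and can therefore bind two different
antigens simultaneously.

## The problem and the model

The six CDR loops of an Fv can be partitioned into two contiguous surfaces
on opposite faces of the domain:

* **H-side paratope** = HCDR1 ∪ HCDR3 ∪ LCDR2 (plus optional "enhancing"
  framework residues at the VH N-terminus and VH outer loop),
* **L-side paratope** = LCDR1 ∪ LCDR3 ∪ HCDR2 (plus Vk N-terminus and Vk
  outer loop).

Because the two resolved position sets are disjoint, a monospecific binder
selected on the H-side and another selected on the L-side can be **merged**
by positional substitution into one bispecific sequence: the merged Fv
equals the scaffold everywhere except at H-side positions (taken from the
H-side binder) and L-side positions (taken from the L-side binder).
Modularity is protected by scaffold rules: invariant Fv interface residues
(VH35, VH50, VK34, VK91), a kinked HCDR3 enforced by a basic residue at
VH94 with invariant Asp at VH101, an aromatic pair (Tyr/Phe) at VH99 and
VK49, and one fixed HCDR3 length per library.

The package provides, as a library plus a thin `dutafab` CLI:

| module | capability |
|---|---|
| `fv_numbering` | FASTA parsing, template-anchored Kabat-style numbering (H1–H113, L1–L107, insertion codes only at canonical anchors), Kabat/Chothia/Contact/union CDR annotation |
| `paratope_model` | H-side/L-side position resolution, paratope extraction, scaffold-rule audits |
| `merge_engine` | paratope merging with per-position provenance, labelled point-mutation sets (e.g. the five-residue YHE co-operativity motif `L:Q3Y, L:T5H, L:S7E, L:Q100H, L:L104V`) |
| `library_design` | per-position diversification specs, exact big-integer diversity ∏ᵢ&#124;Aᵢ&#124;, seeded sampling, affinity-maturation specs with a frozen opposite paratope |
| `structure_tools` | Shrake–Rupley SASA, interface footprints ΔSASA = SASA(alone) − SASA(in complex) with CDR attribution, Kabsch superposition, ternary co-binding models with vdW clash scans, Matthews coefficient V_M = V/(z·n·MW) and solvent content S = 1 − 1.66054·v̄/V_M |
| `assay_models` | 4-parameter logistic fits y = bottom + (top−bottom)/(1+(x/IC50)^n_H); DLS-bead viscosity η = η₀·(r_h/r_h,0) |
| `fixtures` | seeded synthetic generators: compliant scaffolds, binders with known deviation sets, toy complexes with oracle-computed areas/clashes, dose-response curves |

## Worked example

```python
from dutafab import assign_numbering, merge_paratopes, diff_fv
from dutafab.fixtures import make_scaffold, make_binder

scaffold = assign_numbering(make_scaffold(seed=7))
h_binder, h_truth = make_binder(scaffold, "H-side", n_mutations=6, seed=8)
l_binder, l_truth = make_binder(scaffold, "L-side", n_mutations=5, seed=9)
result = merge_paratopes(scaffold, assign_numbering(h_binder),
                         assign_numbering(l_binder))
print(len(diff_fv(scaffold, result.merged_numbered)))   # -> 11
```

Running `python examples/02_audit_and_merge.py` prints (abridged):

```
merged scaffold-7-hbinder-8+scaffold-7-lbinder-9: {'scaffold': 120, 'H-binder': 46, 'L-binder': 54}
differences vs scaffold: 11 (ground truth 11), all attributed to a side:
  H33: A -> L  [H-side]
  H53: G -> R  [L-side]
  ...
```

The provenance counts say how many positions of the bispecific Fv came from
each input; the 11 differences are exactly the union of the two binders'
ground-truth mutation sets, each attributed to the paratope that owns it —
the merge touched nothing else. The other scripts in `examples/` walk
through numbering, library design (`diversity 685,440 (10^5.84)`), interface
footprints (`buried(A) = 136.0 A^2` vs a 5000-point oracle value of 135.2),
co-binding models (`severe inter-antigen clashes: 0`) and assay fits
(`IC50 = 99.9 pM, Hill = 1.21` from a noisy curve with true IC50 100 pM).

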