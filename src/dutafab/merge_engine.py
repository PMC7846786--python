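"""Paratope merging: combine monospecific H-side and L-side binders into one
bispecific Fv on a shared scaffold.

The merge is a positional substitution: the bispecific sequence equals the
scaffold everywhere except at resolved H-side positions (taken from the
H-side binder) and resolved L-side positions (taken from the L-side binder).
Because the two resolved sets are disjoint by construction there is no
ownership conflict; loop-length changes are allowed only inside a side's own
CDRs (the H-side binder dictates the merged HCDR3 length, the L-side binder
the LCDR1/LCDR3 lengths).  In strict mode a binder deviating from the
scaffold outside its own side is rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import MergeError, MutationError
from .fv_numbering import FvSequence, NumberedFv, annotate_regions, assign_numbering, label_key
from .paratope_model import ParatopeScheme, Position, default_scheme_pair, resolve_paratope_positions

SOURCE_SCAFFOLD = "scaffold"
SOURCE_H = "H-binder"
SOURCE_L = "L-binder"
SOURCE_MUT = "mutation"


@dataclass(frozen=True)
class MergeResult:
    merged: FvSequence
    merged_numbered: NumberedFv
    provenance: dict[Position, str]
    conflicts: tuple[Position, ...]
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class MutationSpec:
    chain: str
    wt: str
    label: str
    new: str

    def __post_init__(self):
        if self.wt == self.new:
            raise MutationError(f"mutation {self} has wt == new")

    def __str__(self) -> str:
        return f"{self.chain}:{self.wt}{self.label}{self.new}"


_MUT_RE = re.compile(r"^([HL]):([A-Z])(\d+[A-Z]?)([A-Z])$")


def parse_mutation(text: str) -> MutationSpec:
    """Parse "chain:wt+label+new", e.g. "L:Q3Y" or "H:G100AY" (label 100A)."""
    m = _MUT_RE.match(text.strip())
    if not m:
        raise MutationError(f"malformed mutation spec {text!r}")
    chain, wt, label, new = m.groups()
    return MutationSpec(chain, wt, label, new)


def _side_positions(
    nfv: NumberedFv, scheme: ParatopeScheme, include_enhancing: bool
) -> set[Position]:
    ann = annotate_regions(nfv, scheme.cdr_scheme)
    return set(resolve_paratope_positions(scheme, ann, include_enhancing))


def _off_side_deviations(
    binder: NumberedFv, scaffold: NumberedFv, own: set[Position]
) -> list[Position]:
    """Positions where a binder deviates from the scaffold outside its side."""
    out = []
    for chain in "HL":
        b, s = binder.label_map(chain), scaffold.label_map(chain)
        for label in set(b) | set(s):
            pos = (chain, label)
            if pos in own:
                continue
            if b.get(label) != s.get(label):
                out.append(pos)
    return sorted(out, key=lambda p: (p[0], label_key(p[1])))


def merge_paratopes(
    scaffold: NumberedFv,
    h_binder: NumberedFv,
    l_binder: NumberedFv,
    scheme_pair: tuple[ParatopeScheme, ParatopeScheme] | None = None,
    include_enhancing: bool = True,
    strict: bool = True,
    merged_id: str | None = None,
) -> MergeResult:
    """Merge an H-side binder and an L-side binder into a bispecific Fv."""
    h_scheme, l_scheme = scheme_pair or default_scheme_pair()
    if {h_scheme.side, l_scheme.side} != {"H-side", "L-side"}:
        raise MergeError("scheme_pair must contain one H-side and one L-side scheme")
    if h_scheme.side != "H-side":
        h_scheme, l_scheme = l_scheme, h_scheme
    if not (scaffold.template_id == h_binder.template_id == l_binder.template_id):
        raise MergeError("scaffold and binders are numbered on different templates")

    # each binder's side resolved on that binder (it owns its CDR lengths)
    h_set = _side_positions(h_binder, h_scheme, include_enhancing)
    l_set = _side_positions(l_binder, l_scheme, include_enhancing)
    conflicts = tuple(sorted(h_set & l_set))
    if conflicts:
        raise MergeError(f"positions claimed by both sides: {conflicts}")

    warnings: list[str] = []
    # a binder may legitimately carry residues in the opposite paratope (e.g.
    # a previous merge output re-used as input); those are simply not copied.
    # Strict mode rejects only true framework deviations, outside both sides.
    for binder, name in ((h_binder, "H-side"), (l_binder, "L-side")):
        either = _side_positions(binder, h_scheme, include_enhancing) | _side_positions(
            binder, l_scheme, include_enhancing
        )
        off = _off_side_deviations(binder, scaffold, either)
        if off:
            msg = f"{name} binder deviates from scaffold off-paratope at {off}"
            if strict:
                raise MergeError("off-paratope deviation: " + msg)
            warnings.append(msg + " (scaffold wins)")

    # scaffold's own side footprints (may differ in extent from the binders')
    h_set_sc = _side_positions(scaffold, h_scheme, include_enhancing)
    l_set_sc = _side_positions(scaffold, l_scheme, include_enhancing)

    provenance: dict[Position, str] = {}
    chains: dict[str, str] = {}
    for chain in "HL":
        merged: dict[str, str] = {}
        for label, aa in scaffold.label_map(chain).items():
            pos = (chain, label)
            if pos in h_set_sc or pos in l_set_sc:
                continue  # paratope positions are owned by the binders
            merged[label] = aa
            provenance[pos] = SOURCE_SCAFFOLD
        for binder, own, src in ((h_binder, h_set, SOURCE_H), (l_binder, l_set, SOURCE_L)):
            for label, aa in binder.label_map(chain).items():
                pos = (chain, label)
                if pos in own:
                    merged[label] = aa
                    provenance[pos] = src
        chains[chain] = "".join(
            merged[label] for label in sorted(merged, key=label_key)
        )

    if merged_id is None:
        merged_id = f"{h_binder.source.id}+{l_binder.source.id}"
    fv = FvSequence(heavy=chains["H"], light=chains["L"], id=merged_id)
    nfv = assign_numbering(fv)
    # provenance must cover the merged frame exactly
    frame = {(c, r.label) for c in "HL" for r in nfv.residues(c)}
    assert frame == set(provenance)
    return MergeResult(fv, nfv, provenance, conflicts, tuple(warnings))


def apply_mutations(nfv: NumberedFv, muts: Sequence[MutationSpec | str]) -> NumberedFv:
    """Apply labelled point mutations (e.g. the YHE co-operativity motif)."""
    specs = [parse_mutation(m) if isinstance(m, str) else m for m in muts]
    seen = set()
    repl = {}
    for m in specs:
        key = (m.chain, m.label)
        if key in seen:
            raise MutationError(f"duplicate mutation at {m.chain}{m.label}")
        seen.add(key)
        obs = nfv.aa_at(m.chain, m.label)
        if obs is None:
            raise MutationError(f"label {m.chain}{m.label} absent from numbering frame")
        if obs != m.wt:
            raise MutationError(
                f"wt mismatch at {m.chain}{m.label}: expected {m.wt}, observed {obs}"
            )
        repl[key] = m.new
    return nfv.with_replacements(repl)


@dataclass(frozen=True)
class DiffEntry:
    chain: str
    label: str
    aa_a: str | None  # None = label absent in a
    aa_b: str | None
    side: str  # "H-side" | "L-side" | "framework"


def diff_fv(
    a: NumberedFv,
    b: NumberedFv,
    scheme_pair: tuple[ParatopeScheme, ParatopeScheme] | None = None,
    include_enhancing: bool = True,
) -> tuple[DiffEntry, ...]:
    """Positional differences between two numbered Fvs with side attribution."""
    h_scheme, l_scheme = scheme_pair or default_scheme_pair()
    h_set = _side_positions(a, h_scheme, include_enhancing) | _side_positions(
        b, h_scheme, include_enhancing
    )
    l_set = _side_positions(a, l_scheme, include_enhancing) | _side_positions(
        b, l_scheme, include_enhancing
    )
    entries = []
    for chain in "HL":
        ma, mb = a.label_map(chain), b.label_map(chain)
        for label in sorted(set(ma) | set(mb), key=label_key):
            va, vb = ma.get(label), mb.get(label)
            if va == vb:
                continue
            pos = (chain, label)
            side = "H-side" if pos in h_set else "L-side" if pos in l_set else "framework"
            entries.append(DiffEntry(chain, label, va, vb, side))
    return tuple(entries)
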