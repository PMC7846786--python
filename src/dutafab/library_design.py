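"""Phage-display library specification, exact diversity and member sampling.

A library is described per position: every diversified (chain, label) gets an
allowed amino-acid alphabet; everything else is fixed to the base sequence.
Diversity is the exact big-integer product of alphabet sizes (amino-acid
combinations, not codons).  H-side libraries fix the HCDR3 to a single
length so that loop-length variation can never perturb the opposite (L-side)
paratope; the scaffold rule set is enforced at specification time, so every
sampled member is rule-compliant by construction.

Affinity-maturation specs re-diversify one paratope while the opposite
paratope stays frozen; optionally, framework mutations outside the outer
loops are reverted to the germline template first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import LibraryError
from .fv_numbering import (
    AMINO_ACIDS,
    FvSequence,
    NumberedFv,
    annotate_regions,
    assign_numbering,
    label_key,
    template_aa,
)
from .paratope_model import (
    ParatopeScheme,
    Position,
    ScaffoldRuleSet,
    default_rules,
    default_scheme_pair,
    resolve_paratope_positions,
)

HCDR3_ANCHOR = 100


@dataclass(frozen=True)
class LibrarySpec:
    base: NumberedFv
    side: str  # "H-side" | "L-side"
    position_alphabets: dict[Position, frozenset[str]]
    hcdr3_length: int | None = None
    germline_reversions: frozenset[Position] = frozenset()

    def positions(self) -> tuple[Position, ...]:
        return tuple(sorted(self.position_alphabets, key=lambda p: (p[0], label_key(p[1]))))


@dataclass(frozen=True)
class DiversityCount:
    exact: int
    log10: float


def resize_hcdr3(nfv: NumberedFv, length: int, fill: str = "G") -> NumberedFv:
    """Return a re-numbered Fv whose Kabat HCDR3 (H95-102) has `length` residues.

    Extra residues are filled with `fill` after the H100 anchor; excess
    residues are removed counting back from the anchor, mirroring the
    numbering engine's indel placement.
    """
    ann = annotate_regions(nfv, "kabat")
    cdr3 = list(ann.regions["HCDR3"])
    delta = length - len(cdr3)
    if delta == 0:
        return nfv
    labels = [r.label for r in nfv.heavy_residues]
    seq = list(nfv.source.heavy)
    anchor_pos = max(
        i for i, lab in enumerate(labels) if lab in cdr3 and label_key(lab)[0] <= HCDR3_ANCHOR
    )
    if delta > 0:
        seq[anchor_pos + 1 : anchor_pos + 1] = [fill] * delta
    else:
        start = anchor_pos + delta + 1
        if labels[start] not in cdr3:
            raise LibraryError(f"HCDR3 cannot be shortened to {length}")
        del seq[start : anchor_pos + 1]
    fv = FvSequence("".join(seq), nfv.source.light, nfv.source.id)
    return assign_numbering(fv)


def build_library_spec(
    base: NumberedFv,
    side: str,
    alphabets: Mapping[Position, Sequence[str]],
    hcdr3_length: int | None = None,
    rules: ScaffoldRuleSet | None = None,
    scheme_pair: tuple[ParatopeScheme, ParatopeScheme] | None = None,
    include_enhancing: bool = True,
) -> LibrarySpec:
    """Validate per-position alphabets against side ownership and scaffold rules."""
    rules = rules or default_rules()
    h_scheme, l_scheme = scheme_pair or default_scheme_pair()
    scheme = h_scheme if side == "H-side" else l_scheme
    if side not in ("H-side", "L-side"):
        raise LibraryError(f"unknown side {side!r}")
    if hcdr3_length is not None:
        if side != "H-side":
            raise LibraryError("hcdr3_length applies to H-side libraries only")
        base = resize_hcdr3(base, hcdr3_length)

    ann = annotate_regions(base, scheme.cdr_scheme)
    resolved = set(resolve_paratope_positions(scheme, ann, include_enhancing))
    frame = {(c, r.label) for c in "HL" for r in base.residues(c)}

    clean: dict[Position, frozenset[str]] = {}
    for pos, letters in alphabets.items():
        chain, label = pos
        alpha = frozenset(letters)
        if not alpha or not alpha <= set(AMINO_ACIDS):
            raise LibraryError(f"invalid alphabet at {chain}{label}")
        if pos not in frame:
            raise LibraryError(f"position {chain}{label} absent from the base Fv")
        if pos not in resolved:
            raise LibraryError(f"position {chain}{label} outside the {side} resolved set")
        allowed = rules.allowed_at(chain, label)
        if allowed is not None and not alpha <= allowed:
            rid = next(r.id for r in rules.rules if (r.chain, r.label) == pos)
            raise LibraryError(
                f"alphabet {''.join(sorted(alpha))} at {chain}{label} violates rule {rid}"
            )
        clean[pos] = alpha
    return LibrarySpec(base, side, clean, hcdr3_length)


def theoretical_diversity(spec: LibrarySpec) -> DiversityCount:
    """Exact theoretical diversity = product of per-position alphabet sizes."""
    exact = 1
    log10 = 0.0
    for alpha in spec.position_alphabets.values():
        exact *= len(alpha)
        log10 += math.log10(len(alpha))
    return DiversityCount(exact=exact, log10=log10)


def sample_members(spec: LibrarySpec, n: int, seed: int) -> list[FvSequence]:
    """Draw `n` library members, each position uniform over its alphabet.

    Deterministic for a given seed; member ids carry seed and index.
    """
    if n < 1:
        raise LibraryError("n must be >= 1")
    rng = np.random.default_rng(seed)
    positions = spec.positions()
    sorted_alphas = [sorted(spec.position_alphabets[p]) for p in positions]
    out = []
    for i in range(n):
        repl = {
            pos: alpha[rng.integers(len(alpha))]
            for pos, alpha in zip(positions, sorted_alphas)
        }
        member = spec.base.with_replacements(repl)
        out.append(
            FvSequence(
                member.source.heavy,
                member.source.light,
                f"{spec.base.source.id}|seed={seed}|member={i}",
            )
        )
    return out


def enumerate_members(spec: LibrarySpec, limit: int = 10_000) -> list[FvSequence]:
    """Exhaustively enumerate all members (guarded; intended for small specs)."""
    import itertools

    div = theoretical_diversity(spec).exact
    if div > limit:
        raise LibraryError(f"diversity {div} exceeds enumeration limit {limit}")
    positions = spec.positions()
    alphas = [sorted(spec.position_alphabets[p]) for p in positions]
    out = []
    for i, combo in enumerate(itertools.product(*alphas)):
        member = spec.base.with_replacements(dict(zip(positions, combo)))
        out.append(
            FvSequence(member.source.heavy, member.source.light,
                       f"{spec.base.source.id}|enum={i}")
        )
    return out


def maturation_spec(
    dutafab: NumberedFv,
    side_to_rediversify: str,
    alphabets: Mapping[Position, Sequence[str]],
    revert_framework: bool = False,
    rules: ScaffoldRuleSet | None = None,
    scheme_pair: tuple[ParatopeScheme, ParatopeScheme] | None = None,
) -> LibrarySpec:
    """Affinity-maturation library: re-diversify one paratope, freeze the other.

    With `revert_framework`, framework positions outside both paratopes and
    outside the enhancing outer-loop/N-terminal ranges are reset to germline
    template identity before diversification (outer loops are deliberately
    left free to deviate, since they can modulate CDR1 conformation).
    """
    h_scheme, l_scheme = scheme_pair or default_scheme_pair()
    own = h_scheme if side_to_rediversify == "H-side" else l_scheme
    opp = l_scheme if side_to_rediversify == "H-side" else h_scheme

    ann = annotate_regions(dutafab, opp.cdr_scheme)
    opp_set = set(resolve_paratope_positions(opp, ann, include_enhancing=True))
    for pos in alphabets:
        if pos in opp_set:
            raise LibraryError(
                f"alphabet at {pos[0]}{pos[1]} touches the frozen {opp.side} paratope"
            )

    base = dutafab
    reverted: set[Position] = set()
    if revert_framework:
        own_set = set(resolve_paratope_positions(own, ann, include_enhancing=True))
        enhancing_all: set[Position] = set()
        for scheme in (h_scheme, l_scheme):
            core = set(resolve_paratope_positions(scheme, ann, include_enhancing=False))
            full = set(resolve_paratope_positions(scheme, ann, include_enhancing=True))
            enhancing_all |= full - core
        repl = {}
        for chain in "HL":
            for res in dutafab.residues(chain):
                pos = (chain, res.label)
                if pos in own_set or pos in opp_set or pos in enhancing_all:
                    continue
                if label_key(res.label)[1]:
                    continue  # insertion-coded framework labels have no template identity
                germ = template_aa(chain, res.label)
                if res.aa != germ:
                    repl[pos] = germ
                    reverted.add(pos)
        if repl:
            base = dutafab.with_replacements(repl)

    spec = build_library_spec(
        base, side_to_rediversify, alphabets, rules=rules,
        scheme_pair=(h_scheme, l_scheme), include_enhancing=True,
    )
    return LibrarySpec(
        spec.base, spec.side, spec.position_alphabets, spec.hcdr3_length,
        germline_reversions=frozenset(reverted),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def spec_to_yaml(spec: LibrarySpec) -> str:
    doc = {
        "base_id": spec.base.source.id,
        "side": spec.side,
        "hcdr3_length": spec.hcdr3_length,
        "germline_reversions": sorted(f"{c}{l}" for c, l in spec.germline_reversions),
        "positions": {
            f"{c}{l}": "".join(sorted(a))
            for (c, l), a in sorted(spec.position_alphabets.items())
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
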