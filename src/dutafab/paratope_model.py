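"""H-side / L-side paratope definitions and scaffold stability rules.

The dual-paratope design partitions the six CDR loops into two independent
binding surfaces on opposite faces of the Fv:

* **H-side** — HCDR1 + HCDR3 + LCDR2, optionally extended by "enhancing"
  framework residues at the VH N-terminus and the VH outer loop;
* **L-side** — LCDR1 + LCDR3 + HCDR2, optionally extended by the Vk
  N-terminus and the Vk outer loop.

Disjointness of the two resolved label sets is the platform's core
structural contract: it is what makes monospecific binders mergeable.

The scaffold rule set encodes the stability and HCDR3-conformation
constraints: invariant Fv interface residues (H35, H50, L34, L91), the
kinked-HCDR3 motif (basic residue at H94, invariant Asp at H101) and the
aromatic pair restriction (Tyr/Phe at H99 and at L49).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import SchemeError
from .fv_numbering import (
    NumberedFv,
    RegionAnnotation,
    annotate_regions,
    label_key,
    template_aa,
)

Position = tuple[str, str]  # (chain, label)

DEFAULT_ENHANCING = {
    "H-side": {"vh_nterm": ("H", 1, 7), "vh_outer_loop": ("H", 71, 78)},
    "L-side": {"vk_nterm": ("L", 1, 7), "vk_outer_loop": ("L", 66, 71)},
}

CORE_REGIONS = {
    "H-side": ("HCDR1", "HCDR3", "LCDR2"),
    "L-side": ("LCDR1", "LCDR3", "HCDR2"),
}


@dataclass(frozen=True)
class ParatopeScheme:
    """One side's paratope definition: core CDR regions + enhancing ranges."""

    side: str  # "H-side" | "L-side"
    core_regions: tuple[str, ...]
    enhancing_ranges: Mapping[str, tuple[str, int, int]]
    cdr_scheme: str = "union"

    def __post_init__(self):
        if self.side not in CORE_REGIONS:
            raise SchemeError(f"unknown paratope side {self.side!r}")


def default_scheme_pair(
    cdr_scheme: str = "union",
    enhancing: Mapping[str, Mapping[str, tuple[str, int, int]]] | None = None,
) -> tuple[ParatopeScheme, ParatopeScheme]:
    """The platform's (H-side, L-side) scheme pair; enhancing extents overridable."""
    enh = enhancing or DEFAULT_ENHANCING
    return (
        ParatopeScheme("H-side", CORE_REGIONS["H-side"], dict(enh["H-side"]), cdr_scheme),
        ParatopeScheme("L-side", CORE_REGIONS["L-side"], dict(enh["L-side"]), cdr_scheme),
    )


def resolve_paratope_positions(
    scheme: ParatopeScheme,
    annotation: RegionAnnotation,
    include_enhancing: bool = False,
) -> tuple[Position, ...]:
    """Resolve a paratope scheme to an ordered (chain, label) set.

    Core positions come from the annotation's CDR regions; enhancing ranges
    are label intervals resolved against the labels actually present (so a
    residue "100A" inside a covered interval is included).
    """
    if annotation.scheme != scheme.cdr_scheme:
        raise SchemeError(
            f"annotation scheme {annotation.scheme!r} != paratope cdr_scheme "
            f"{scheme.cdr_scheme!r}"
        )
    positions: set[Position] = set()
    for region in scheme.core_regions:
        if region not in annotation.regions:
            raise SchemeError(f"region {region} missing from annotation")
        positions.update((region[0], lab) for lab in annotation.regions[region])
    if include_enhancing:
        for chain, start, end in scheme.enhancing_ranges.values():
            for name, labels in annotation.regions.items():
                if not name.startswith(chain):
                    continue
                for lab in labels:
                    num, _ = label_key(lab)
                    if start <= num <= end:
                        positions.add((chain, lab))
    return tuple(sorted(positions, key=lambda p: (p[0], label_key(p[1]))))


def extract_paratope(
    nfv: NumberedFv,
    scheme: ParatopeScheme,
    include_enhancing: bool = False,
    annotation: RegionAnnotation | None = None,
) -> dict[Position, str]:
    """Residues at the resolved paratope positions of one Fv.

    Positions absent from the Fv (shorter CDR than the scheme's extent)
    are simply not in the returned map — callers can compare key sets.
    """
    ann = annotation or annotate_regions(nfv, scheme.cdr_scheme)
    positions = resolve_paratope_positions(scheme, ann, include_enhancing)
    out = {}
    for chain, label in positions:
        aa = nfv.aa_at(chain, label)
        if aa is not None:
            out[(chain, label)] = aa
    return out


# ---------------------------------------------------------------------------
# scaffold rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    id: str
    chain: str
    label: str
    allowed: frozenset[str]
    text: str = ""

    def __post_init__(self):
        if not self.allowed:
            raise SchemeError(f"rule {self.id}: empty allowed set")


@dataclass(frozen=True)
class ScaffoldRuleSet:
    rules: tuple[Rule, ...]
    lenient_missing: bool = False

    def __post_init__(self):
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise SchemeError("duplicate rule ids")

    def rule_positions(self) -> set[Position]:
        return {(r.chain, r.label) for r in self.rules}

    def allowed_at(self, chain: str, label: str) -> frozenset[str] | None:
        for r in self.rules:
            if (r.chain, r.label) == (chain, label):
                return r.allowed
        return None


def default_rules(lenient_missing: bool = False) -> ScaffoldRuleSet:
    """The platform's default stability / HCDR3-conformation rule set.

    Invariant interface positions take their identity from the embedded
    templates; users with the exact scaffold identities supply a config.
    """
    inv = [
        Rule(f"inv_{c}{p}", c, str(p), frozenset(template_aa(c, str(p))),
             "invariant Fv interface stability residue")
        for c, p in (("H", 35), ("H", 50), ("L", 34), ("L", 91))
    ]
    rules = inv + [
        Rule("hcdr3_basic94", "H", "94", frozenset("RK"),
             "kinked HCDR3: basic residue at H94"),
        Rule("hcdr3_D101", "H", "101", frozenset("D"),
             "kinked HCDR3: invariant Asp at H101"),
        Rule("hcdr3_YF99", "H", "99", frozenset("YF"),
             "aromatic pair: Tyr/Phe at H99"),
        Rule("lcdr2_flank_YF49", "L", "49", frozenset("YF"),
             "aromatic pair: Tyr/Phe at L49 in front of LCDR2"),
    ]
    return ScaffoldRuleSet(tuple(rules), lenient_missing=lenient_missing)


@dataclass(frozen=True)
class Check:
    rule_id: str
    chain: str
    label: str
    expected: frozenset[str]
    observed: str | None  # None = label absent from numbering frame
    passed: bool
    applicable: bool


@dataclass(frozen=True)
class ComplianceReport:
    checks: tuple[Check, ...]
    overall: bool

    def failures(self) -> tuple[Check, ...]:
        return tuple(c for c in self.checks if not c.passed)


def check_scaffold_compliance(nfv: NumberedFv, rules: ScaffoldRuleSet | None = None) -> ComplianceReport:
    """Audit a numbered Fv against the scaffold rule set, one check per rule."""
    rules = rules or default_rules()
    checks = []
    for r in rules.rules:
        obs = nfv.aa_at(r.chain, r.label)
        if obs is None:
            passed = rules.lenient_missing
            checks.append(Check(r.id, r.chain, r.label, r.allowed, None, passed, False))
        else:
            checks.append(Check(r.id, r.chain, r.label, r.allowed, obs, obs in r.allowed, True))
    return ComplianceReport(tuple(checks), overall=all(c.passed for c in checks))


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------


def rules_to_yaml(rules: ScaffoldRuleSet) -> str:
    doc = {
        "lenient_missing": rules.lenient_missing,
        "rules": [
            {"id": r.id, "chain": r.chain, "label": r.label,
             "allowed": "".join(sorted(r.allowed)), "text": r.text}
            for r in rules.rules
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def rules_from_yaml(text: str) -> ScaffoldRuleSet:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise SchemeError("rule config must be a mapping with a 'rules' list")
    rules = []
    for item in doc["rules"]:
        try:
            rules.append(
                Rule(item["id"], item["chain"], str(item["label"]),
                     frozenset(item["allowed"]), item.get("text", ""))
            )
        except KeyError as exc:
            raise SchemeError(f"rule entry missing field {exc}") from exc
    return ScaffoldRuleSet(tuple(rules), bool(doc.get("lenient_missing", False)))


def compliance_table(report: ComplianceReport):
    import pandas as pd

    return pd.DataFrame(
        [
            {"rule": c.rule_id, "chain": c.chain, "label": c.label,
             "expected": "".join(sorted(c.expected)),
             "observed": c.observed or "-", "pass": c.passed}
            for c in report.checks
        ]
    )
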