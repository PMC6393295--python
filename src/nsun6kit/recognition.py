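"""NSun6 substrate-recognition rule sets and tRNA classification.

Archaeal and eukaryotic NSun6 enzymes methylate C72 in the tRNA
acceptor stem but read different identity elements.  The archaeal
enzyme (PhNSun6, from Pyrococcus horikoshii) requires the CCA terminus,
the target cytosine C72, a discriminator base of U73 *or* G73, and the
C2:G71 base pair; it ignores the 3:70 pair and the D-stem entirely.
The human enzyme (hNSun6) requires CCA, C72, strictly U73, and the
G2:C71 pair carried by its native substrates.  Because the two enzymes
demand opposite orientations of the 2:71 pair, no tRNA satisfies both
rule sets, which is why each enzyme methylates only its cognate
substrates.

A :class:`RuleSet` is a declarative bundle of these constraints; the
classifier compares an :class:`~nsun6kit.trna.IdentityElementProfile`
against it element by element and reports every violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import pandas as pd

from .trna import AnnotatedTRNA, IdentityElementProfile, element_profile

__all__ = [
    "RuleSet",
    "Violation",
    "ClassificationResult",
    "PanelMember",
    "PanelSpec",
    "MemberResult",
    "PanelResult",
    "builtin_rulesets",
    "builtin_panels",
    "classify",
    "classify_annotated",
    "classify_panel",
]

Pair = tuple[str, str]


def _fmt_pair(pair: Pair | None) -> str:
    return "unpaired" if pair is None else f"{pair[0]}:{pair[1]}"


def _fmt_residue(res: str | None) -> str:
    return "absent" if res is None else res


@dataclass(frozen=True)
class RuleSet:
    """Declarative substrate requirements of one NSun6 enzyme.

    Constrained fields hold the set of allowed values; ``None`` means
    the element is not read by the enzyme.  Pair constraints are sets
    of ordered (5' residue, 3' residue) tuples, so C2:G71 and G2:C71
    are distinct.
    """

    name: str
    required_cca: bool = True
    required_n72: frozenset[str] = frozenset({"C"})
    allowed_n73: frozenset[str] | None = None
    required_pair_2_71: frozenset[Pair] | None = None
    required_pair_3_70: frozenset[Pair] | None = None
    required_d_stem_pairs: Mapping[tuple[int, int], frozenset[Pair]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for label, value in (
            ("required_n72", self.required_n72),
            ("allowed_n73", self.allowed_n73),
            ("required_pair_2_71", self.required_pair_2_71),
            ("required_pair_3_70", self.required_pair_3_70),
        ):
            if value is not None and len(value) == 0:
                raise ValueError(f"{self.name}: {label} constrained but empty")
        for pos, allowed in self.required_d_stem_pairs.items():
            if len(allowed) == 0:
                raise ValueError(f"{self.name}: empty D-stem constraint at {pos}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "required_cca": self.required_cca,
            "required_n72": sorted(self.required_n72),
            "allowed_n73": None if self.allowed_n73 is None else sorted(self.allowed_n73),
            "required_pair_2_71": _pairs_out(self.required_pair_2_71),
            "required_pair_3_70": _pairs_out(self.required_pair_3_70),
            "required_d_stem_pairs": {
                f"{p5}:{p3}": _pairs_out(allowed)
                for (p5, p3), allowed in self.required_d_stem_pairs.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RuleSet":
        d_pairs = {}
        for key, allowed in (data.get("required_d_stem_pairs") or {}).items():
            p5, p3 = (int(x) for x in key.split(":"))
            d_pairs[(p5, p3)] = _pairs_in(allowed)
        return cls(
            name=data["name"],
            required_cca=bool(data.get("required_cca", True)),
            required_n72=frozenset(data.get("required_n72", ["C"])),
            allowed_n73=_set_in(data.get("allowed_n73")),
            required_pair_2_71=_pairs_in(data.get("required_pair_2_71")),
            required_pair_3_70=_pairs_in(data.get("required_pair_3_70")),
            required_d_stem_pairs=d_pairs,
        )


def _pairs_out(pairs: frozenset[Pair] | None) -> list[str] | None:
    return None if pairs is None else sorted(f"{a}:{b}" for a, b in pairs)


def _pairs_in(value: Iterable[str] | None) -> frozenset[Pair] | None:
    if value is None:
        return None
    return frozenset(tuple(item.split(":")) for item in value)  # type: ignore[misc]


def _set_in(value: Iterable[str] | None) -> frozenset[str] | None:
    return None if value is None else frozenset(value)


@dataclass(frozen=True)
class Violation:
    """One identity element that fails a rule, with observed vs required."""

    element: str
    observed: str
    required: str


@dataclass(frozen=True)
class ClassificationResult:
    trna_id: str
    ruleset_name: str
    substrate: bool
    violated_elements: tuple[Violation, ...]

    def __post_init__(self) -> None:
        assert self.substrate == (len(self.violated_elements) == 0)


def classify(
    profile: IdentityElementProfile, rules: RuleSet, trna_id: str = ""
) -> ClassificationResult:
    """Decide whether a tRNA is a substrate under one rule set.

    A tRNA is a substrate iff every constrained element matches; every
    failing element is reported with its observed value.  Elements
    missing from the profile (unpaired positions, absent CCA) count as
    violations of constrained rules, never as errors.
    """
    violations: list[Violation] = []

    if rules.required_cca and not profile.cca_present:
        violations.append(Violation("cca", "absent", "present"))
    if rules.required_n72 is not None and profile.n72 not in rules.required_n72:
        violations.append(
            Violation("n72", _fmt_residue(profile.n72), "/".join(sorted(rules.required_n72)))
        )
    if rules.allowed_n73 is not None and profile.n73 not in rules.allowed_n73:
        violations.append(
            Violation("n73", _fmt_residue(profile.n73), "/".join(sorted(rules.allowed_n73)))
        )
    for element, observed, required in (
        ("pair_2_71", profile.pair_2_71, rules.required_pair_2_71),
        ("pair_3_70", profile.pair_3_70, rules.required_pair_3_70),
    ):
        if required is not None and observed not in required:
            violations.append(
                Violation(element, _fmt_pair(observed), "|".join(sorted(_fmt_pair(p) for p in required)))
            )
    for (p5, p3), allowed in rules.required_d_stem_pairs.items():
        observed_pair = {(11, 24): profile.pair_11_24, (12, 23): profile.pair_12_23}.get(
            (p5, p3)
        )
        if observed_pair not in allowed:
            violations.append(
                Violation(
                    f"pair_{p5}_{p3}",
                    _fmt_pair(observed_pair),
                    "|".join(sorted(_fmt_pair(p) for p in allowed)),
                )
            )

    return ClassificationResult(
        trna_id=trna_id,
        ruleset_name=rules.name,
        substrate=not violations,
        violated_elements=tuple(violations),
    )


def classify_annotated(
    annotated: AnnotatedTRNA, rules: RuleSet
) -> ClassificationResult:
    """Convenience: derive the element profile and classify."""
    return classify(element_profile(annotated), rules, trna_id=annotated.record.id)


def builtin_rulesets() -> dict[str, RuleSet]:
    """The archaeal (PhNSun6) and human (hNSun6) recognition rule sets.

    PhNSun6: CCA, C72, U73 or G73, C2:G71; 3:70 and the D-stem are not
    read.  hNSun6: CCA, C72, strictly U73, G2:C71 (the pair its native
    substrates carry); further D-stem/3:70 preferences of the human
    enzyme are representable but left unconstrained here.
    """
    ph = RuleSet(
        name="PhNSun6",
        required_cca=True,
        required_n72=frozenset({"C"}),
        allowed_n73=frozenset({"U", "G"}),
        required_pair_2_71=frozenset({("C", "G")}),
    )
    human = RuleSet(
        name="hNSun6",
        required_cca=True,
        required_n72=frozenset({"C"}),
        allowed_n73=frozenset({"U"}),
        required_pair_2_71=frozenset({("G", "C")}),
    )
    return {ph.name: ph, human.name: human}


# ---------------------------------------------------------------------------
# Panels


@dataclass(frozen=True)
class PanelMember:
    """One panel entry: either scaffold constraints or mutations of the
    panel's reference scaffold, plus the expected verdict per rule set."""

    id: str
    constraints: Mapping[str, Any] | None = None
    mutations: tuple[tuple, ...] = ()
    expected: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.constraints is None) == (len(self.mutations) == 0):
            raise ValueError(
                f"{self.id}: exactly one of constraints/mutations must be given"
            )


@dataclass(frozen=True)
class PanelSpec:
    name: str
    members: tuple[PanelMember, ...]
    reference: Mapping[str, Any] | None = None  # constraints for mutant panels

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.name}: duplicate member ids")
        if any(m.mutations for m in self.members) and self.reference is None:
            raise ValueError(f"{self.name}: mutant members need a reference")

    def member(self, member_id: str) -> PanelMember:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)


@dataclass(frozen=True)
class MemberResult:
    result: ClassificationResult
    expected: bool | None

    @property
    def matches_expected(self) -> bool | None:
        if self.expected is None:
            return None
        return self.result.substrate == self.expected


@dataclass(frozen=True)
class PanelResult:
    panel_name: str
    ruleset_name: str
    members: tuple[MemberResult, ...]

    @property
    def n_substrates(self) -> int:
        return sum(1 for m in self.members if m.result.substrate)

    @property
    def n_non_substrates(self) -> int:
        return len(self.members) - self.n_substrates

    @property
    def mismatches(self) -> tuple[MemberResult, ...]:
        return tuple(m for m in self.members if m.matches_expected is False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.members:
            rows.append(
                {
                    "id": m.result.trna_id,
                    "ruleset": m.result.ruleset_name,
                    "substrate": m.result.substrate,
                    "violations": ";".join(
                        f"{v.element}={v.observed}(req {v.required})"
                        for v in m.result.violated_elements
                    ),
                    "expected": m.expected,
                    "matches_expected": m.matches_expected,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "id",
                "ruleset",
                "substrate",
                "violations",
                "expected",
                "matches_expected",
            ],
        )


class MissingSequenceError(KeyError):
    """A panel member has no parsed sequence."""


def classify_panel(
    panel: PanelSpec,
    rules: RuleSet,
    annotated: Mapping[str, AnnotatedTRNA],
) -> PanelResult:
    """Classify every panel member and compare with expected verdicts.

    ``annotated`` maps member id to its parsed tRNA (normally produced
    by :func:`nsun6kit.synth.generate_panel`).
    """
    results = []
    for member in panel.members:
        if member.id not in annotated:
            raise MissingSequenceError(
                f"panel {panel.name!r}: no sequence for member {member.id!r}"
            )
        res = classify_annotated(annotated[member.id], rules)
        results.append(
            MemberResult(result=res, expected=member.expected.get(rules.name))
        )
    return PanelResult(
        panel_name=panel.name, ruleset_name=rules.name, members=tuple(results)
    )


# -- Built-in panels --------------------------------------------------------

_WT_THR_CGU = {
    "anticodon": "CGU",
    "n73": "U",
    "pair_2_71": ("C", "G"),
    "pair_3_70": ("C", "G"),
    "pair_11_24": ("C", "G"),
    "pair_12_23": ("C", "G"),
    "cca": True,
}


def _ph_member(name: str, anticodon: str, n73: str, *, long_arm: bool = False,
               pair_2_71: tuple[str, str] = ("C", "G"),
               expected_ph: bool = True) -> PanelMember:
    return PanelMember(
        id=name,
        constraints={
            "anticodon": anticodon,
            "n73": n73,
            "pair_2_71": pair_2_71,
            "pair_3_70": ("C", "G"),
            "long_variable_arm": long_arm,
            "cca": True,
        },
        expected={"PhNSun6": expected_ph, "hNSun6": False},
    )


def builtin_panels() -> dict[str, PanelSpec]:
    """Panels mirroring the characterized substrate sets and mutant series.

    * ``PH12`` - the twelve P. horikoshii tRNAs assayed against both
      enzymes: four U73 substrates (three Thr isoacceptors and Cys),
      seven G73 substrates (four Ser isoacceptors, Asn, Asp, Arg; the
      Ser tRNAs are type II with a long variable arm), plus the
      Phe(GAA) negative control with A73 and G2:C71.
    * ``HC3`` - three human cytoplasmic hNSun6 substrates (U73 with the
      native G2:C71 pair).
    * ``MUTANTS`` - the Thr(CGU) mutant series probing each element:
      CCA deletion, C72 substitutions, discriminator substitutions,
      2:71 and 3:70 pair swaps, and ten D-stem pair swaps.
    """
    ph12 = PanelSpec(
        name="PH12",
        members=(
            _ph_member("PhtRNA-Thr(CGU)", "CGU", "U"),
            _ph_member("PhtRNA-Thr(GGU)", "GGU", "U"),
            _ph_member("PhtRNA-Thr(UGU)", "UGU", "U"),
            _ph_member("PhtRNA-Cys(GCA)", "GCA", "U"),
            _ph_member("PhtRNA-Ser(UGA)", "UGA", "G", long_arm=True),
            _ph_member("PhtRNA-Ser(CGA)", "CGA", "G", long_arm=True),
            _ph_member("PhtRNA-Ser(GGA)", "GGA", "G", long_arm=True),
            _ph_member("PhtRNA-Ser(GCU)", "GCU", "G", long_arm=True),
            _ph_member("PhtRNA-Asn(GUU)", "GUU", "G"),
            _ph_member("PhtRNA-Asp(GUC)", "GUC", "G"),
            _ph_member("PhtRNA-Arg(GCG)", "GCG", "G"),
            _ph_member(
                "PhtRNA-Phe(GAA)", "GAA", "A",
                pair_2_71=("G", "C"), expected_ph=False,
            ),
        ),
    )

    def hc_member(name: str, anticodon: str) -> PanelMember:
        return PanelMember(
            id=name,
            constraints={
                "anticodon": anticodon,
                "n73": "U",
                "pair_2_71": ("G", "C"),
                "gc_content_target": 0.55,
                "cca": True,
            },
            expected={"PhNSun6": False, "hNSun6": True},
        )

    hc3 = PanelSpec(
        name="HC3",
        members=(
            hc_member("hctRNA-Thr(AGU)", "AGU"),
            hc_member("hctRNA-Thr(UGU)", "UGU"),
            hc_member("hctRNA-Cys(GCA)", "GCA"),
        ),
    )

    def mut(name: str, mutations: tuple[tuple, ...], accepted: bool) -> PanelMember:
        return PanelMember(
            id=f"Thr(CGU)-{name}",
            mutations=mutations,
            expected={"PhNSun6": accepted},
        )

    d_swaps = [("A", "U"), ("U", "A"), ("G", "C"), ("G", "U"), ("U", "G")]
    mutant_members = [
        mut("dCCA", (("delete_cca",),), False),
        mut("C72A", (("point", 72, "A"),), False),
        mut("C72G", (("point", 72, "G"),), False),
        mut("C72U", (("point", 72, "U"),), False),
        mut("U73A", (("point", 73, "A"),), False),
        mut("U73C", (("point", 73, "C"),), False),
        mut("U73G", (("point", 73, "G"),), True),
        mut("C2G:G71C", (("pair_swap", 2, 71, "G", "C"),), False),
        mut("C2G:G71U", (("pair_swap", 2, 71, "G", "U"),), False),
        mut("C3G:G70C", (("pair_swap", 3, 70, "G", "C"),), True),
        mut("C3A:G70U", (("pair_swap", 3, 70, "A", "U"),), True),
        mut("C3G:G70U", (("pair_swap", 3, 70, "G", "U"),), True),
    ]
    for p5, p3 in ((11, 24), (12, 23)):
        for n5, n3 in d_swaps:
            mutant_members.append(
                mut(
                    f"C{p5}{n5}:G{p3}{n3}",
                    (("pair_swap", p5, p3, n5, n3),),
                    True,
                )
            )

    mutants = PanelSpec(
        name="MUTANTS",
        members=tuple(mutant_members),
        reference=dict(_WT_THR_CGU),
    )

    return {"PH12": ph12, "HC3": hc3, "MUTANTS": mutants}
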