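"""Cloverleaf parsing and canonical numbering of tRNA sequences.

The tRNA acceptor stem carries the identity elements that NSun6-family
m5C72 methyltransferases read: the CCA terminus, the target cytosine at
canonical position 72, the discriminator base N73, and the 2:71 base
pair.  This module turns a raw transcript sequence into an
:class:`AnnotatedTRNA` with canonical numbering (acceptor stem 1-7 paired
with 66-72, discriminator 73, CCA 74-76, D-stem pairs 10:25-13:22,
anticodon stem 27-31/39-43, T-stem 49-53/61-65) so that identity
elements can be addressed by position, mutated, and classified.

Parsing is template-based and anchored at the 3' end: the discriminator
sits four residues from the end when the CCA terminus is present, the
acceptor 3' strand is the seven residues 5' of the discriminator, and
the T-arm is the 17 residues preceding that.  On the 5' side the D-stem
is anchored at canonical position 10 with a variable-length D-loop; the
anticodon stem-loop follows after a single-nucleotide hinge (position
26).  No thermodynamic folding is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "TRNARecord",
    "BasePair",
    "AnnotatedTRNA",
    "IdentityElementProfile",
    "TRNAError",
    "AlphabetError",
    "CloverleafParseError",
    "parse_cloverleaf",
    "element_profile",
    "apply_point_mutation",
    "apply_pair_swap",
    "delete_cca",
    "extinction_coefficient_260",
    "pair_kind",
]

RNA_ALPHABET = frozenset("ACGU")

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})

#: Molar absorptivity of the ribonucleotide monophosphates at 260 nm,
#: in M^-1 cm^-1.  Simple base-composition sum, no hypochromicity term.
MONOMER_EPSILON_260 = {"A": 15400.0, "C": 7400.0, "G": 11500.0, "U": 9900.0}

MIN_LENGTH = 60
MAX_LENGTH = 100


class TRNAError(ValueError):
    """Base class for tRNA model errors."""


class AlphabetError(TRNAError):
    """Sequence contains residues outside A/C/G/U after normalization."""


class CloverleafParseError(TRNAError):
    """No acceptable cloverleaf architecture could be assigned."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase and convert DNA-style T to U."""
    return sequence.strip().upper().replace("T", "U")


def pair_kind(base5: str, base3: str) -> str:
    """Classify an ordered base pair as watson-crick, wobble or mismatch."""
    pair = (base5, base3)
    if pair in WATSON_CRICK:
        return "watson-crick"
    if pair in WOBBLE:
        return "wobble"
    return "mismatch"


def _is_paired(base5: str, base3: str) -> bool:
    return (base5, base3) in WATSON_CRICK or (base5, base3) in WOBBLE


@dataclass(frozen=True)
class TRNARecord:
    """A single tRNA sequence.

    The sequence is normalized (T->U, uppercased) and validated on
    construction: 60-100 nt over the A/C/G/U alphabet.
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.id!r}: non-RNA residues after normalization: {sorted(bad)}"
            )
        if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
            raise TRNAError(
                f"{self.id!r}: length {len(seq)} outside [{MIN_LENGTH}, {MAX_LENGTH}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BasePair:
    """An ordered base pair between two canonical positions.

    ``kind`` is always computed from the bases; A:U/U:A/G:C/C:G are
    watson-crick, G:U/U:G wobble, anything else mismatch.
    """

    pos5: int
    pos3: int
    bases: tuple[str, str]
    kind: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", pair_kind(*self.bases))


@dataclass(frozen=True)
class IdentityElementProfile:
    """The identity-element values a NSun6 rule set reads.

    Pair fields hold the ordered (5' residue, 3' residue) tuple, or
    ``None`` when the position pair is absent from the annotation (for
    example 13:22 in a 3-bp D-stem).
    """

    n72: str | None
    n73: str | None
    pair_2_71: tuple[str, str] | None
    pair_3_70: tuple[str, str] | None
    pair_11_24: tuple[str, str] | None
    pair_12_23: tuple[str, str] | None
    cca_present: bool


@dataclass(frozen=True)
class AnnotatedTRNA:
    """A parsed cloverleaf: arm spans, canonical numbering and pairs.

    ``arm_spans`` maps region names to half-open 0-based index
    intervals, disjoint and in 5'->3' order, covering the sequence.
    ``position_map`` maps canonical positions (1-based) to sequence
    indices for every numbered residue; variable-region and D-loop
    residues carry no canonical number.
    """

    record: TRNARecord
    arm_spans: Mapping[str, tuple[int, int]]
    position_map: Mapping[int, int]
    pairs: tuple[BasePair, ...]
    cca_present: bool

    @property
    def sequence(self) -> str:
        return self.record.sequence

    def residue(self, position: int) -> str | None:
        """Residue at a canonical position, or None if unnumbered."""
        idx = self.position_map.get(position)
        return None if idx is None else self.sequence[idx]

    def pair_at(self, pos5: int, pos3: int) -> BasePair | None:
        for pair in self.pairs:
            if pair.pos5 == pos5 and pair.pos3 == pos3:
                return pair
        return None

    def to_json(self, indent: int | None = 2) -> str:
        """Serialize the annotation (spans, numbering, pairs) to JSON."""
        payload = {
            "id": self.record.id,
            "sequence": self.sequence,
            "source": self.record.source,
            "cca_present": self.cca_present,
            "arm_spans": {k: list(v) for k, v in self.arm_spans.items()},
            "position_map": {str(k): v for k, v in sorted(self.position_map.items())},
            "pairs": [
                {"pos5": p.pos5, "pos3": p.pos3, "bases": list(p.bases), "kind": p.kind}
                for p in self.pairs
            ],
        }
        return json.dumps(payload, indent=indent)


def _acceptor_pairs(seq: str, disc: int) -> list[BasePair]:
    # canonical k (1..7) pairs canonical 73-k; canonical 66+m sits at disc-7+m
    return [
        BasePair(k, 73 - k, (seq[k - 1], seq[disc - k])) for k in range(1, 8)
    ]


def _count_paired(pairs: Sequence[BasePair]) -> int:
    return sum(1 for p in pairs if p.kind != "mismatch")


def parse_cloverleaf(record: TRNARecord) -> AnnotatedTRNA:
    """Assign cloverleaf arms and canonical numbering to a tRNA.

    The parse is anchored at the 3' end (CCA / discriminator / acceptor
    3' strand / T-arm are placed by template) and scans the D-loop
    length on the 5' side, choosing the architecture that maximizes the
    number of paired (watson-crick or wobble) positions in the D- and
    anticodon stems.  Ties prefer the canonical geometry: 4-bp D-stem,
    D-loop length closest to 8.

    Raises
    ------
    CloverleafParseError
        If fewer than 5 of the 7 acceptor-stem positions pair, or no
        D-arm/anticodon-arm architecture with a well-paired anticodon
        stem (>= 4 of 5 positions) fits between position 10 and the
        T-arm.
    """
    seq = record.sequence
    n = len(seq)
    cca_present = seq.endswith("CCA")
    disc = n - 4 if cca_present else n - 1

    acc_pairs = _acceptor_pairs(seq, disc)
    if _count_paired(acc_pairs) < 5:
        raise CloverleafParseError(
            f"{record.id!r}: acceptor stem has only {_count_paired(acc_pairs)}"
            " of 7 paired positions (need >= 5)"
        )

    acc3_start = disc - 7
    t_start = acc3_start - 17
    if t_start < 9 + 10 + 1 + 17:
        raise CloverleafParseError(
            f"{record.id!r}: sequence too short for T-arm and 5' arms"
        )

    best: tuple | None = None
    # Candidates ordered so that the first maximum wins ties:
    # canonical 8-nt D-loop first, then nearer loop lengths, 4-bp stem
    # before 3-bp.
    loop_order = sorted(range(4, 13), key=lambda L: (abs(L - 8), L))
    for stem in (4, 3):
        for dloop in loop_order:
            d3_start = 9 + stem + dloop
            d3_end = d3_start + stem
            ac_start = d3_end + 1  # single-nt hinge, canonical 26
            ac_end = ac_start + 17
            if ac_end > t_start:
                continue
            d_pairs = [
                BasePair(
                    10 + k,
                    25 - k,
                    (seq[9 + k], seq[d3_end - 1 - k]),
                )
                for k in range(stem)
            ]
            ac_pairs = [
                BasePair(27 + k, 43 - k, (seq[ac_start + k], seq[ac_end - 1 - k]))
                for k in range(5)
            ]
            n_d = _count_paired(d_pairs)
            n_ac = _count_paired(ac_pairs)
            if n_ac < 4 or n_d < stem - 1:
                continue
            score = n_d + n_ac
            if best is None or score > best[0]:
                best = (score, stem, dloop, d3_start, d3_end, ac_start, ac_end,
                        d_pairs, ac_pairs)
    if best is None:
        raise CloverleafParseError(
            f"{record.id!r}: no D-arm/anticodon-arm architecture found"
        )
    _, stem, dloop, d3_start, d3_end, ac_start, ac_end, d_pairs, ac_pairs = best

    t_pairs = [
        BasePair(49 + k, 65 - k, (seq[t_start + k], seq[t_start + 16 - k]))
        for k in range(5)
    ]

    position_map: dict[int, int] = {}
    for k in range(1, 8):
        position_map[k] = k - 1
    position_map[8] = 7
    position_map[9] = 8
    # D-stem: 5' strand always starts at canonical 10; a 3-bp stem lacks
    # the innermost 13:22 pair, so its 3' strand is 23-25.
    for k in range(stem):
        position_map[10 + k] = 9 + k
        position_map[25 - k] = d3_end - 1 - k
    position_map[26] = d3_end
    for k in range(17):
        position_map[27 + k] = ac_start + k
    for k in range(17):
        position_map[49 + k] = t_start + k
    for m in range(7):
        position_map[66 + m] = acc3_start + m
    position_map[73] = disc
    if cca_present:
        position_map[74] = disc + 1
        position_map[75] = disc + 2
        position_map[76] = disc + 3

    arm_spans: dict[str, tuple[int, int]] = {
        "acceptor_5p": (0, 7),
        "connector_8_9": (7, 9),
        "d_arm": (9, d3_end),
        "hinge_26": (d3_end, ac_start),
        "anticodon_arm": (ac_start, ac_end),
        "variable_region": (ac_end, t_start),
        "t_arm": (t_start, t_start + 17),
        "acceptor_3p": (acc3_start, disc),
        "discriminator": (disc, disc + 1),
    }
    if cca_present:
        arm_spans["cca"] = (disc + 1, n)

    pairs = tuple(acc_pairs + d_pairs + ac_pairs + t_pairs)
    return AnnotatedTRNA(
        record=record,
        arm_spans=arm_spans,
        position_map=position_map,
        pairs=pairs,
        cca_present=cca_present,
    )


def element_profile(annotated: AnnotatedTRNA) -> IdentityElementProfile:
    """Read the NSun6 identity elements off an annotated tRNA.

    Positions missing from the numbering (e.g. 13:22 in a 3-bp D-stem)
    are reported as ``None``, never as an error.
    """

    def pair_values(pos5: int, pos3: int) -> tuple[str, str] | None:
        r5 = annotated.residue(pos5)
        r3 = annotated.residue(pos3)
        if r5 is None or r3 is None:
            return None
        return (r5, r3)

    return IdentityElementProfile(
        n72=annotated.residue(72),
        n73=annotated.residue(73),
        pair_2_71=pair_values(2, 71),
        pair_3_70=pair_values(3, 70),
        pair_11_24=pair_values(11, 24),
        pair_12_23=pair_values(12, 23),
        cca_present=annotated.cca_present,
    )


def _reparse(annotated: AnnotatedTRNA, new_sequence: str, note: str) -> AnnotatedTRNA:
    record = replace(
        annotated.record,
        sequence=new_sequence,
        source=(annotated.record.source + "; " + note).strip("; "),
    )
    return parse_cloverleaf(record)


def apply_point_mutation(
    annotated: AnnotatedTRNA, position: int, base: str
) -> AnnotatedTRNA:
    """Replace the residue at a canonical position and re-parse.

    Exactly one residue of the raw sequence changes (or none, for an
    identity mutation).
    """
    base = normalize_sequence(base)
    if base not in RNA_ALPHABET:
        raise AlphabetError(f"invalid residue {base!r}")
    idx = annotated.position_map.get(position)
    if idx is None:
        raise TRNAError(f"canonical position {position} is not numbered here")
    seq = annotated.sequence
    new_seq = seq[:idx] + base + seq[idx + 1 :]
    old = seq[idx]
    return _reparse(annotated, new_seq, f"{old}{position}{base}")


def apply_pair_swap(
    annotated: AnnotatedTRNA,
    pos5: int,
    pos3: int,
    new5: str,
    new3: str,
) -> AnnotatedTRNA:
    """Replace both residues of an annotated base pair and re-parse."""
    if annotated.pair_at(pos5, pos3) is None:
        raise TRNAError(f"{pos5}:{pos3} is not an annotated base pair")
    new5 = normalize_sequence(new5)
    new3 = normalize_sequence(new3)
    if new5 not in RNA_ALPHABET or new3 not in RNA_ALPHABET:
        raise AlphabetError(f"invalid residues {new5!r}/{new3!r}")
    i5 = annotated.position_map[pos5]
    i3 = annotated.position_map[pos3]
    seq = list(annotated.sequence)
    old5, old3 = seq[i5], seq[i3]
    seq[i5], seq[i3] = new5, new3
    note = f"{old5}{pos5}{new5}:{old3}{pos3}{new3}"
    return _reparse(annotated, "".join(seq), note)


def delete_cca(annotated: AnnotatedTRNA) -> AnnotatedTRNA:
    """Remove the 3'-terminal CCA; the former discriminator remains 73."""
    if not annotated.cca_present:
        raise TRNAError(f"{annotated.record.id!r} has no CCA terminus to delete")
    truncated = annotated.sequence[:-3]
    if truncated.endswith("CCA"):
        # residues 71-73 spell C,C,A: the deletion product would be
        # re-read as CCA-terminated, so the operation is ill-defined
        raise TRNAError(
            f"{annotated.record.id!r}: residues 71-73 read 'CCA'; the "
            "deletion product cannot be distinguished from a "
            "CCA-terminated tRNA"
        )
    return _reparse(annotated, truncated, "dCCA")


def extinction_coefficient_260(record: TRNARecord | str) -> float:
    """Molar absorptivity at 260 nm (M^-1 cm^-1) from base composition.

    Additive over the sequence: sum of fixed per-monomer coefficients
    (AMP 15400, CMP 7400, GMP 11500, UMP 9900), no hypochromicity
    correction.  Used to convert A260 to transcript concentration.
    Accepts a :class:`TRNARecord` or a bare sequence string.
    """
    seq = record.sequence if isinstance(record, TRNARecord) else normalize_sequence(record)
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-RNA residues: {sorted(bad)}")
    return float(sum(MONOMER_EPSILON_260[b] for b in seq))
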