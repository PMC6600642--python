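"""Synthetic sequence families with controlled conservation and indels.

Emulates a curated family of motor-domain sequences: most members share the
reference's exact domain length (a dominant modal length), a controlled
fraction carry insertions or deletions at declared positions, and individual
columns mutate by plain substitution or by acidic/basic charge swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CANONICAL_RESIDUES",
    "ACIDIC",
    "BASIC",
    "IndelSpec",
    "SyntheticSequenceFamily",
    "generate_sequence_family",
    "family_alignment",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ACIDIC = frozenset("DE")
BASIC = frozenset("HKR")


@dataclass(frozen=True)
class IndelSpec:
    """One indel event assigned to a fraction of the family.

    position : 1-based residue position in the reference where the event
        applies (deletion starts there; insertion is placed after it).
    length   : number of residues deleted or inserted (>= 1).
    kind     : "insertion" or "deletion".
    fraction : fraction of sequences carrying the event (0..1).
    residues : inserted residues; generated randomly when empty.
    """

    position: int
    length: int
    kind: str
    fraction: float
    residues: str = ""

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"indel kind must be insertion|deletion, got {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("indel fraction must lie in [0, 1]")
        if self.residues and len(self.residues) != self.length:
            raise ValueError("residues string must match indel length")


@dataclass
class SyntheticSequenceFamily:
    ids: list
    sequences: list                  # ungapped amino-acid strings
    reference: str
    true_indels: dict                # sequence index -> list of (pos, len, kind)
    substitution_rate: float
    charge_swap_rate: float
    charge_swap_columns: tuple       # 1-based reference positions eligible for swaps
    seed: int
    true_domain_spans: dict = field(default_factory=dict)  # name -> (start, end)


def _validate_reference(reference):
    for i, aa in enumerate(reference):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(
                f"non-canonical residue {aa!r} at reference position {i + 1}"
            )


def generate_sequence_family(
    reference,
    n,
    substitution_rate=0.0,
    charge_swap_rate=0.0,
    charge_swap_columns=None,
    indel_spec=(),
    domain_spans=None,
    seed=0,
):
    """Generate ``n`` sequences derived from ``reference`` with ground truth.

    Substitutions hit each column independently at ``substitution_rate`` and
    replace the residue by a uniformly drawn different canonical residue.
    Charge swaps act on ``charge_swap_columns`` (default: every acidic/basic
    reference column) at ``charge_swap_rate``, exchanging D/E for a random
    residue of H/K/R and vice versa. Indels are assigned to the first
    ``round(fraction * n)`` sequences of a random permutation, so the realized
    count is exact, not binomial. Fixed seed gives byte-identical output.
    """
    _validate_reference(reference)
    if n < 1:
        raise ValueError("n must be >= 1")
    for rate, name in ((substitution_rate, "substitution_rate"),
                       (charge_swap_rate, "charge_swap_rate")):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    indel_spec = tuple(indel_spec)
    L = len(reference)
    for spec in indel_spec:
        if not 1 <= spec.position <= L:
            raise ValueError(f"indel position {spec.position} outside reference 1..{L}")
        if spec.kind == "deletion" and spec.position + spec.length - 1 > L:
            raise ValueError("deletion extends past the reference end")
    if domain_spans:
        for name, (start, end) in domain_spans.items():
            if not (1 <= start <= end <= L):
                raise ValueError(f"domain {name} span {start}..{end} outside reference")
        for spec in indel_spec:
            inside = any(s <= spec.position <= e for s, e in domain_spans.values())
            if not inside:
                raise ValueError(
                    f"indel position {spec.position} lies outside declared domains"
                )

    rng = np.random.default_rng(seed)
    if charge_swap_columns is None:
        charge_swap_columns = tuple(
            i + 1 for i, aa in enumerate(reference) if aa in ACIDIC | BASIC
        )
    else:
        charge_swap_columns = tuple(int(c) for c in charge_swap_columns)
    swap_cols = set(charge_swap_columns)

    # Exact indel carrier assignment per spec'd fraction.
    carriers = {}  # sequence index -> list of IndelSpec
    for spec in indel_spec:
        k = int(round(spec.fraction * n))
        chosen = rng.permutation(n)[:k]
        for idx in chosen:
            carriers.setdefault(int(idx), []).append(spec)

    basic = sorted(BASIC)
    acidic = sorted(ACIDIC)
    ids, sequences, true_indels = [], [], {}
    for i in range(n):
        residues = list(reference)
        # substitutions
        if substitution_rate > 0:
            hits = np.nonzero(rng.random(L) < substitution_rate)[0]
            for j in hits:
                choices = [aa for aa in CANONICAL_RESIDUES if aa != residues[j]]
                residues[j] = choices[rng.integers(len(choices))]
        # charge swaps on eligible columns
        if charge_swap_rate > 0 and swap_cols:
            for col in swap_cols:
                if rng.random() < charge_swap_rate:
                    aa = residues[col - 1]
                    if aa in ACIDIC:
                        residues[col - 1] = basic[rng.integers(len(basic))]
                    elif aa in BASIC:
                        residues[col - 1] = acidic[rng.integers(len(acidic))]
        # indels, applied right-to-left so positions stay valid
        events = sorted(carriers.get(i, []), key=lambda s: -s.position)
        for spec in events:
            p = spec.position
            if spec.kind == "deletion":
                del residues[p - 1 : p - 1 + spec.length]
            else:
                ins = spec.residues or "".join(
                    CANONICAL_RESIDUES[k]
                    for k in rng.integers(len(CANONICAL_RESIDUES), size=spec.length)
                )
                residues[p:p] = list(ins)
        if events:
            true_indels[i] = [(s.position, s.length, s.kind) for s in events]
        ids.append(f"synth{i:04d}")
        sequences.append("".join(residues))

    return SyntheticSequenceFamily(
        ids=ids,
        sequences=sequences,
        reference=reference,
        true_indels=true_indels,
        substitution_rate=float(substitution_rate),
        charge_swap_rate=float(charge_swap_rate),
        charge_swap_columns=charge_swap_columns,
        seed=int(seed),
        true_domain_spans=dict(domain_spans or {}),
    )


def family_alignment(family):
    """Exact multiple alignment of a synthetic family from its ground truth.

    No aligner is run: because every sequence derives from the reference by
    recorded point mutations and indels, the true alignment is known.
    Columns are the reference positions; each insertion site adds a block of
    extra columns (width = longest insertion there), left-aligned and
    gap-padded. The returned object is a
    :class:`~dynstalk.seqcons.MultipleAlignment` whose first row is the
    reference itself.
    """
    from ..seqcons import GAP, MultipleAlignment

    L = len(family.reference)
    # Insertion block widths per reference position.
    ins_width = {}
    for events in family.true_indels.values():
        for pos, length, kind in events:
            if kind == "insertion":
                ins_width[pos] = max(ins_width.get(pos, 0), length)

    def build_row(seq, events):
        deletions = {}
        insertions = {}
        for pos, length, kind in events:
            if kind == "deletion":
                for p in range(pos, pos + length):
                    deletions[p] = True
            else:
                insertions[pos] = length
        out = []
        cursor = 0  # index into the ungapped sequence
        for p in range(1, L + 1):
            if deletions.get(p):
                out.append(GAP)
            else:
                out.append(seq[cursor])
                cursor += 1
            width = ins_width.get(p, 0)
            if width:
                k = insertions.get(p, 0)
                out.append(seq[cursor:cursor + k] + GAP * (width - k))
                cursor += k
        return "".join(out)

    ids = ["reference"] + list(family.ids)
    rows = [build_row(family.reference, [])]
    for i, seq in enumerate(family.sequences):
        rows.append(build_row(seq, family.true_indels.get(i, [])))
    return MultipleAlignment(ids=ids, rows=rows)
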