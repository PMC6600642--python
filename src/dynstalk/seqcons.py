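"""Stalk sequence curation, domain delineation, and conservation metrics.

The stalk of the dynein motor domain is an antiparallel coiled-coil (helices
CC1 and CC2) whose *length* is far better conserved across dyneins than its
sequence. This module provides the analyses behind that observation:

* rule-based curation of a heavy-chain sequence set, with a rejection log;
* delineation of domains (CC1, CC2, ...) in a multiple alignment from
  anchor residues of a reference sequence;
* per-domain ungapped length distributions (histogram, modal length and the
  fraction of sequences at the modal length);
* per-column conservation metrics: an AMAS-style 0-10 physicochemical
  property score (the Taylor/Zvelebil property set, as popularized by
  Jalview's conservation track), hydrophobic fraction, charge variation
  (the minority fraction among acidic D/E versus basic H/K/R residues) and
  a charge consensus call;
* design of insertion/deletion mutants within an annotated domain.

Alignments are consumed, not produced: run your aligner of choice upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAP",
    "AMAS_PROPERTIES",
    "DEFAULT_HYDROPHOBIC",
    "MultipleAlignment",
    "read_alignment",
    "CurationRule",
    "standard_rules",
    "curate_sequences",
    "DomainAnnotation",
    "delineate_domain",
    "LengthDistribution",
    "domain_length_distribution",
    "ColumnConservation",
    "ConservationProfile",
    "conservation_profile",
    "IndelMutantDesign",
    "design_indel_mutants",
]

GAP = "-"
ACIDIC = frozenset("DE")
BASIC = frozenset("HKR")

# Taylor/Zvelebil boolean physicochemical properties (the AMAS set used by
# Jalview's conservation annotation).
AMAS_PROPERTIES = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "polar": frozenset("YWHKREQDNST"),
    "small": frozenset("VCAGDNSTP"),
    "tiny": frozenset("AGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FYWH"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("HKRDE"),
    "proline": frozenset("P"),
}

# Hydrophobic set for the hydrophobic-fraction track (Kyte-Doolittle-like).
DEFAULT_HYDROPHOBIC = frozenset("ACFILMVWY")


@dataclass
class MultipleAlignment:
    """Aligned rows over the 20 residues plus the gap character."""

    ids: list
    rows: list
    n_columns: int = field(init=False)

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence identifiers must be unique")
        self.n_columns = len(self.rows[0])

    def row(self, seq_id):
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def column(self, col):
        """1-based column as a string over all rows."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside 1..{self.n_columns}")
        return "".join(r[col - 1] for r in self.rows)

    def write_fasta(self, path):
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def read_alignment(path, fmt=None):
    """Read an aligned FASTA or Stockholm file (Bio.AlignIO behind the scenes)."""
    from Bio import AlignIO

    if fmt is None:
        fmt = "stockholm" if str(path).endswith((".sto", ".stk", ".stockholm")) \
            else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MultipleAlignment(
        ids=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
    )


# ---------------------------------------------------------------------------
# Curation

@dataclass(frozen=True)
class CurationRule:
    """A named predicate; ``check`` returns None when a record passes, else a
    short reason string."""

    name: str
    check: callable


def standard_rules(min_length=1000, max_length=6000, max_x_fraction=0.01):
    """Default heavy-chain curation rules: length window and ambiguity cap."""
    def length_rule(seq):
        n = len(seq)
        if not min_length <= n <= max_length:
            return f"length {n} outside {min_length}..{max_length}"
        return None

    def ambiguity_rule(seq):
        if not seq:
            return "empty sequence"
        frac = seq.count("X") / len(seq)
        if frac > max_x_fraction:
            return f"X fraction {frac:.3f} > {max_x_fraction}"
        return None

    return [
        CurationRule("length", length_rule),
        CurationRule("ambiguity", ambiguity_rule),
    ]


def curate_sequences(records, rules=None, dedup=True):
    """Filter (id, sequence) records through a rule list, order-preserving.

    Returns ``(retained, rejections)`` where each rejection is
    ``(id, rule_name, reason)`` for the first rule that failed. Exact
    duplicates (after the first occurrence) are rejected under rule name
    ``"duplicate"`` when ``dedup`` is on. The active rule set should be
    recorded alongside any downstream result.
    """
    records = list(records)
    if not records:
        raise ValueError("no sequence records supplied")
    rules = list(rules) if rules is not None else standard_rules()
    retained, rejections = [], []
    seen = set()
    for sid, seq in records:
        seq = str(seq).upper()
        reason = None
        for rule in rules:
            msg = rule.check(seq)
            if msg is not None:
                reason = (sid, rule.name, msg)
                break
        if reason is None and dedup:
            if seq in seen:
                reason = (sid, "duplicate", "exact duplicate of earlier record")
        if reason is None:
            retained.append((sid, seq))
            seen.add(seq)
        else:
            rejections.append(reason)
    return retained, rejections


# ---------------------------------------------------------------------------
# Domain delineation and length statistics

@dataclass
class DomainAnnotation:
    name: str
    reference_id: str
    anchor_start: int   # 1-based reference residue numbers
    anchor_end: int
    column_span: tuple  # 1-based inclusive alignment columns

    def columns(self):
        return range(self.column_span[0], self.column_span[1] + 1)


def _residue_to_column(row, residue_number):
    """Alignment column (1-based) of the reference's n-th non-gap character."""
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            count += 1
            if count == residue_number:
                return col
    raise ValueError(
        f"anchor residue {residue_number} beyond reference length {count}"
    )


def delineate_domain(alignment, reference_id, name, anchor_start, anchor_end):
    """Map reference anchor residues to an alignment column span.

    Anchors are 1-based residue numbers of the (ungapped) reference row; the
    returned span covers the columns of residues ``anchor_start`` through
    ``anchor_end`` inclusive, skipping reference gaps in the count.
    """
    if anchor_start < 1 or anchor_end < anchor_start:
        raise ValueError("anchors must satisfy 1 <= anchor_start <= anchor_end")
    row = alignment.row(reference_id)
    start_col = _residue_to_column(row, anchor_start)
    end_col = _residue_to_column(row, anchor_end)
    return DomainAnnotation(
        name=name, reference_id=reference_id,
        anchor_start=int(anchor_start), anchor_end=int(anchor_end),
        column_span=(start_col, end_col),
    )


@dataclass
class LengthDistribution:
    domain: str
    lengths: np.ndarray      # per-sequence ungapped residue counts
    histogram: dict          # length -> count
    modal_length: int
    modal_fraction: float
    tie_broken: bool = False

    def summary(self):
        return {
            "domain": self.domain,
            "n_sequences": int(self.lengths.size),
            "modal_length": int(self.modal_length),
            "modal_fraction": float(self.modal_fraction),
            "histogram": {int(k): int(v) for k, v in sorted(self.histogram.items())},
        }


def domain_length_distribution(alignment, annotation, domain_name=None):
    """Per-sequence ungapped lengths within an annotated column span.

    ``annotation`` may be one DomainAnnotation or a sequence of them (their
    column spans are combined — e.g. CC1 + CC2 for the full stalk). Mode
    ties break toward the smaller length, deterministically.
    """
    annotations = (annotation,) if isinstance(annotation, DomainAnnotation) \
        else tuple(annotation)
    cols = []
    for ann in annotations:
        cols.extend(ann.columns())
    lengths = np.array([
        sum(1 for c in cols if row[c - 1] != GAP) for row in alignment.rows
    ])
    values, counts = np.unique(lengths, return_counts=True)
    top = counts.max()
    candidates = values[counts == top]
    modal = int(candidates.min())          # tie -> smaller length
    name = domain_name or "+".join(a.name for a in annotations)
    return LengthDistribution(
        domain=name,
        lengths=lengths,
        histogram=dict(zip(values.tolist(), counts.tolist())),
        modal_length=modal,
        modal_fraction=float(top / lengths.size),
        tie_broken=bool(candidates.size > 1),
    )


# ---------------------------------------------------------------------------
# Conservation metrics

@dataclass
class ColumnConservation:
    column: int
    amas_score: int = None            # 0-10 conserved properties
    identity: bool = False
    hydrophobic_fraction: float = None
    charge_variation: float = None
    charge_consensus: str = None      # acidic | basic | mixed | none
    n_residues: int = 0
    all_gap: bool = False


@dataclass
class ConservationProfile:
    columns: list                     # ColumnConservation records
    gap_policy: str
    hydrophobic_set: frozenset

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(c) for c in self.columns])


def _amas_score(residues):
    score = 0
    for members in AMAS_PROPERTIES.values():
        inside = sum(1 for r in residues if r in members)
        if inside == 0 or inside == len(residues):
            score += 1
    return score


def conservation_profile(alignment, column_range=None, gap_policy="exclude",
                         hydrophobic_set=DEFAULT_HYDROPHOBIC,
                         consensus_threshold=0.5):
    """Per-column conservation metrics over a 1-based inclusive column range.

    ``gap_policy``: "exclude" drops gaps from a column before scoring;
    "strict" treats any gap as breaking identity and every property (the
    column scores 0 and identity is False if a gap is present). Columns
    that are entirely gaps are emitted flagged, with metrics missing.
    """
    if gap_policy not in ("exclude", "strict"):
        raise ValueError("gap_policy must be 'exclude' or 'strict'")
    if column_range is None:
        column_range = (1, alignment.n_columns)
    lo, hi = column_range
    records = []
    for col in range(lo, hi + 1):
        column = alignment.column(col)
        residues = [c for c in column if c != GAP]
        has_gap = len(residues) < len(column)
        if not residues:
            records.append(ColumnConservation(column=col, all_gap=True))
            continue
        if gap_policy == "strict" and has_gap:
            records.append(ColumnConservation(
                column=col, amas_score=0, identity=False,
                hydrophobic_fraction=_frac(residues, hydrophobic_set),
                charge_variation=_charge_variation(residues),
                charge_consensus=_charge_consensus(residues, consensus_threshold),
                n_residues=len(residues),
            ))
            continue
        records.append(ColumnConservation(
            column=col,
            amas_score=_amas_score(residues),
            identity=len(set(residues)) == 1,
            hydrophobic_fraction=_frac(residues, hydrophobic_set),
            charge_variation=_charge_variation(residues),
            charge_consensus=_charge_consensus(residues, consensus_threshold),
            n_residues=len(residues),
        ))
    return ConservationProfile(
        columns=records, gap_policy=gap_policy,
        hydrophobic_set=frozenset(hydrophobic_set),
    )


def _frac(residues, members):
    return sum(1 for r in residues if r in members) / len(residues)


def _charge_variation(residues):
    """Minority-class fraction among charged residues: min(n_D/E, n_H/K/R)/n.

    Zero when either charge class is absent; bounded by 0.5. Symmetric under
    exchanging the acidic and basic sets.
    """
    n_acid = sum(1 for r in residues if r in ACIDIC)
    n_base = sum(1 for r in residues if r in BASIC)
    if n_acid == 0 or n_base == 0:
        return 0.0
    return min(n_acid, n_base) / len(residues)


def _charge_consensus(residues, threshold):
    frac_acid = _frac(residues, ACIDIC)
    frac_base = _frac(residues, BASIC)
    acid = frac_acid >= threshold
    base = frac_base >= threshold
    if acid and base:
        return "mixed"
    if acid:
        return "acidic"
    if base:
        return "basic"
    if frac_acid > 0 and frac_base > 0:
        return "mixed" if min(frac_acid, frac_base) >= threshold else "none"
    return "none"


# ---------------------------------------------------------------------------
# Indel mutant design

@dataclass
class IndelMutantDesign:
    mutant_id: str
    location: str            # domain name (e.g. CC1, CC2)
    position: int            # 1-based reference residue number
    delta: int               # +insertion / -deletion residue count
    inserted_residues: str
    mutated_sequence: str


def design_indel_mutants(reference_seq, annotation, requests):
    """Apply insertion/deletion requests to a reference sequence.

    Each request is ``(mutant_id, position, delta, inserted_residues)`` with
    ``delta > 0`` inserting ``inserted_residues`` after ``position`` and
    ``delta < 0`` deleting ``|delta|`` residues starting at ``position``.
    Positions must lie within the annotated domain's anchor range and
    deletions may not run past its end.
    """
    lo, hi = annotation.anchor_start, annotation.anchor_end
    designs = []
    for mutant_id, position, delta, inserted in requests:
        if delta == 0:
            raise ValueError(f"{mutant_id}: delta must be non-zero")
        if not lo <= position <= hi:
            raise ValueError(
                f"{mutant_id}: position {position} outside {annotation.name} "
                f"({lo}..{hi})"
            )
        if delta > 0:
            if len(inserted) != delta:
                raise ValueError(
                    f"{mutant_id}: inserted_residues length {len(inserted)} "
                    f"!= delta {delta}"
                )
            mutated = reference_seq[:position] + inserted + reference_seq[position:]
        else:
            if position + (-delta) - 1 > hi:
                raise ValueError(
                    f"{mutant_id}: deletion of {-delta} at {position} extends "
                    f"past {annotation.name} end {hi}"
                )
            inserted = ""
            mutated = reference_seq[:position - 1] + reference_seq[position - 1 - delta:]
        designs.append(IndelMutantDesign(
            mutant_id=str(mutant_id), location=annotation.name,
            position=int(position), delta=int(delta),
            inserted_residues=inserted, mutated_sequence=mutated,
        ))
    return designs
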