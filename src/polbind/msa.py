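"""Alignment-based conservation and substitution-frequency analysis.

Given an aligned set of Y-family polymerase homologs with a designated
reference sequence (Dbh), this module classifies each ungapped reference
position as conserved or non-conserved and tabulates, for the non-conserved
positions, which residues the homologs carry and how often — the
"mutability" table that candidate mutations are drawn from.

Counting rules:

* identity between two aligned sequences is computed over columns where
  neither sequence has a gap; homolog inclusion is strict (> 40% by
  default);
* per-column counts cover the non-reference sequences only, and gaps are
  tallied separately so that counts + gaps always equal n − 1;
* "non-conserved" means more than ``max_nonref_fraction`` (default 5%) of
  the non-gap homolog residues differ from the reference residue;
* substitution frequencies are reported as raw counts, e.g. ``R/28``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import AlphabetError, ContractError, FormatError, ResidueLookupError

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


@dataclass
class Alignment:
    """Aligned amino-acid records with one designated reference."""

    records: list[tuple[str, str]]  # (id, aligned sequence)
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if self.reference_id not in ids:
            raise ResidueLookupError(
                f"reference id {self.reference_id!r} not in alignment"
            )
        for rid, seq in self.records:
            bad = set(seq) - AA_ALPHABET - {GAP}
            if bad:
                raise AlphabetError(
                    f"record {rid!r} contains non-amino-acid characters {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    @property
    def reference(self) -> str:
        return dict(self.records)[self.reference_id]

    @property
    def reference_sequence(self) -> str:
        """Ungapped reference sequence."""
        return self.reference.replace(GAP, "")

    def non_reference(self) -> list[tuple[str, str]]:
        return [(rid, seq) for rid, seq in self.records if rid != self.reference_id]


@dataclass
class ColumnProfile:
    """Residue composition of one ungapped reference position."""

    position: int            # 1-based over the ungapped reference
    ref_residue: str
    counts: dict[str, int] = field(default_factory=dict)
    gap_count: int = 0

    @property
    def n_nonref(self) -> int:
        return sum(self.counts.values()) + self.gap_count


def read_alignment(path: str | Path, reference_id: str) -> Alignment:
    """Read an aligned FASTA file and flag the reference record."""
    from Bio import SeqIO

    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    return Alignment(records, reference_id)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over columns where neither has a gap."""
    if len(a) != len(b):
        raise ContractError("aligned sequences differ in length")
    comparable = matches = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            matches += 1
    return matches / comparable if comparable else 0.0


def filter_homologs(aln: Alignment, min_identity: float = 0.40) -> Alignment:
    """Keep the reference plus records strictly above ``min_identity`` to it."""
    ref = aln.reference
    kept = [
        (rid, seq)
        for rid, seq in aln.records
        if rid == aln.reference_id or pairwise_identity(seq, ref) > min_identity
    ]
    return Alignment(kept, aln.reference_id)


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """One profile per ungapped reference position.

    Columns where the reference has a gap produce no profile; gaps in the
    homologs are counted separately from residues.
    """
    ref = aln.reference
    if ref.count(GAP) == len(ref):
        raise ContractError("reference sequence is all gaps")
    others = [seq for _, seq in aln.non_reference()]
    profiles: list[ColumnProfile] = []
    pos = 0
    for col, ref_res in enumerate(ref):
        if ref_res == GAP:
            continue
        pos += 1
        counts: dict[str, int] = {}
        gaps = 0
        for seq in others:
            res = seq[col]
            if res == GAP:
                gaps += 1
            else:
                counts[res] = counts.get(res, 0) + 1
        profiles.append(ColumnProfile(pos, ref_res, counts, gaps))
    return profiles


def classify_conservation(profile: ColumnProfile,
                          max_nonref_fraction: float = 0.05) -> bool:
    """True (conserved) iff ≤ ``max_nonref_fraction`` of the non-gap homolog
    residues differ from the reference residue.  Columns with no non-gap
    homolog residues carry no evidence of variation and count as conserved."""
    nongap = sum(profile.counts.values())
    if nongap == 0:
        return True
    differing = sum(c for res, c in profile.counts.items() if res != profile.ref_residue)
    return differing / nongap <= max_nonref_fraction


def ranked_substitutions(profile: ColumnProfile) -> list[tuple[str, int]]:
    """Observed substitutions sorted by count descending, ties alphabetical.

    The reference residue itself is never listed as a substitution.
    """
    subs = [
        (res, c) for res, c in profile.counts.items()
        if res != profile.ref_residue and c > 0
    ]
    subs.sort(key=lambda rc: (-rc[1], rc[0]))
    return subs
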