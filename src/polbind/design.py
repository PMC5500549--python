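"""Mutation-site selection, mutant sequences, and fusion assembly.

Candidate mutation sites are the intersection of two criteria: the residue
sits in the DNA contact shell (within 6 Å of the duplex) and its alignment
column is non-conserved.  Each candidate carries the ranked substitutions
observed among homologs; the top pick is the highest-frequency residue.
Maximal runs of consecutive candidates become block mutations such as
KSKIP(241–245)RVRKS.  The module also expands linker notation like
``SS(GGGGS)_3_GM`` and assembles N-domain/linker/C-domain fusion sequences
(the Sso7d–Dbh construct).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import GrammarError, MappingError, ValidationError
from .msa import ColumnProfile, classify_conservation, ranked_substitutions
from .structure import ContactShell

EN_DASH = "–"


@dataclass
class CandidateRow:
    position: int
    wt_residue: str
    substitutions: list[tuple[str, int]]   # ranked: count desc, ties alphabetical
    conserved: bool
    min_dna_distance: float | None = None

    @property
    def top_pick(self) -> str | None:
        return self.substitutions[0][0] if self.substitutions else None


@dataclass
class CandidateTable:
    rows: list[CandidateRow] = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [r.position for r in self.rows],
                "wt_aa": [r.wt_residue for r in self.rows],
                "substitutions": [
                    ", ".join(f"{res}/{c}" for res, c in r.substitutions)
                    for r in self.rows
                ],
                "min_dist_A": [
                    "" if r.min_dna_distance is None else f"{r.min_dna_distance:.4f}"
                    for r in self.rows
                ],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class MutationSpec:
    """One or more point substitutions in reference (1-based) coordinates."""

    substitutions: list[tuple[int, str, str]]  # (position, wt, new)
    label: str = ""

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.substitutions]
        if sorted(set(positions)) != positions:
            raise ValidationError("substitution positions must be unique and ascending")
        if not self.label:
            self.label = render_label(self.substitutions)


@dataclass
class FusionDesign:
    n_domain: str
    linker_notation: str
    linker: str
    c_domain: str

    @property
    def fused(self) -> str:
        return self.n_domain + self.linker + self.c_domain


def render_label(substitutions: list[tuple[int, str, str]]) -> str:
    """Human-readable label: "M76I" or "KSKIP(241–245)RVRKS" for a block."""
    if len(substitutions) == 1:
        p, wt, new = substitutions[0]
        return f"{wt}{p}{new}"
    positions = [p for p, _, _ in substitutions]
    if positions == list(range(positions[0], positions[-1] + 1)):
        wt_run = "".join(wt for _, wt, _ in substitutions)
        new_run = "".join(new for _, _, new in substitutions)
        return f"{wt_run}({positions[0]}{EN_DASH}{positions[-1]}){new_run}"
    return "+".join(f"{wt}{p}{new}" for p, wt, new in substitutions)


_SINGLE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_BLOCK_RE = re.compile(r"^([A-Z]+)\((\d+)[-–](\d+)\)([A-Z]+)$")


def parse_mutation_label(label: str) -> MutationSpec:
    """Parse "M76I" or "KSKIP(241-245)RVRKS" (hyphen or en dash) labels."""
    label = label.strip()
    m = _SINGLE_RE.match(label)
    if m:
        wt, pos, new = m.group(1), int(m.group(2)), m.group(3)
        return MutationSpec([(pos, wt, new)], label)
    m = _BLOCK_RE.match(label)
    if m:
        wt_run, start, end, new_run = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
        if end - start + 1 != len(wt_run) or len(wt_run) != len(new_run):
            raise GrammarError(f"block label {label!r}: run lengths disagree with range")
        subs = [
            (start + i, wt_run[i], new_run[i]) for i in range(len(wt_run))
        ]
        return MutationSpec(subs)
    raise GrammarError(f"cannot parse mutation label {label!r}")


def candidate_sites(
    shell: ContactShell,
    profiles: list[ColumnProfile],
    max_nonref_fraction: float = 0.05,
) -> CandidateTable:
    """Intersect the DNA contact shell with the non-conserved positions.

    Rows are exactly the positions that are both in the shell and
    non-conserved, each carrying its ranked substitutions and min DNA
    distance.  A shell position absent from the profiles indicates that the
    structure and alignment use different coordinates.
    """
    by_pos = {p.position: p for p in profiles}
    rows: list[CandidateRow] = []
    for chain, resi, resname, dist in shell.entries:
        profile = by_pos.get(resi)
        if profile is None:
            raise MappingError(
                f"shell position {resi} (chain {chain}) has no alignment column"
            )
        if classify_conservation(profile, max_nonref_fraction):
            continue
        rows.append(
            CandidateRow(
                position=resi,
                wt_residue=profile.ref_residue,
                substitutions=ranked_substitutions(profile),
                conserved=False,
                min_dna_distance=dist,
            )
        )
    rows.sort(key=lambda r: r.position)
    return CandidateTable(rows)


def site_candidates(table: CandidateTable) -> list[MutationSpec]:
    """One single-site MutationSpec per candidate row (top-frequency pick)."""
    specs = []
    for row in table.rows:
        if row.top_pick is None:
            continue
        specs.append(MutationSpec([(row.position, row.wt_residue, row.top_pick)]))
    return specs


def block_candidates(table: CandidateTable, min_run_length: int = 2) -> list[MutationSpec]:
    """Maximal runs of consecutive candidate positions as block mutations.

    Each block substitutes every position in the run with its top-frequency
    residue; positions without any observed substitution break a run.
    """
    rows = sorted(
        (r for r in table.rows if r.top_pick is not None),
        key=lambda r: r.position,
    )
    blocks: list[MutationSpec] = []
    run: list[CandidateRow] = []

    def flush() -> None:
        if len(run) >= min_run_length:
            subs = [(r.position, r.wt_residue, r.top_pick) for r in run]
            blocks.append(MutationSpec(subs))
        run.clear()

    for row in rows:
        if run and row.position != run[-1].position + 1:
            flush()
        run.append(row)
    flush()
    return blocks


def apply_mutations(reference_sequence: str, spec: MutationSpec) -> str:
    """Apply a MutationSpec to the reference sequence (1-based positions).

    The stated wild-type residue must match the sequence at every position —
    this guards against coordinate drift between structure and alignment.
    """
    seq = list(reference_sequence)
    for pos, wt, new in spec.substitutions:
        if pos < 1 or pos > len(seq):
            raise ValidationError(f"position {pos} outside sequence of length {len(seq)}")
        if seq[pos - 1] != wt:
            raise ValidationError(
                f"position {pos}: expected wild-type {wt}, sequence has {seq[pos - 1]}"
            )
        seq[pos - 1] = new
    return "".join(seq)


_LINKER_RE = re.compile(r"^([A-Z]*)\(([A-Z]+)\)_(\d+)_([A-Z]*)$")


def expand_linker(notation: str) -> str:
    """Expand "SS(GGGGS)_3_GM" → "SSGGGGSGGGGSGGGGSGM"; plain sequences pass."""
    notation = notation.strip()
    m = _LINKER_RE.match(notation)
    if m:
        prefix, unit, k, suffix = m.group(1), m.group(2), int(m.group(3)), m.group(4)
        return prefix + unit * k + suffix
    if re.fullmatch(r"[A-Z]*", notation):
        return notation
    raise GrammarError(f"malformed linker notation {notation!r}")


def build_fusion(n_domain: str, linker_notation: str, c_domain: str) -> FusionDesign:
    """Assemble an N-domain / linker / C-domain fusion (e.g. Sso7d–linker–Dbh)."""
    linker = expand_linker(linker_notation)
    return FusionDesign(n_domain, linker_notation, linker, c_domain)
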