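"""End-to-end orchestration and report generation.

``run_design`` composes the design stages — contact shell from the
structure, conservation profiles from the alignment, candidate
intersection, block detection — and records a run manifest (inputs hashed,
config snapshot, package version) sufficient to re-run the pipeline.

The report builders regenerate every derived column from its inputs: the
mutant − WT ΔΔG column from per-chain ΔG values and the V_max/K_m
efficiency column from K_m and V_max.  When a table also carries reported
values, rows whose recomputed value disagrees are flagged rather than
silently overwritten or copied — arithmetic inconsistencies in published
tables surface instead of propagating.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import CandidateTable, MutationSpec, block_candidates, candidate_sites
from .errors import SchemaError
from .kinetics import round_sig
from .msa import column_profiles, filter_homologs, read_alignment
from .structure import ContactShell, contact_shell, read_structure

#: absolute tolerance (kcal/mol) when checking a reported ΔΔG against the
#: recomputed per-chain sum; generous enough for last-digit rounding of the
#: printed per-chain values, far below any real bookkeeping discrepancy.
DDG_CHECK_TOL = 0.05


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None = None
    input_hashes: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_hashes[str(path)] = digest

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_design(
    structure_path: str | Path,
    msa_path: str | Path,
    reference_id: str,
    cutoff: float = 6.0,
    min_identity: float = 0.40,
    max_nonref_fraction: float = 0.05,
    min_run_length: int = 2,
    out_dir: str | Path | None = None,
) -> tuple[ContactShell, CandidateTable, list[MutationSpec], RunManifest]:
    """Structure + alignment → contact shell → candidates → blocks."""
    manifest = RunManifest(
        command="design",
        config=dict(
            cutoff=cutoff, min_identity=min_identity,
            max_nonref_fraction=max_nonref_fraction,
            min_run_length=min_run_length, reference_id=reference_id,
        ),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.add_input(structure_path)
    manifest.add_input(msa_path)

    model = read_structure(structure_path)
    shell = contact_shell(model, cutoff=cutoff)
    aln = filter_homologs(read_alignment(msa_path, reference_id), min_identity)
    profiles = column_profiles(aln)
    table = candidate_sites(shell, profiles, max_nonref_fraction)
    blocks = block_candidates(table, min_run_length)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        shell.to_tsv(out_dir / "shell.tsv")
        table.to_tsv(out_dir / "candidates.tsv")
        (out_dir / "blocks.txt").write_text(
            "".join(b.label + "\n" for b in blocks)
        )
        manifest.outputs = [
            str(out_dir / n) for n in ("shell.tsv", "candidates.tsv", "blocks.txt")
        ]
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.to_json(out_dir / "manifest.json")
    else:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    return shell, table, blocks, manifest


def binding_energy_report(df: pd.DataFrame, wt_label: str = "WTDbh",
                          tol: float = DDG_CHECK_TOL) -> pd.DataFrame:
    """Regenerate the mutant − WT ΔΔG column from per-chain ΔG values.

    Input columns: ``variant``, ``dg_P``, ``dg_T`` and optionally
    ``reported_ddg``.  The output adds ``computed_ddg`` and, when reported
    values are present, a ``flag`` column marking rows whose reported
    difference is not the sum of the per-chain differences.
    """
    for col in ("variant", "dg_P", "dg_T"):
        if col not in df.columns:
            raise SchemaError(f"binding-energy table lacks column {col!r}")
    df = df[df["dg_P"].notna() & df["dg_T"].notna()].copy()
    wt = df[df["variant"] == wt_label]
    if len(wt) != 1:
        raise SchemaError(f"expected exactly one wild-type row {wt_label!r}")
    wt_p = float(wt["dg_P"].iloc[0])
    wt_t = float(wt["dg_T"].iloc[0])
    out = df[df["variant"] != wt_label].copy()
    out["computed_ddg"] = (out["dg_P"] - wt_p) + (out["dg_T"] - wt_t)
    if "reported_ddg" in out.columns:
        out["flag"] = [
            ""
            if pd.isna(rep) or abs(comp - rep) <= tol
            else f"reported {rep:g} != per-chain sum {comp:g}"
            for comp, rep in zip(out["computed_ddg"], out["reported_ddg"])
        ]
    return out.reset_index(drop=True)


def kinetics_report(df: pd.DataFrame) -> pd.DataFrame:
    """Regenerate the V_max/K_m efficiency column (K_m in mM, 2 sig figs).

    Input columns: ``variant``, ``template_base``, ``dntp``, ``km_uM``,
    ``vmax_nM_min`` and optionally ``reported_eff``.  Adds
    ``computed_eff`` and flags rows whose reported efficiency does not
    match the recomputed one.
    """
    required = ("variant", "template_base", "dntp", "km_uM", "vmax_nM_min")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"kinetics table lacks column {col!r}")
    out = df.copy()
    out["computed_eff"] = [
        round_sig(v / (k / 1000.0), 2)
        for k, v in zip(out["km_uM"], out["vmax_nM_min"])
    ]
    if "reported_eff" in out.columns:
        out["flag"] = [
            ""
            if pd.isna(rep) or np.isclose(comp, rep, rtol=1e-9)
            else f"reported {rep:g} != computed {comp:g}"
            for comp, rep in zip(out["computed_eff"], out["reported_eff"])
        ]
    return out.reset_index(drop=True)
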