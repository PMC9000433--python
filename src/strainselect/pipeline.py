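"""File-based pipeline orchestration with a reproducible run manifest.

Stages run in a fixed order: read -> replicate consensus -> region split
-> feature binning -> clustering -> dendrogram cut -> MAN construction
-> greedy prioritization -> reports.  Every run writes a manifest
recording the configuration, the package version and the SHA-256 of
each input file, so a rerun from the same manifest reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .cluster import build_dendrogram, cut_dendrogram, distance_matrix
from .features import bin_features
from .man import annotate_man, build_man
from .msio import (
    read_mzml,
    read_peaklist_table,
    write_graphml,
    write_newick,
    write_peaklist_table,
    write_selection_report,
)
from .preprocess import merge_replicates, split_regions, subtract_blank
from .prioritize import LibrarySelection, Threshold, prioritize_all
from .types import ConsensusPeakList, PeakList

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_stages", "consensus_stage"]


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run.

    Tolerances are absolute Daltons; the protein/np pairs reflect the
    much poorer mass accuracy of linear-mode TOF above 2 kDa.
    """

    input_dir: Optional[str] = None  # directory of peak tables / mzML files
    out_dir: str = "strainselect_out"
    naming_pattern: str = "{isolate}_{replicate}"
    # replicate consensus
    min_presence: float = 2 / 3
    tol_rep_protein: float = 2.0
    tol_rep_np: float = 0.2
    # optional peak picking (profile mzML only)
    snr_min_protein: float = 4.0
    snr_min_np: float = 10.0
    halfwindow: int = 10
    # optional matrix-blank subtraction
    blank_paths: list[str] = field(default_factory=list)
    blank_tol: float = 0.2
    # feature binning
    tol_bin_protein: float = 2.0
    tol_bin_np: float = 0.2
    # clustering / cut
    metric: str = "cosine"
    linkage: str = "average"
    cut_mode: str = "k"  # "height" or "k"
    cut_value: float = 1
    # prioritization
    threshold: float = 0.75
    min_per_group: int = 0
    seed: int = 0

    _FIELDS = None  # filled after class creation

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_inputs(config: RunConfig) -> tuple[dict[str, dict[str, PeakList]], dict[str, str]]:
    """Collect per-isolate per-replicate peak lists from the input directory.

    Delimited tables are keyed by file stem via the naming pattern; mzML
    files contribute one peak list per spectrum.
    """
    if config.input_dir is None:
        raise ValueError("config.input_dir is not set")
    root = Path(config.input_dir)
    if not root.is_dir():
        raise ValueError(f"input directory not found: {root}")
    from .msio import _pattern_to_regex

    regex = _pattern_to_regex(config.naming_pattern)
    peaklists: dict[str, dict[str, PeakList]] = {}
    checksums: dict[str, str] = {}
    blanks = {Path(b).resolve() for b in config.blank_paths}
    for path in sorted(root.iterdir()):
        if path.resolve() in blanks:
            continue
        suffix = path.suffix.lower()
        if suffix == ".mzml":
            lists = read_mzml(path, naming_pattern=config.naming_pattern)
        elif suffix in (".csv", ".tsv", ".txt"):
            m = regex.fullmatch(path.stem)
            if m is None:
                raise ValueError(
                    f"file name {path.stem!r} does not match naming pattern "
                    f"{config.naming_pattern!r}"
                )
            lists = [
                read_peaklist_table(path, m.group("isolate"), m.group("replicate"))
            ]
        else:
            continue
        checksums[path.name] = _sha256(path)
        for pl in lists:
            peaklists.setdefault(pl.isolate_id, {})[pl.replicate_id] = pl
    if not peaklists:
        raise ValueError(f"no peak lists found in {root}")
    return peaklists, checksums


def consensus_stage(
    peaklists: dict[str, dict[str, PeakList]],
    config: RunConfig,
    blank_consensus: Optional[ConsensusPeakList] = None,
) -> tuple[list[ConsensusPeakList], list[ConsensusPeakList]]:
    """Replicate consensus and region split for every isolate.

    Replicate matching runs separately below and above 2000 Da so each
    mass range gets the tolerance appropriate to its mass accuracy.
    Returns (protein_lists, np_lists) in sorted isolate order.
    """
    protein_lists, np_lists = [], []
    for iso in sorted(peaklists):
        reps = [peaklists[iso][r] for r in sorted(peaklists[iso])]
        low = [
            PeakList(r.isolate_id, r.replicate_id, [p for p in r.peaks if p.mz < 2000])
            for r in reps
        ]
        high = [
            PeakList(r.isolate_id, r.replicate_id, [p for p in r.peaks if p.mz >= 2000])
            for r in reps
        ]
        cons_low = merge_replicates(
            low, tol=config.tol_rep_np, min_presence=config.min_presence
        )
        cons_high = merge_replicates(
            high, tol=config.tol_rep_protein, min_presence=config.min_presence
        )
        consensus = ConsensusPeakList(
            isolate_id=iso,
            peaks=cons_low.peaks + cons_high.peaks,
            presence=cons_low.presence + cons_high.presence,
            n_replicates=len(reps),
        )
        if blank_consensus is not None:
            consensus = subtract_blank(consensus, blank_consensus, config.blank_tol)
        protein, np_part = split_regions(consensus)
        protein_lists.append(protein)
        np_lists.append(np_part)
    return protein_lists, np_lists


def run_stages(
    peaklists: dict[str, dict[str, PeakList]],
    config: RunConfig,
    out_dir: Optional[Union[str, Path]] = None,
    input_checksums: Optional[dict[str, str]] = None,
) -> LibrarySelection:
    """Execute all pipeline stages on in-memory peak lists.

    If ``out_dir`` is given, all intermediate artifacts (consensus peak
    tables, feature matrices, Newick tree, group table, per-group
    GraphML, selection report, selected-isolate list, manifest) are
    written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    # matrix blanks: consensus over blank replicate lists
    stage("consensus")
    blank_consensus = None
    if config.blank_paths:
        blank_lists = [
            read_peaklist_table(p, "matrix_blank", f"r{i + 1}")
            for i, p in enumerate(config.blank_paths)
        ]
        # a blank peak is real if seen in any blank replicate
        blank_consensus = merge_replicates(
            blank_lists, tol=config.tol_rep_np, min_presence=1.0 / len(blank_lists)
        )

    protein_lists, np_lists = consensus_stage(peaklists, config, blank_consensus)
    for protein, np_part in zip(protein_lists, np_lists):
        iso = protein.isolate_id
        if out is not None:
            write_peaklist_table(protein.peaks, out / f"consensus_{iso}_protein.csv")
            write_peaklist_table(np_part.peaks, out / f"consensus_{iso}_np.csv")

    stage("binning")
    protein_matrix = bin_features(protein_lists, tol=config.tol_bin_protein)
    np_matrix = bin_features(np_lists, tol=config.tol_bin_np)
    if out is not None:
        protein_matrix.write_table(out / "features_protein.tsv")
        np_matrix.write_table(out / "features_np.tsv")

    stage("clustering")
    dist = distance_matrix(protein_matrix, metric=config.metric)
    dend = build_dendrogram(
        dist, protein_matrix, linkage=config.linkage, metric=config.metric
    )
    assignment = cut_dendrogram(dend, mode=config.cut_mode, value=config.cut_value)
    if out is not None:
        write_newick(dend, out / "dendrogram.nwk")
        assignment.write_table(out / "groups.tsv")

    stage("prioritization")
    selection = prioritize_all(
        assignment,
        np_matrix,
        Threshold(config.threshold),
        min_per_group=config.min_per_group,
    )

    stage("reports")
    if out is not None:
        for gs in selection.per_group:
            man = build_man(assignment.members(gs.group_id), np_matrix, gs.group_id)
            annotate_man(man, gs)
            write_graphml(man, out / f"man_group{gs.group_id:03d}.graphml")
        write_selection_report(selection.to_report(), out / "selection_report.json")
        (out / "selected_isolates.txt").write_text(
            "".join(f"{iso}\n" for iso in selection.selected_isolates)
        )
        manifest = {
            "tool": "strainselect",
            "version": __version__,
            "config": config.to_dict(),
            "input_checksums": input_checksums or {},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return selection


def run_pipeline(config: RunConfig) -> LibrarySelection:
    """Run the full file-based pipeline described by ``config``."""
    peaklists, checksums = _read_inputs(config)
    return run_stages(
        peaklists, config, out_dir=config.out_dir, input_checksums=checksums
    )
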