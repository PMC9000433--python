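"""Readers and writers for the pipeline's file formats.

Reads centroided spectra from mzML (via pyteomics) or plain delimited
peak tables; writes peak tables, Newick dendrograms, GraphML metabolite
association networks, and JSON selection reports.
"""

from __future__ import annotations

import base64
import json
import logging
import re
import zlib
from pathlib import Path
from xml.etree import ElementTree
from typing import TYPE_CHECKING, Optional, Sequence, Union

import networkx as nx

from .types import Peak, PeakList, sorted_peaks

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .cluster import Dendrogram
    from .man import MAN

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTableParseError",
    "read_peaklist_table",
    "write_peaklist_table",
    "read_mzml",
    "write_newick",
    "newick_string",
    "write_graphml",
    "man_to_graph",
    "write_selection_report",
]

_DELIMITERS = (",", "\t", ";")


class PeakTableParseError(ValueError):
    """Raised when a delimited peak table cannot be parsed."""


def _sniff_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)  # type: ignore[arg-type]
    if counts[best] == 0:
        # whitespace-separated fallback covers single-column-pair exports
        return best if best in line else ","
    return best


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_peaklist_table(
    path: Union[str, Path], isolate_id: str, replicate_id: str
) -> PeakList:
    """Read a two-column (m/z, intensity) delimited text file.

    Comma, tab or semicolon delimiters are auto-detected; an optional
    header row is recognized by a non-numeric first field.  Columns beyond
    the first two are ignored.  Exact duplicate m/z rows are collapsed
    keeping the maximum intensity, and the result is sorted by m/z.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows: list[tuple[int, str]] = [
        (i + 1, ln) for i, ln in enumerate(lines) if ln.strip()
    ]
    if not rows:
        raise PeakTableParseError(f"{path}: no peaks")
    delim = _sniff_delimiter(rows[0][1])
    first_fields = [f.strip() for f in rows[0][1].split(delim)]
    # header row: no numeric field at all ("abc,5" is a malformed data row)
    if first_fields and not any(_is_number(f) for f in first_fields[:2]):
        rows = rows[1:]
    peaks: list[Peak] = []
    for lineno, ln in rows:
        fields = [f.strip() for f in ln.split(delim)]
        if len(fields) < 2:
            raise PeakTableParseError(
                f"{path}: line {lineno}: expected at least 2 columns"
            )
        try:
            mz = float(fields[0])
            intensity = float(fields[1])
        except ValueError as exc:
            raise PeakTableParseError(f"{path}: line {lineno}: {exc}") from exc
        peaks.append(Peak(mz=mz, intensity=intensity))
    if not peaks:
        raise PeakTableParseError(f"{path}: no peaks")
    return PeakList(
        isolate_id=isolate_id, replicate_id=replicate_id, peaks=sorted_peaks(peaks)
    )


def write_peaklist_table(
    peaks: Sequence[Peak], path: Union[str, Path], delimiter: str = ","
) -> None:
    """Write peaks as an ``mz,intensity`` table with a header row."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"mz{delimiter}intensity\n")
        for p in peaks:
            fh.write(f"{p.mz:.10g}{delimiter}{p.intensity:.10g}\n")


def _pattern_to_regex(pattern: str) -> re.Pattern[str]:
    out, pos = [], 0
    for m in re.finditer(r"\{(isolate|replicate)\}", pattern):
        out.append(re.escape(pattern[pos : m.start()]))
        # isolate is greedy so the *last* separator splits isolate/replicate
        out.append(f"(?P<{m.group(1)}>.+)")
        pos = m.end()
    out.append(re.escape(pattern[pos:]))
    return re.compile("".join(out))


_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_TITLE = "MS:1000796"


def _decode_binary_array(elem) -> "np.ndarray":
    """Decode one mzML binaryDataArray element to a float array."""
    import numpy as np

    accs = {cv.get("accession") for cv in elem.iter() if cv.tag.endswith("cvParam")}
    dtype = "<f4" if _CV_FLOAT32 in accs else "<f8"
    binary = next(e for e in elem.iter() if e.tag.endswith("}binary"))
    raw = base64.b64decode((binary.text or "").strip())
    if _CV_ZLIB in accs:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_spectra(path: Path):
    """Yield (spectrum_id, accessions, mz_array, intensity_array) tuples."""
    try:
        tree = ElementTree.parse(str(path))
    except ElementTree.ParseError as exc:
        raise ValueError(f"{path}: invalid mzML: {exc}") from exc
    root = tree.getroot()
    if not root.tag.endswith("mzML") and not any(
        e.tag.endswith("mzML") for e in root.iter()
    ):
        raise ValueError(f"{path}: invalid mzML: no <mzML> element")
    for spec in root.iter():
        if not spec.tag.endswith("}spectrum"):
            continue
        sid = spec.get("id", "")
        accs: dict[str, str] = {}
        for cv in spec.iter():
            if cv.tag.endswith("cvParam"):
                accs[cv.get("accession", "")] = cv.get("value", "")
        arrays = {}
        for arr in spec.iter():
            if not arr.tag.endswith("}binaryDataArray"):
                continue
            arr_accs = {
                cv.get("accession")
                for cv in arr.iter()
                if cv.tag.endswith("cvParam")
            }
            if _CV_MZ_ARRAY in arr_accs:
                arrays["mz"] = _decode_binary_array(arr)
            elif _CV_INTENSITY_ARRAY in arr_accs:
                arrays["intensity"] = _decode_binary_array(arr)
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(
                f"{path}: spectrum {sid!r} lacks m/z or intensity array"
            )
        yield sid, accs, arrays["mz"], arrays["intensity"]


def read_mzml(
    path: Union[str, Path],
    naming_pattern: str = "{isolate}_{replicate}",
    force_centroid: bool = False,
) -> list[PeakList]:
    """Read all spectra of an mzML file into per-replicate peak lists.

    Supports 32/64-bit float arrays with zlib or no compression.
    Isolate and replicate identifiers are extracted from the spectrum
    title (or id) with ``naming_pattern``, which must contain
    ``{isolate}`` and ``{replicate}`` placeholders.  Profile-mode spectra
    are rejected unless ``force_centroid`` is set, in which case the raw
    arrays are passed through for downstream peak picking.
    """
    path = Path(path)
    regex = _pattern_to_regex(naming_pattern)
    out: list[PeakList] = []
    unmatched: list[str] = []
    for sid, accs, mz, inten in _parse_mzml_spectra(path):
        title = accs.get(_CV_TITLE) or sid
        is_profile = _CV_PROFILE in accs or _CV_CENTROID not in accs
        if is_profile and not force_centroid:
            raise ValueError(
                f"{path}: spectrum {title!r}: profile spectra not supported "
                "(set force_centroid to pass raw arrays through)"
            )
        m = regex.fullmatch(str(title))
        if m is None:
            unmatched.append(str(title))
            continue
        peaks = sorted_peaks(
            Peak(mz=float(a), intensity=float(b))
            for a, b in zip(mz, inten)
            if a > 0
        )
        out.append(
            PeakList(
                isolate_id=m.group("isolate"),
                replicate_id=m.group("replicate"),
                peaks=peaks,
            )
        )
    if unmatched:
        raise ValueError(
            f"{path}: naming pattern {naming_pattern!r} did not match "
            f"spectrum ids: {', '.join(unmatched)}"
        )
    if not out:
        logger.warning("%s: mzML file contains no spectra", path)
    return out


def newick_string(dendrogram: "Dendrogram", precision: int = 6) -> str:
    """Serialize a dendrogram to Newick with merge-height branch lengths.

    Each branch length is the difference between the parent merge height
    and the child node's own merge height (0 for leaves), so root-to-leaf
    path lengths equal the root merge height.
    """
    labels = dendrogram.leaves
    if len(labels) == 1:
        return f"{labels[0]};"
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(dendrogram.linkage_matrix)

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def walk(node, parent_height: Optional[float]) -> str:
        if node.is_leaf():
            body = labels[node.id]
            height = 0.0
        else:
            body = f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
            height = node.dist
        if parent_height is None:
            return body
        return f"{body}:{fmt(max(parent_height - height, 0.0))}"

    return walk(root, None) + ";"


def write_newick(
    dendrogram: "Dendrogram", path: Union[str, Path], precision: int = 6
) -> None:
    """Write a dendrogram as a Newick file (see :func:`newick_string`)."""
    Path(path).write_text(newick_string(dendrogram, precision=precision) + "\n")


def man_to_graph(man: "MAN") -> nx.Graph:
    """Convert a metabolite association network to a networkx graph.

    Isolate nodes keep their ids; feature nodes are prefixed ``f:`` to
    avoid collisions.  Node attributes: ``node_type`` (isolate/feature),
    ``selected`` (true/false/na), ``captured`` (true/false/na).
    """
    g = nx.Graph(group_id=man.group_id)
    for iso in sorted(man.isolate_nodes):
        sel = man.selected.get(iso)
        g.add_node(
            iso,
            node_type="isolate",
            selected="na" if sel is None else ("true" if sel else "false"),
            captured="na",
        )
    for feat in sorted(man.feature_nodes):
        cap = man.captured.get(feat)
        g.add_node(
            f"f:{feat}",
            node_type="feature",
            feature_id=int(feat),
            selected="na",
            captured="na" if cap is None else ("true" if cap else "false"),
        )
    for iso, feat in sorted(man.edges):
        g.add_edge(iso, f"f:{feat}")
    return g


def write_graphml(man: "MAN", path: Union[str, Path]) -> None:
    """Write a metabolite association network as GraphML."""
    nx.write_graphml(man_to_graph(man), str(path))


def write_selection_report(report: dict, path: Union[str, Path]) -> None:
    """Write a selection report dictionary as pretty-printed JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
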