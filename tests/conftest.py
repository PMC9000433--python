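"""Shared fixtures and helpers for the strainselect test suite."""

from __future__ import annotations

import base64
import struct
from pathlib import Path

import numpy as np
import pytest

from strainselect.features import FeatureBin, FeatureMatrix

MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">
"""

MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""

SPECTRUM_TEMPLATE = """      <spectrum index="{index}" id="{sid}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def _b64_doubles(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *[float(v) for v in values])
    return base64.b64encode(raw).decode("ascii")


def write_mzml(path: Path, spectra: list[tuple[str, list, list, bool]]) -> None:
    """Write a minimal synthetic mzML file.

    ``spectra`` is a list of (spectrum_id, mz, intensity, centroided).
    Synthetic stand-in for instrument-exported mzML; covers only what
    the reader consumes.
    """
    parts = [MZML_HEADER.format(count=len(spectra))]
    for index, (sid, mz, inten, centroided) in enumerate(spectra):
        mz_b64 = _b64_doubles(mz)
        int_b64 = _b64_doubles(inten)
        parts.append(
            SPECTRUM_TEMPLATE.format(
                index=index,
                sid=sid,
                npts=len(mz),
                mode_acc="MS:1000127" if centroided else "MS:1000128",
                mode_name="centroid spectrum" if centroided else "profile spectrum",
                mz_len=len(mz_b64),
                int_len=len(int_b64),
                mz_b64=mz_b64,
                int_b64=int_b64,
            )
        )
    parts.append(MZML_FOOTER)
    Path(path).write_text("".join(parts))


def matrix_from_sets(
    feature_sets: dict[str, set[int]], region: str = "np"
) -> FeatureMatrix:
    """Build a FeatureMatrix directly from per-isolate feature-label sets.

    Column j corresponds to the j-th smallest label in the union, so with
    labels 0..m-1 all present, labels coincide with feature ids.
    """
    ids = sorted(feature_sets)
    labels = sorted(set().union(*feature_sets.values())) if feature_sets else []
    base = 210.0 if region == "np" else 2100.0
    bins = [
        FeatureBin(
            feature_id=j,
            mz_center=base + 10.0 * lab,
            mz_min=base + 10.0 * lab,
            mz_max=base + 10.0 * lab,
            region=region,
        )
        for j, lab in enumerate(labels)
    ]
    incidence = np.zeros((len(ids), len(labels)), dtype=np.int8)
    for i, iso in enumerate(ids):
        for lab in feature_sets[iso]:
            incidence[i, labels.index(lab)] = 1
    return FeatureMatrix(isolate_ids=ids, bins=bins, incidence=incidence, region=region)


def random_feature_sets(
    rng: np.random.Generator,
    n_isolates: int,
    n_features: int,
    density: float = 0.4,
) -> dict[str, set[int]]:
    """Random per-isolate feature sets; every feature touches >= 1 isolate."""
    while True:
        inc = rng.random((n_isolates, n_features)) < density
        if n_features == 0 or inc.any(axis=0).all():
            break
    return {
        f"I{i:02d}": set(np.flatnonzero(inc[i]).tolist()) for i in range(n_isolates)
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
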