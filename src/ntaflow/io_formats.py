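"""Readers and writers for every external format the pipeline touches.

Canonical dialects
------------------
Alignment CSV
    Header ``feature_id,mz,rt,ion_mode,adduct_link,<sample_id>...`` with one
    row per feature. Missing (below-MDL) areas are empty cells, never ``0``
    -- zero is a legal peak area. RT is written with 4 decimals, m/z with 5.

Sample manifest CSV
    ``sample_id,matrix,batch,outcome,creatinine``; ``matrix`` is one of
    serum/urine/blank; blanks may leave outcome/creatinine empty.

MSP spectral library
    NIST-style text blocks: ``NAME``, optional ``FORMULA``, ``MW`` (neutral
    monoisotopic mass), ``PRECURSORMZ``, ``IONMODE``, optional
    ``RETENTIONTIME``, optional ``COMMENT`` carrying ``sources=a|b`` and
    ``standard=true``, then ``Num Peaks: n`` followed by n ``mz<TAB>int``
    lines.

Networks
    node-link JSON (d3-compatible) or GraphML via networkx.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .types import (
    FeatureTable,
    ParseError,
    Spectrum,
    SpectralLibraryEntry,
    ValidationError,
    ION_MODES,
)

PathLike = Union[str, Path]

ALIGNMENT_META_COLUMNS = ["feature_id", "mz", "rt", "ion_mode", "adduct_link"]
MANIFEST_COLUMNS = ["sample_id", "matrix", "batch", "outcome", "creatinine"]


# ---------------------------------------------------------------------------
# sample manifest
# ---------------------------------------------------------------------------

def read_manifest(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "matrix": str, "outcome": str})
    missing = set(MANIFEST_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    df = df.set_index("sample_id")
    df["batch"] = df["batch"].astype(int)
    if "creatinine" in df.columns:
        df["creatinine"] = pd.to_numeric(df["creatinine"], errors="coerce")
    return df


def write_manifest(manifest: pd.DataFrame, path: PathLike) -> None:
    out = manifest.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    cols = [c for c in MANIFEST_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# alignment CSV
# ---------------------------------------------------------------------------

def write_alignment(table: FeatureTable, path: PathLike) -> None:
    feats = table.features
    out = pd.DataFrame(index=feats.index)
    out["mz"] = feats["mz"].map(lambda v: f"{v:.5f}")
    out["rt"] = feats["rt"].map(lambda v: f"{v:.4f}")
    out["ion_mode"] = feats["ion_mode"]
    link = feats["adduct_link"] if "adduct_link" in feats.columns else None
    out["adduct_link"] = "" if link is None else link.fillna("")
    ab = table.abundance.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out = pd.concat([out, ab], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path)


def read_alignment(
    path: PathLike,
    ion_mode: Optional[str] = None,
    manifest: Optional[pd.DataFrame] = None,
) -> FeatureTable:
    """Read a canonical alignment CSV into a :class:`FeatureTable`.

    When ``manifest`` is given, sample metadata comes from it (columns not
    listed there raise). Otherwise minimal sample records are synthesized
    with matrix "serum" so the table still validates; callers doing real
    work should always pass the manifest.
    """
    df = pd.read_csv(path, dtype={"feature_id": str, "adduct_link": str})
    missing = set(ALIGNMENT_META_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: alignment header missing {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ParseError(f"{path}: duplicated feature_id {dup!r}")
    feats = df[ALIGNMENT_META_COLUMNS].set_index("feature_id")
    feats["adduct_link"] = feats["adduct_link"].replace("", np.nan)
    if ion_mode is not None:
        bad = feats.index[feats["ion_mode"] != ion_mode]
        if len(bad):
            raise ParseError(
                f"{path}: feature {bad[0]!r} has ion_mode "
                f"{feats.loc[bad[0], 'ion_mode']!r}, expected {ion_mode!r}"
            )
    sample_cols = [c for c in df.columns if c not in ALIGNMENT_META_COLUMNS]
    ab = df[sample_cols].copy()
    ab.index = feats.index
    ab = ab.apply(pd.to_numeric, errors="coerce")
    raw = df[sample_cols]
    for col in sample_cols:
        mask = ab[col].isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if mask.any():
            raise ParseError(
                f"{path}: non-numeric area at feature {feats.index[mask][0]!r}, "
                f"column {col!r}"
            )
        neg = ab[col] < 0
        if neg.any():
            raise ParseError(
                f"{path}: negative area at feature {ab.index[neg][0]!r}, column {col!r}"
            )
    if manifest is not None:
        unknown = set(sample_cols) - set(manifest.index)
        if unknown:
            raise ParseError(f"{path}: samples not in manifest: {sorted(unknown)[:5]}")
        samples = manifest.loc[sample_cols].copy()
    else:
        samples = pd.DataFrame(
            {"matrix": "serum", "batch": 1, "outcome": pd.NA, "creatinine": np.nan},
            index=pd.Index(sample_cols, name="sample_id"),
        )
    table = FeatureTable(feats, ab, samples)
    try:
        return table.validate()
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def split_blanks(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Route blank/QC columns (manifest matrix == 'blank') to a second table."""
    is_blank = table.samples["matrix"] == "blank"
    blanks = table.subset_samples(table.samples.index[is_blank])
    main = table.subset_samples(table.samples.index[~is_blank])
    return main, blanks


# ---------------------------------------------------------------------------
# MSP spectral libraries
# ---------------------------------------------------------------------------

def write_msp(entries: list[SpectralLibraryEntry], path: PathLike) -> None:
    lines: list[str] = []
    for entry in entries:
        lines.append(f"NAME: {entry.name}")
        if entry.formula:
            lines.append(f"FORMULA: {entry.formula}")
        lines.append(f"MW: {entry.neutral_mass:.5f}")
        lines.append(f"PRECURSORMZ: {entry.spectrum.precursor_mz:.5f}")
        lines.append(f"IONMODE: {entry.spectrum.ion_mode}")
        if entry.rt is not None:
            lines.append(f"RETENTIONTIME: {entry.rt:.4f}")
        comment_parts = []
        if entry.sources:
            comment_parts.append("sources=" + "|".join(sorted(entry.sources)))
        if entry.is_authentic_standard:
            comment_parts.append("standard=true")
        if comment_parts:
            lines.append("COMMENT: " + "; ".join(comment_parts))
        lines.append(f"Num Peaks: {entry.spectrum.n_fragments}")
        for mz, intensity in entry.spectrum.fragments:
            lines.append(f"{mz:.5f}\t{intensity:.4f}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _parse_msp_block(block_lines: list[str], block_index: int) -> SpectralLibraryEntry:
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_peaks: Optional[int] = None
    in_peaks = False
    for line in block_lines:
        if in_peaks:
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"MSP block {block_index}: bad fragment line {line!r}")
            peaks.append((float(parts[0]), float(parts[1])))
            continue
        if ":" not in line:
            raise ParseError(f"MSP block {block_index}: expected 'key: value', got {line!r}")
        key, _, value = line.partition(":")
        key = key.strip().upper()
        value = value.strip()
        if key == "NUM PEAKS":
            n_peaks = int(value)
            in_peaks = True
        else:
            fields[key] = value
    if "NAME" not in fields:
        raise ParseError(f"MSP block {block_index}: missing NAME")
    if n_peaks is None:
        raise ParseError(f"MSP block {block_index}: missing 'Num Peaks'")
    if len(peaks) != n_peaks:
        raise ParseError(
            f"MSP block {block_index} ({fields['NAME']!r}): 'Num Peaks: {n_peaks}' "
            f"but {len(peaks)} fragment lines"
        )
    ion_mode = fields.get("IONMODE", "positive").lower()
    if ion_mode not in ION_MODES:
        raise ParseError(f"MSP block {block_index}: unknown IONMODE {ion_mode!r}")
    if "PRECURSORMZ" not in fields:
        raise ParseError(f"MSP block {block_index}: missing PRECURSORMZ")
    spectrum = Spectrum(
        precursor_mz=float(fields["PRECURSORMZ"]),
        ion_mode=ion_mode,
        fragments=np.array(peaks, dtype=float).reshape(-1, 2),
    )
    sources: frozenset = frozenset()
    is_standard = False
    comment = fields.get("COMMENT", "")
    for part in comment.split(";"):
        part = part.strip()
        if part.startswith("sources="):
            tags = [t for t in part[len("sources="):].split("|") if t]
            sources = frozenset(tags)
        elif part == "standard=true":
            is_standard = True
    if "MW" in fields:
        neutral_mass = float(fields["MW"])
    else:
        shift = 1.00782 if ion_mode == "positive" else -1.00782
        neutral_mass = spectrum.precursor_mz - shift
    rt = float(fields["RETENTIONTIME"]) if "RETENTIONTIME" in fields else None
    try:
        return SpectralLibraryEntry(
            name=fields["NAME"],
            spectrum=spectrum,
            neutral_mass=neutral_mass,
            formula=fields.get("FORMULA") or None,
            rt=rt,
            sources=sources,
            is_authentic_standard=is_standard,
        )
    except ValidationError as exc:
        raise ParseError(f"MSP block {block_index}: {exc}") from exc


def read_msp(path: PathLike) -> list[SpectralLibraryEntry]:
    text = Path(path).read_text()
    entries: list[SpectralLibraryEntry] = []
    block: list[str] = []
    index = 0
    for raw in text.splitlines() + [""]:
        line = raw.rstrip()
        if line:
            block.append(line)
        elif block:
            entries.append(_parse_msp_block(block, index))
            block = []
            index += 1
    return entries


# ---------------------------------------------------------------------------
# graph export / import
# ---------------------------------------------------------------------------

GRAPH_FORMATS = ("node-link", "graphml")


def _stringify_attrs(graph: nx.Graph) -> nx.Graph:
    out = graph.copy()
    for key, val in list(out.graph.items()):
        if isinstance(val, (frozenset, set, tuple, list)):
            out.graph[key] = "|".join(sorted(str(v) for v in val))
        elif val is None:
            out.graph[key] = ""
    for _, data in out.nodes(data=True):
        for key, val in list(data.items()):
            if isinstance(val, (frozenset, set, tuple, list)):
                data[key] = "|".join(sorted(str(v) for v in val))
            elif val is None:
                data[key] = ""
    for _, _, data in out.edges(data=True):
        for key, val in list(data.items()):
            if val is None:
                data[key] = ""
    return out


def write_graph(network: nx.Graph, path: PathLike, fmt: str = "node-link") -> None:
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")
    graph = _stringify_attrs(network)
    if fmt == "node-link":
        payload = nx.node_link_data(graph, edges="links")
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        nx.write_graphml(graph, path)


def read_graph(path: PathLike, fmt: str = "node-link") -> nx.Graph:
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")
    if fmt == "node-link":
        payload = json.loads(Path(path).read_text())
        return nx.node_link_graph(payload, edges="links")
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def read_yaml(path: PathLike) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a YAML mapping at top level")
    return data


def write_yaml(data: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
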