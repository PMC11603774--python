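"""MS2 library matching, confidence-level assignment, annotation transfer
onto the MS1 alignment, and source attribution.

Confidence levels follow the 1-5 identification-confidence scale:
1 confirmed by an authentic standard (RT < 0.05 min, precursor and matched
product ions within 5 ppm), 2 probable library match (score > 90),
3 tentative candidate (50 < score <= 90), 4 unknown with MS2 but no match,
5 no usable MS2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    Annotation,
    FeatureTable,
    Spectrum,
    SpectralLibraryEntry,
    UNKNOWN_SOURCE,
    NOISE_FLOOR,
)

log = logging.getLogger(__name__)

DEFAULT_FRAGMENT_TOL_PPM = 10.0
DEFAULT_PRECURSOR_TOL_PPM = 10.0
LEVEL1_RT_TOL = 0.05
LEVEL1_PPM_TOL = 5.0
LEVEL2_SCORE = 90.0
LEVEL3_SCORE = 50.0
TRANSFER_RT_TOL = 0.1
TRANSFER_PPM_TOL = 2.0
MIN_FRAGMENTS = 2


def _match_fragments(
    a: np.ndarray, b: np.ndarray, tol_ppm: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one fragment pairing by ascending ppm distance."""
    pairs = []
    for i, mz_a in enumerate(a[:, 0]):
        for j, mz_b in enumerate(b[:, 0]):
            mean = 0.5 * (mz_a + mz_b)
            ppm = abs(mz_a - mz_b) / mean * 1e6
            if ppm <= tol_ppm:
                pairs.append((ppm, i, j))
    pairs.sort(key=lambda t: t[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    return matched


def spectral_match_score(
    query: Spectrum,
    library: Spectrum | SpectralLibraryEntry,
    fragment_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> float:
    """Weighted cosine similarity of two fragment spectra, scaled to 0-100.

    Fragments are aligned one-to-one within ``fragment_tol_ppm``; each
    fragment contributes weight intensity**0.5 (no m/z weighting). The score
    is symmetric in its arguments.
    """
    lib_spec = library.spectrum if isinstance(library, SpectralLibraryEntry) else library
    if query.n_fragments == 0 or lib_spec.n_fragments == 0:
        raise ValueError("cannot score an empty spectrum")
    wq = np.sqrt(query.fragments[:, 1])
    wl = np.sqrt(lib_spec.fragments[:, 1])
    matched = _match_fragments(query.fragments, lib_spec.fragments, fragment_tol_ppm)
    dot = sum(wq[i] * wl[j] for i, j in matched)
    norm = np.linalg.norm(wq) * np.linalg.norm(wl)
    return float(np.clip(100.0 * dot / norm, 0.0, 100.0))


@dataclass
class MatchEvidence:
    """The best library candidate for one query spectrum, with its evidence."""

    entry: SpectralLibraryEntry
    score: float
    precursor_ppm: float
    rt_error: Optional[float]           # None when the entry carries no RT
    max_fragment_ppm: float             # worst matched-fragment mass error
    n_matched_fragments: int


def best_library_match(
    query: Spectrum,
    library: Sequence[SpectralLibraryEntry],
    query_rt: Optional[float] = None,
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    fragment_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> Optional[MatchEvidence]:
    """Best-scoring entry among those with a precursor inside tolerance and
    the same ion mode; ties break toward smaller precursor ppm error."""
    best: Optional[MatchEvidence] = None
    for entry in library:
        spec = entry.spectrum
        if spec.ion_mode != query.ion_mode:
            continue
        mean = 0.5 * (spec.precursor_mz + query.precursor_mz)
        ppm = abs(spec.precursor_mz - query.precursor_mz) / mean * 1e6
        if ppm > precursor_tol_ppm:
            continue
        score = spectral_match_score(query, spec, fragment_tol_ppm)
        matched = _match_fragments(query.fragments, spec.fragments, fragment_tol_ppm)
        if matched:
            frag_ppm = max(
                abs(query.fragments[i, 0] - spec.fragments[j, 0])
                / (0.5 * (query.fragments[i, 0] + spec.fragments[j, 0]))
                * 1e6
                for i, j in matched
            )
        else:
            frag_ppm = np.inf
        rt_error = (
            abs(query_rt - entry.rt)
            if (query_rt is not None and entry.rt is not None)
            else None
        )
        evidence = MatchEvidence(entry, score, ppm, rt_error, frag_ppm, len(matched))
        if best is None or (evidence.score, -evidence.precursor_ppm) > (
            best.score, -best.precursor_ppm
        ):
            best = evidence
    return best


def assign_level(best: Optional[MatchEvidence], has_ms2: bool) -> int:
    """Map match evidence to a confidence level 1-5 (total over all inputs)."""
    if best is not None:
        if (
            best.entry.is_authentic_standard
            and best.rt_error is not None
            and best.rt_error < LEVEL1_RT_TOL
            and best.precursor_ppm <= LEVEL1_PPM_TOL
            and best.n_matched_fragments > 0
            and best.max_fragment_ppm <= LEVEL1_PPM_TOL
        ):
            return 1
        if best.score > LEVEL2_SCORE:
            return 2
        if best.score > LEVEL3_SCORE:
            return 3
    return 4 if has_ms2 else 5


def attribute_sources(entry: Optional[SpectralLibraryEntry]) -> frozenset:
    """The entry's category set; an empty/absent set becomes {'unknown'}."""
    if entry is None or not entry.sources:
        return frozenset({UNKNOWN_SOURCE})
    return frozenset(entry.sources)


def annotate_spectra(
    spectra: Mapping[str, Spectrum],
    library: Sequence[SpectralLibraryEntry],
    rts: Optional[Mapping[str, float]] = None,
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    fragment_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    min_fragments: int = MIN_FRAGMENTS,
) -> list[Annotation]:
    """Annotate every query spectrum against the library.

    Spectra with fewer than ``min_fragments`` fragments are unusable and
    yield Level 5. Returns one Annotation per query, keyed by the query id
    (for pooled-sample spectra this is later re-assigned by transfer).
    """
    annotations = []
    for qid in sorted(spectra):
        spec = spectra[qid]
        has_ms2 = spec.n_fragments >= min_fragments
        query_rt = rts.get(qid) if rts is not None else None
        best = (
            best_library_match(
                spec, library, query_rt, precursor_tol_ppm, fragment_tol_ppm
            )
            if has_ms2
            else None
        )
        level = assign_level(best, has_ms2)
        if best is not None and level <= 3:
            ann = Annotation(
                feature_id=qid,
                compound_name=best.entry.name,
                level=level,
                score=best.score,
                formula=best.entry.formula,
                sources=attribute_sources(best.entry),
                precursor_mz=spec.precursor_mz,
                rt=query_rt,
                precursor_ppm_error=best.precursor_ppm,
                rt_error_min=best.rt_error,
                n_matched_fragments=best.n_matched_fragments,
            )
        else:
            ann = Annotation(
                feature_id=qid,
                compound_name=None,
                level=level,
                precursor_mz=spec.precursor_mz,
                rt=query_rt,
            )
        annotations.append(ann)
    return annotations


def transfer_annotations(
    ms1_table: FeatureTable,
    pooled_annotations: Iterable[Annotation],
    rt_tol: float = TRANSFER_RT_TOL,
    ppm_tol: float = TRANSFER_PPM_TOL,
) -> tuple[dict[str, Annotation], list[Annotation]]:
    """Attach pooled-sample annotations to MS1 features.

    An annotation lands on the feature with |dRT| <= rt_tol and mass error
    <= ppm_tol; among several qualifying features the lowest ppm error wins.
    When several annotations hit the same feature, the better one (lower
    level, then higher score) is kept. Returns (feature_id -> Annotation,
    unmatched annotations).
    """
    feats = ms1_table.features
    mzs = feats["mz"].to_numpy()
    rts = feats["rt"].to_numpy()
    ids = list(feats.index)
    attached: dict[str, Annotation] = {}
    unmatched: list[Annotation] = []
    for ann in pooled_annotations:
        if ann.precursor_mz is None or ann.rt is None:
            unmatched.append(ann)
            continue
        ppm = np.abs(mzs - ann.precursor_mz) / ann.precursor_mz * 1e6
        drt = np.abs(rts - ann.rt)
        ok = (ppm <= ppm_tol) & (drt <= rt_tol)
        if not ok.any():
            unmatched.append(ann)
            continue
        cand = np.nonzero(ok)[0]
        winner = ids[cand[np.argmin(ppm[cand])]]
        placed = Annotation(
            feature_id=winner,
            compound_name=ann.compound_name,
            level=ann.level,
            score=ann.score,
            formula=ann.formula,
            sources=ann.sources,
            precursor_mz=ann.precursor_mz,
            rt=ann.rt,
            precursor_ppm_error=float(ppm[cand].min()),
            rt_error_min=float(drt[cand[np.argmin(ppm[cand])]]),
            n_matched_fragments=ann.n_matched_fragments,
        )
        prev = attached.get(winner)
        if prev is None or (placed.level, -placed.score) < (prev.level, -prev.score):
            attached[winner] = placed
    return attached, unmatched


def annotations_to_frame(annotations: Iterable[Annotation]) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        rows.append(
            {
                "feature_id": ann.feature_id,
                "compound_name": ann.compound_name,
                "level": ann.level,
                "score": ann.score,
                "formula": ann.formula,
                "sources": "|".join(sorted(ann.sources)),
                "precursor_mz": ann.precursor_mz,
                "rt": ann.rt,
                "precursor_ppm_error": ann.precursor_ppm_error,
                "rt_error_min": ann.rt_error_min,
                "n_matched_fragments": ann.n_matched_fragments,
            }
        )
    return pd.DataFrame(rows)


def detection_frequency_by_group(
    table: FeatureTable,
    annotations: Mapping[str, Annotation],
    group_label: str = "outcome",
    levels: Sequence[int] = (1, 2),
    noise_floor: float = NOISE_FLOOR,
) -> pd.DataFrame:
    """Percent of samples with a detection per annotated compound, split by
    group and matrix; empty groups report NaN."""
    detected = table.detected(noise_floor)
    samples = table.samples
    groups = [g for g in samples[group_label].dropna().unique()]
    matrices = [m for m in samples["matrix"].unique() if m != "blank"]
    rows = []
    for fid, ann in annotations.items():
        if ann.level not in levels or fid not in detected.index:
            continue
        row = {"feature_id": fid, "compound_name": ann.compound_name, "level": ann.level}
        for matrix in matrices:
            for group in groups:
                mask = (samples["matrix"] == matrix) & (samples[group_label] == group)
                cols = samples.index[mask]
                key = f"pct_{matrix}_{group}"
                row[key] = (
                    100.0 * detected.loc[fid, cols].mean() if len(cols) else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)
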