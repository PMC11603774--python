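"""Feature-filtering cascade: adduct removal, blank filtering, detection
frequency cutoff, product-ion filter and cross-polarity (ESI+/ESI-) merging.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .chem import HYDROGEN_MASS
from .types import (
    FeatureTable,
    MergeRecord,
    Spectrum,
    ValidationError,
    NOISE_FLOOR,
)

log = logging.getLogger(__name__)

DEFAULT_PPM_TOL = 5.0     # merge mass tolerance, ppm (inclusive)
DEFAULT_RT_TOL = 0.5      # merge RT tolerance, minutes (exclusive)
DEFAULT_BLANK_RATIO = 1.0 / 3.0
DEFAULT_FREQUENCY_CUTOFF = 0.70
DEFAULT_MIN_FRAGMENTS = 2


def remove_linked_adducts(table: FeatureTable) -> FeatureTable:
    """Drop features whose ``adduct_link`` resolves (transitively) to another
    retained feature; chain roots are kept."""
    feats = table.features
    if "adduct_link" not in feats.columns:
        return table.copy()
    links = feats["adduct_link"].dropna()
    missing = set(links) - set(feats.index)
    if missing:
        raise ValidationError(
            f"adduct_link points to unknown feature(s): {sorted(missing)[:5]}"
        )
    link_map = links.to_dict()

    def root_of(fid: str) -> str:
        seen = {fid}
        while fid in link_map:
            fid = link_map[fid]
            if fid in seen:
                raise ValidationError(f"adduct_link cycle involving {fid!r}")
            seen.add(fid)
        return fid

    keep = [fid for fid in feats.index if root_of(fid) == fid]
    dropped = len(feats) - len(keep)
    if dropped:
        log.info("remove_linked_adducts: dropped %d linked adduct features", dropped)
    return table.subset_features(keep)


def filter_blanks(
    table: FeatureTable,
    blanks: FeatureTable | pd.DataFrame,
    ratio_threshold: float = DEFAULT_BLANK_RATIO,
) -> FeatureTable:
    """Drop features whose mean blank area reaches ``ratio_threshold`` times
    the mean sample area. Missing areas count as zero signal."""
    blank_ab = blanks.abundance if isinstance(blanks, FeatureTable) else blanks
    if blank_ab.shape[1] == 0:
        raise ValueError("blank set is empty")
    blank_ab = blank_ab.reindex(table.abundance.index)
    blank_mean = blank_ab.fillna(0.0).mean(axis=1)
    sample_mean = table.abundance.fillna(0.0).mean(axis=1)
    drop = blank_mean >= ratio_threshold * sample_mean
    # a silent blank (mean 0) can never reach the threshold unless the
    # sample mean is itself 0, in which case the feature carries no signal
    drop &= blank_mean > 0
    keep = table.abundance.index[~drop]
    if drop.any():
        log.info("filter_blanks: dropped %d blank-dominated features", int(drop.sum()))
    return table.subset_features(keep)


def apply_frequency_cutoff(
    table: FeatureTable,
    cutoff_fraction: float = DEFAULT_FREQUENCY_CUTOFF,
    noise_floor: float = NOISE_FLOOR,
) -> FeatureTable:
    """Retain features detected (non-missing and above the noise floor) in at
    least ``cutoff_fraction`` of samples. The cutoff is inclusive; a feature
    with zero detections is always dropped. The observed detection frequency
    is stored in the feature metadata."""
    if not (0.0 <= cutoff_fraction <= 1.0):
        raise ValueError("cutoff_fraction must be in [0, 1]")
    detected = table.detected(noise_floor)
    freq = detected.mean(axis=1)
    keep_mask = (freq >= cutoff_fraction) & (detected.sum(axis=1) > 0)
    out = table.subset_features(table.abundance.index[keep_mask])
    out.features["detection_frequency"] = freq[keep_mask]
    dropped = int((~keep_mask).sum())
    if dropped:
        log.info(
            "apply_frequency_cutoff(%.0f%%): dropped %d features",
            100 * cutoff_fraction, dropped,
        )
    return out


def require_product_ions(
    feature_ids: Iterable[str],
    spectra: Mapping[str, Spectrum],
    min_fragments: int = DEFAULT_MIN_FRAGMENTS,
) -> list[str]:
    """Keep feature ids that have an MS2 spectrum with >= min_fragments fragments."""
    return [
        fid
        for fid in feature_ids
        if fid in spectra and spectra[fid].n_fragments >= min_fragments
    ]


def neutral_mass(mz: float | np.ndarray, ion_mode: str, h_mass: float = HYDROGEN_MASS):
    """Neutral mass of an [M+H]+ or [M-H]- ion."""
    if ion_mode == "positive":
        return mz - h_mass
    if ion_mode == "negative":
        return mz + h_mass
    raise ValueError(f"unknown ion mode {ion_mode!r}")


def find_merge_pairs(
    pos: FeatureTable,
    neg: FeatureTable,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    h_mass: float = HYDROGEN_MASS,
) -> list[MergeRecord]:
    """One-to-one cross-polarity pairs: mass error <= ppm_tol (ppm of the mean
    neutral mass) and |dRT| < rt_tol, matched greedily by ascending ppm error
    with ties broken by smaller dRT, then lexicographic feature ids."""
    pos_neutral = neutral_mass(pos.features["mz"].to_numpy(), "positive", h_mass)
    neg_neutral = neutral_mass(neg.features["mz"].to_numpy(), "negative", h_mass)
    pos_rt = pos.features["rt"].to_numpy()
    neg_rt = neg.features["rt"].to_numpy()

    mean_mass = 0.5 * (pos_neutral[:, None] + neg_neutral[None, :])
    ppm = np.abs(pos_neutral[:, None] - neg_neutral[None, :]) / mean_mass * 1e6
    drt = np.abs(pos_rt[:, None] - neg_rt[None, :])
    cand_i, cand_j = np.nonzero((ppm <= ppm_tol) & (drt < rt_tol))

    pos_ids = list(pos.features.index)
    neg_ids = list(neg.features.index)
    candidates = sorted(
        (
            (ppm[i, j], drt[i, j], pos_ids[i], neg_ids[j], i, j)
            for i, j in zip(cand_i, cand_j)
        ),
        key=lambda t: (t[0], t[1], t[2], t[3]),
    )
    used_pos: set[str] = set()
    used_neg: set[str] = set()
    records: list[MergeRecord] = []
    for err, d, pid, nid, i, j in candidates:
        if pid in used_pos or nid in used_neg:
            continue
        used_pos.add(pid)
        used_neg.add(nid)
        records.append(
            MergeRecord(
                pos_feature_id=pid,
                neg_feature_id=nid,
                neutral_mass_pos=float(pos_neutral[i]),
                neutral_mass_neg=float(neg_neutral[j]),
                mass_error_ppm=float(err),
                delta_rt=float(d),
            )
        )
    return records


def merge_esi_modes(
    pos: FeatureTable,
    neg: FeatureTable,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    h_mass: float = HYDROGEN_MASS,
) -> tuple[FeatureTable, list[MergeRecord]]:
    """Merge the ESI+ and ESI- tables into one.

    For each matched pair the mode whose areas have the higher median
    becomes the representative row (its abundances feed downstream
    statistics); the partner id and mean neutral mass are recorded.
    Unpaired features pass through unchanged.
    """
    if list(pos.samples.index) != list(neg.samples.index):
        raise ValidationError("positive and negative tables have different samples")
    records = find_merge_pairs(pos, neg, ppm_tol, rt_tol, h_mass)

    pos_out = pos.features.copy()
    neg_out = neg.features.copy()
    for df, nm in ((pos_out, "positive"), (neg_out, "negative")):
        df["partner_id"] = pd.NA
        df["neutral_mass"] = neutral_mass(df["mz"].to_numpy(), nm, h_mass)

    absorbed_pos: set[str] = set()
    absorbed_neg: set[str] = set()
    for rec in records:
        pos_median = pos.abundance.loc[rec.pos_feature_id].median(skipna=True)
        neg_median = neg.abundance.loc[rec.neg_feature_id].median(skipna=True)
        mean_neutral = 0.5 * (rec.neutral_mass_pos + rec.neutral_mass_neg)
        if (neg_median > pos_median) if not np.isnan(neg_median) else False:
            keep_df, keep_id = neg_out, rec.neg_feature_id
            absorbed_pos.add(rec.pos_feature_id)
            partner = rec.pos_feature_id
        else:
            keep_df, keep_id = pos_out, rec.pos_feature_id
            absorbed_neg.add(rec.neg_feature_id)
            partner = rec.neg_feature_id
        keep_df.loc[keep_id, "partner_id"] = partner
        keep_df.loc[keep_id, "neutral_mass"] = mean_neutral

    keep_pos = [f for f in pos_out.index if f not in absorbed_pos]
    keep_neg = [f for f in neg_out.index if f not in absorbed_neg]
    features = pd.concat([pos_out.loc[keep_pos], neg_out.loc[keep_neg]])
    abundance = pd.concat(
        [pos.abundance.loc[keep_pos], neg.abundance.loc[keep_neg]]
    )
    merged = FeatureTable(features, abundance, pos.samples.copy()).validate()
    log.info(
        "merge_esi_modes: %d pairs merged; %d features in merged table",
        len(records), merged.n_features,
    )
    return merged, records


def run_filter_cascade(
    pos: FeatureTable,
    neg: FeatureTable,
    pos_blanks: Optional[FeatureTable] = None,
    neg_blanks: Optional[FeatureTable] = None,
    cutoff_fraction: float = DEFAULT_FREQUENCY_CUTOFF,
    blank_ratio: float = DEFAULT_BLANK_RATIO,
    noise_floor: float = NOISE_FLOOR,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> tuple[FeatureTable, list[MergeRecord], dict]:
    """Adducts -> blanks -> frequency -> ESI merge, with per-stage counts."""
    report: dict = {"input": {"pos": pos.n_features, "neg": neg.n_features}}
    pos, neg = remove_linked_adducts(pos), remove_linked_adducts(neg)
    report["after_adducts"] = {"pos": pos.n_features, "neg": neg.n_features}
    if pos_blanks is not None and pos_blanks.n_samples:
        pos = filter_blanks(pos, pos_blanks, blank_ratio)
    if neg_blanks is not None and neg_blanks.n_samples:
        neg = filter_blanks(neg, neg_blanks, blank_ratio)
    report["after_blanks"] = {"pos": pos.n_features, "neg": neg.n_features}
    pos = apply_frequency_cutoff(pos, cutoff_fraction, noise_floor)
    neg = apply_frequency_cutoff(neg, cutoff_fraction, noise_floor)
    report["after_frequency"] = {"pos": pos.n_features, "neg": neg.n_features}
    merged, records = merge_esi_modes(pos, neg, ppm_tol, rt_tol)
    report["merged"] = {"pairs": len(records), "features": merged.n_features}
    return merged, records, report
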