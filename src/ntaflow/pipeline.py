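"""End-to-end orchestration: filter -> merge -> normalize/impute -> batch
correct -> annotate -> stats -> network, with every intermediate written out
and a JSON run manifest of per-stage feature counts.

All randomness flows from a single top-level seed; identical config + seed
gives byte-identical outputs (no timestamps are written anywhere).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotate as ann_mod
from . import diffstats, filtering, io_formats, network as net_mod, normalize, synth
from .types import ConfigError, FeatureTable, NOISE_FLOOR

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the published operating points."""

    # inputs (ignored when simulate=True)
    pos_alignment: Optional[str] = None
    neg_alignment: Optional[str] = None
    manifest: Optional[str] = None
    spectra_msp: Optional[str] = None
    library_msp: Optional[str] = None

    simulate: bool = False
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)

    frequency_cutoff: float = 0.70
    noise_floor: float = 10_000.0
    blank_ratio: float = 1.0 / 3.0
    merge_ppm_tol: float = 5.0          # cross-polarity mass tolerance
    merge_rt_tol: float = 0.5           # minutes
    transfer_rt_tol: float = 0.1        # annotation transfer, minutes
    transfer_ppm_tol: float = 2.0
    level1_rt_tol: float = 0.05
    level1_ppm_tol: float = 5.0
    level2_score: float = 90.0
    creatinine_strategy: str = "median-ratio"
    mdl: Optional[float] = None         # defaults to sim.mdl when simulating
    p_cut: float = 0.05
    fc_cut: float = 1.2
    network_r: float = 0.5
    network_levels: tuple = (1, 2)
    seed: int = 17

    run_annotation: bool = True
    run_network: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = io_formats.read_yaml(path)
        sim_data = data.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if sim_data:
            cfg.sim = synth.SimConfig(**sim_data)
        return cfg


def _write_table(table: FeatureTable, out_dir: Path, name: str) -> None:
    io_formats.write_alignment(table, out_dir / f"{name}.csv")


def run_pipeline(
    config: PipelineConfig, out_dir, seed: Optional[int] = None
) -> dict:
    """Execute the full workflow; returns the run manifest (also written to
    ``run_manifest.json`` in ``out_dir``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.seed = seed
        config.sim.seed = seed
    manifest: dict = {"seed": config.seed, "stages": {}}

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        sample_manifest, pos_all, neg_all, spectra, library, truth = synth.simulate(
            config.sim
        )
        pos, pos_blanks = io_formats.split_blanks(pos_all)
        neg, neg_blanks = io_formats.split_blanks(neg_all)
        mdl = config.mdl if config.mdl is not None else config.sim.mdl
        io_formats.write_manifest(pos_all.samples, out_dir / "manifest.csv")
        _write_table(pos_all, out_dir, "input_pos")
        _write_table(neg_all, out_dir, "input_neg")
        io_formats.write_msp(library, out_dir / "library.msp")
    else:
        for req in ("pos_alignment", "neg_alignment", "manifest"):
            if getattr(config, req) is None:
                raise ConfigError(f"pipeline input {req!r} is required unless simulating")
        sample_manifest = io_formats.read_manifest(config.manifest)
        pos_all = io_formats.read_alignment(
            config.pos_alignment, "positive", sample_manifest
        )
        neg_all = io_formats.read_alignment(
            config.neg_alignment, "negative", sample_manifest
        )
        pos, pos_blanks = io_formats.split_blanks(pos_all)
        neg, neg_blanks = io_formats.split_blanks(neg_all)
        mdl = config.mdl
        spectra = {}
        library = (
            io_formats.read_msp(config.library_msp) if config.library_msp else []
        )
        pooled_rts = {}
        if config.spectra_msp:
            pooled = io_formats.read_msp(config.spectra_msp)
            spectra = {e.name: e.spectrum for e in pooled}
            pooled_rts = {e.name: e.rt for e in pooled if e.rt is not None}
    manifest["stages"]["input"] = {"pos": pos.n_features, "neg": neg.n_features}

    # ---- filtering cascade ----------------------------------------------
    merged, merge_records, filter_report = filtering.run_filter_cascade(
        pos,
        neg,
        pos_blanks,
        neg_blanks,
        cutoff_fraction=config.frequency_cutoff,
        blank_ratio=config.blank_ratio,
        noise_floor=config.noise_floor,
        ppm_tol=config.merge_ppm_tol,
        rt_tol=config.merge_rt_tol,
    )
    manifest["stages"].update(filter_report)
    _write_table(merged, out_dir, "merged")
    pd.DataFrame([dataclasses.asdict(r) for r in merge_records]).to_csv(
        out_dir / "merge_records.csv", index=False
    )

    # ---- normalization / imputation / batch correction -------------------
    normalized = normalize.creatinine_normalize(merged, config.creatinine_strategy)
    imputed = normalize.impute_below_mdl(normalized, seed=config.seed, mdl=mdl)
    manifest["stages"]["imputed"] = {
        "features": imputed.n_features,
        "filled_cells": int(merged.abundance.isna().sum().sum()),
    }
    _write_table(imputed, out_dir, "imputed")

    pca_pre = diffstats.run_pca(imputed)
    corrected, batch_model = normalize.combat_correct(imputed)
    pca_post = diffstats.run_pca(corrected)
    manifest["stages"]["batch_corrected"] = {"features": corrected.n_features}
    _write_table(corrected, out_dir, "corrected")
    (out_dir / "batch_model.json").write_text(
        json.dumps(batch_model.to_dict(), indent=1, sort_keys=True)
    )
    pca_payload = {
        "pre": {
            "variance_explained": pca_pre.variance_explained.tolist(),
            "covariate_correlations": pca_pre.covariate_correlations.to_dict("records"),
        },
        "post": {
            "variance_explained": pca_post.variance_explained.tolist(),
            "covariate_correlations": pca_post.covariate_correlations.to_dict("records"),
        },
    }
    (out_dir / "pca_summary.json").write_text(
        json.dumps(pca_payload, indent=1, sort_keys=True)
    )

    # ---- annotation ------------------------------------------------------
    attached: dict = {}
    if config.run_annotation and spectra:
        usable = filtering.require_product_ions(sorted(spectra), spectra)
        manifest["stages"]["ms2_features"] = {
            "with_spectra": len(spectra),
            "with_product_ions": len(usable),
        }
        if config.simulate and truth.feature_meta is not None:
            rts = truth.feature_meta["rt"].to_dict()
        else:
            rts = pooled_rts
        pooled_annotations = ann_mod.annotate_spectra(
            {fid: spectra[fid] for fid in usable}, library, rts=rts
        )
        attached, unmatched = ann_mod.transfer_annotations(
            corrected,
            pooled_annotations,
            rt_tol=config.transfer_rt_tol,
            ppm_tol=config.transfer_ppm_tol,
        )
        manifest["stages"]["annotation"] = {
            "pooled_annotations": len(pooled_annotations),
            "attached": len(attached),
            "unmatched": len(unmatched),
            "level_counts": {
                str(level): sum(1 for a in attached.values() if a.level == level)
                for level in (1, 2, 3, 4, 5)
            },
        }
        ann_mod.annotations_to_frame(attached.values()).to_csv(
            out_dir / "annotations.csv", index=False
        )
        freq = ann_mod.detection_frequency_by_group(merged, attached)
        freq.to_csv(out_dir / "detection_frequency.csv", index=False)

    # ---- differential statistics ----------------------------------------
    diff_outputs = {}
    for matrix in ("serum", "urine"):
        cols = corrected.samples.index[corrected.samples["matrix"] == matrix]
        sub = corrected.subset_samples(cols)
        results = diffstats.volcano_classify(
            diffstats.differential_test(sub), p_cut=config.p_cut, fc_cut=config.fc_cut
        )
        results.to_csv(out_dir / f"differential_{matrix}.csv")
        diff_outputs[matrix] = results
        manifest["stages"][f"differential_{matrix}"] = {
            "tested": len(results),
            "up": int((results["volcano_class"] == "up").sum()),
            "down": int((results["volcano_class"] == "down").sum()),
        }

    # ---- network ---------------------------------------------------------
    if config.run_network and attached:
        serum_cols = corrected.samples.index[corrected.samples["matrix"] == "serum"]
        serum = corrected.subset_samples(serum_cols)
        graph = net_mod.build_network(
            serum, attached, r_threshold=config.network_r, levels=config.network_levels
        )
        graph = net_mod.group_proportions(graph, merged.subset_samples(serum_cols))
        io_formats.write_graph(graph, out_dir / "network.json", "node-link")
        io_formats.write_graph(graph, out_dir / "network.graphml", "graphml")
        manifest["stages"]["network"] = net_mod.network_summary(graph)

    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
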