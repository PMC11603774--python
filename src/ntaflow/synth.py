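"""Synthetic cohort and feature-table generator.

Emulates the statistical structure the downstream pipeline assumes:
paired serum/urine samples across four instrument batches, log-normal
feature abundances with planted batch shift/scale effects, below-MDL
censoring, group-differential features, cross-polarity ion pairs of shared
neutral molecules (plus decoy near-pairs), adduct satellites linked to
parents, latent-factor correlation clusters, and MS2 spectra with a
matching library that plants every annotation confidence level.

All abundances are simulated on log10 scale and exponentiated; batch
effects are additive in log space with per-batch variance scaling, which
is exactly the model the parametric batch correction assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .chem import HYDROGEN_MASS
from .types import (
    ConfigError,
    FeatureTable,
    Spectrum,
    SpectralLibraryEntry,
    NOISE_FLOOR,
)

LOG2 = np.log10(2.0)  # log2 fold changes expressed on the log10 scale


@dataclass
class SimConfig:
    """Knobs for one synthetic cohort; defaults mirror the study design."""

    n_samples: int = 95          # participant pairs (each has serum + urine)
    n_preterm: int = 35
    n_batches: int = 4
    n_features_pos: int = 300
    n_features_neg: int = 200
    n_shared_neutrals: int = 40
    n_differential: int = 30
    effect_log2fc: float = 2.0
    differential_matrix: str = "serum"
    batch_shift: tuple = (0.0, 0.3, -0.2, 0.1)    # additive, log10 scale
    batch_scale: tuple = (1.0, 1.2, 0.9, 1.1)     # noise sd multipliers
    mdl: float = 20_000.0        # linear-area censoring threshold
    missing_rate: float = 0.10   # per-feature target censoring fraction
    n_corr_clusters: int = 4
    cluster_size: int = 6
    cluster_r: float = 0.7
    n_rare: int = 15             # extra features censored ~50% (fail 70% cutoff)
    n_blank_high: int = 8        # extra features as abundant in blanks as samples
    n_adducts: int = 20          # satellite features linked to parents
    n_decoy_pairs: int = 8       # near-pairs violating one merge tolerance
    n_blanks: int = 3
    creatinine_median: float = 100.0  # mg/dL
    creatinine_gsd: float = 1.5
    seed: int = 17

    def validate(self) -> "SimConfig":
        if not (0 < self.n_preterm < self.n_samples):
            raise ConfigError("need 0 < n_preterm < n_samples")
        if self.n_batches < 1 or self.n_batches > self.n_samples:
            raise ConfigError("n_batches must be in [1, n_samples]")
        if len(self.batch_shift) < self.n_batches or len(self.batch_scale) < self.n_batches:
            raise ConfigError("batch_shift/batch_scale shorter than n_batches")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (-1.0 < self.cluster_r < 1.0):
            raise ConfigError("cluster_r must be in (-1, 1)")
        if self.differential_matrix not in ("serum", "urine"):
            raise ConfigError("differential_matrix must be serum or urine")
        planted = (
            self.n_shared_neutrals
            + self.n_differential
            + self.n_corr_clusters * self.cluster_size
        )
        if planted > self.n_features_pos:
            raise ConfigError(
                f"n_features_pos={self.n_features_pos} too small for "
                f"{planted} planted features"
            )
        if self.n_shared_neutrals > self.n_features_neg:
            raise ConfigError("n_features_neg smaller than n_shared_neutrals")
        if self.mdl < 0:
            raise ConfigError("mdl must be >= 0")
        return self


@dataclass
class GroundTruth:
    """Everything the generators planted, for recovery-oracle tests."""

    differential_feature_ids: set = field(default_factory=set)
    pair_map: dict = field(default_factory=dict)          # pos id -> neg id
    decoy_pairs: list = field(default_factory=list)       # (pos id, neg id)
    adduct_map: dict = field(default_factory=dict)        # child id -> parent id
    cluster_memberships: list = field(default_factory=list)  # list of sets
    batch_params: dict = field(default_factory=dict)      # {"shift": {b: v}, "scale": ...}
    feature_meta: Optional[pd.DataFrame] = None           # all features, both modes
    latent: dict = field(default_factory=dict)            # mode -> log10 latent DataFrame
    annotation_plan: dict = field(default_factory=dict)   # feature id -> planted role
    rare_feature_ids: set = field(default_factory=set)
    blank_high_ids: set = field(default_factory=set)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample manifest: one serum + one urine record per participant.

    Batch labels are assigned round-robin over batches (paired matrices stay
    in the same batch, mirroring urine run alongside its serum); outcome has
    exactly ``n_preterm`` preterm participants; urine records carry positive
    creatinine from a lognormal(median, gsd).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants = [f"P{i + 1:03d}" for i in range(config.n_samples)]
    batches = [(i % config.n_batches) + 1 for i in range(config.n_samples)]
    # outcomes are stratified over batches (mirroring randomized run
    # positioning): without this, batch-outcome confounding lets any batch
    # correction legitimately absorb part of a planted group effect
    by_batch: dict[int, list[int]] = {}
    for i, b in enumerate(batches):
        by_batch.setdefault(b, []).append(i)
    quota = {b: (config.n_preterm * len(idx)) // config.n_samples for b, idx in by_batch.items()}
    shortfall = config.n_preterm - sum(quota.values())
    for b in rng.permutation(sorted(by_batch))[:shortfall]:
        quota[b] += 1
    preterm_idx: set[int] = set()
    for b, idx in sorted(by_batch.items()):
        chosen = rng.choice(idx, size=quota[b], replace=False)
        preterm_idx.update(int(i) for i in chosen)
    creat = np.exp(
        rng.normal(
            np.log(config.creatinine_median),
            np.log(config.creatinine_gsd),
            size=config.n_samples,
        )
    )
    rows = []
    for i, pid in enumerate(participants):
        outcome = "preterm" if i in preterm_idx else "term"
        for matrix in ("serum", "urine"):
            rows.append(
                {
                    "sample_id": f"{pid}-{matrix}",
                    "participant": pid,
                    "matrix": matrix,
                    "batch": batches[i],
                    "outcome": outcome,
                    "creatinine": float(creat[i]) if matrix == "urine" else np.nan,
                }
            )
    manifest = pd.DataFrame(rows).set_index("sample_id")
    truth = GroundTruth(
        batch_params={
            "shift": {b + 1: float(config.batch_shift[b]) for b in range(config.n_batches)},
            "scale": {b + 1: float(config.batch_scale[b]) for b in range(config.n_batches)},
        }
    )
    return manifest, truth


def _feature_mu(rng, sigma, config: SimConfig, censor_target: Optional[float]) -> float:
    """Baseline log10 mean; censor_target pins the expected below-MDL fraction."""
    if censor_target is None or config.mdl <= 0:
        return float(rng.uniform(4.8, 7.0))
    target = float(np.clip(censor_target, 1e-4, 0.95))
    return float(np.log10(config.mdl) - sigma * stats.norm.ppf(target))


def _declash(mz: float, reserved: np.ndarray, min_da: float = 0.01) -> float:
    """Nudge a random m/z away from reserved masses so no accidental pairs form."""
    while reserved.size and np.min(np.abs(reserved - mz)) < min_da:
        mz += 0.05
    return mz


def generate_feature_tables(
    config: SimConfig, manifest: pd.DataFrame, truth: Optional[GroundTruth] = None
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Generate the ESI+ and ESI- feature tables plus ground truth.

    Blank columns (matrix == 'blank') are appended to both tables; split
    them off with :func:`ntaflow.io_formats.split_blanks`.
    """
    config.validate()
    if truth is None:
        truth = GroundTruth(
            batch_params={
                "shift": {b + 1: float(config.batch_shift[b]) for b in range(config.n_batches)},
                "scale": {b + 1: float(config.batch_scale[b]) for b in range(config.n_batches)},
            }
        )
    rng = np.random.default_rng(config.seed + 1)

    n_pairs = config.n_shared_neutrals
    pair_neutrals = np.sort(rng.uniform(150.0, 600.0, size=n_pairs))
    # keep planted pair masses well separated so greedy matching is unambiguous
    for i in range(1, n_pairs):
        if pair_neutrals[i] - pair_neutrals[i - 1] < 0.05:
            pair_neutrals[i] = pair_neutrals[i - 1] + 0.05
    # decoy near-pairs share one neutral/RT base across modes so that each
    # violates exactly one merge tolerance (alternating: mass ppm, then RT)
    decoy_rng = np.random.default_rng(config.seed + 7)
    decoy_neutrals = 700.0 + 10.0 * np.arange(config.n_decoy_pairs) + decoy_rng.uniform(
        0, 2, config.n_decoy_pairs
    )
    decoy_rts = decoy_rng.uniform(1.0, 24.0, config.n_decoy_pairs)
    decoy_ppm = decoy_rng.uniform(10, 20, config.n_decoy_pairs) * decoy_rng.choice(
        [-1, 1], config.n_decoy_pairs
    )
    decoy_drt = decoy_rng.uniform(0.6, 1.0, config.n_decoy_pairs)

    pair_rng = np.random.default_rng(config.seed + 11)
    pair_rts = pair_rng.uniform(1.0, 24.0, n_pairs)
    pair_neg_ppm = pair_rng.uniform(-1.0, 1.0, n_pairs)     # <=1 ppm mass jitter
    pair_neg_drt = pair_rng.uniform(-0.2, 0.2, n_pairs)     # inside RT tolerance

    # random m/z values are nudged away from all planted ion masses so no
    # accidental cross-polarity match can form or steal a planted partner
    reserved = np.concatenate(
        [
            pair_neutrals + HYDROGEN_MASS,
            pair_neutrals - HYDROGEN_MASS,
            decoy_neutrals + HYDROGEN_MASS,
            decoy_neutrals - HYDROGEN_MASS,
        ]
    )

    sample_ids = list(manifest.index)
    blank_ids = [f"BLANK{i + 1}" for i in range(config.n_blanks)]
    n_samp = len(sample_ids)
    batch_of = manifest["batch"].to_numpy()
    shift = np.array([config.batch_shift[b - 1] for b in batch_of])
    scale = np.array([config.batch_scale[b - 1] for b in batch_of])
    is_diff_target = (
        (manifest["matrix"] == config.differential_matrix)
        & (manifest["outcome"] == "preterm")
    ).to_numpy()
    is_diff_ref = (
        (manifest["matrix"] == config.differential_matrix)
        & (manifest["outcome"] == "term")
    ).to_numpy()

    cluster_factors = rng.normal(size=(config.n_corr_clusters, n_samp))

    def build_mode(mode: str) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        prefix = "P" if mode == "positive" else "N"
        n_base = config.n_features_pos if mode == "positive" else config.n_features_neg
        records = []
        latent_rows = []
        blank_rows = []

        def add_feature(fid, mz, rt, role, mu, sigma, link=None,
                        cluster=None, differential=False, blank_level=None,
                        base_eps=None):
            eps = base_eps if base_eps is not None else rng.normal(0.0, 1.0, n_samp)
            vals = mu + shift + sigma * scale * eps
            if cluster is not None:
                lam = sigma * np.sqrt(config.cluster_r / (1.0 - config.cluster_r))
                vals = vals + lam * cluster_factors[cluster]
            if differential:
                # plant the effect conditionally: offset the target group so
                # the empirical latent group-mean difference is exact
                d0 = vals[is_diff_target].mean() - vals[is_diff_ref].mean()
                vals = vals + (config.effect_log2fc * LOG2 - d0) * is_diff_target
            latent_rows.append(vals)
            if blank_level is None:
                blanks = rng.normal(3.2, 0.3, config.n_blanks)
            else:
                blanks = rng.normal(blank_level, 0.1, config.n_blanks)
            blank_rows.append(blanks)
            records.append(
                {
                    "feature_id": fid,
                    "mz": mz,
                    "rt": rt,
                    "ion_mode": mode,
                    "adduct_link": link,
                    "role": role,
                }
            )
            return vals

        counter = 0

        def next_id():
            nonlocal counter
            counter += 1
            return f"{prefix}{counter:04d}"

        censor = config.missing_rate if config.missing_rate > 0 else None

        # --- cross-polarity pair partners -------------------------------
        for i in range(n_pairs):
            fid = next_id()
            sigma = rng.uniform(0.15, 0.35)
            mu = _feature_mu(rng, sigma, config, censor)
            if mode == "positive":
                mz = pair_neutrals[i] + HYDROGEN_MASS
                rt = pair_rts[i]
            else:
                mz = (pair_neutrals[i] - HYDROGEN_MASS) * (1 + pair_neg_ppm[i] * 1e-6)
                rt = pair_rts[i] + pair_neg_drt[i]
            add_feature(fid, mz, rt, "pair", mu, sigma)
            if mode == "positive":
                truth.pair_map[fid] = f"N{i + 1:04d}"

        if mode == "positive":
            # --- differential features ----------------------------------
            for _ in range(config.n_differential):
                fid = next_id()
                sigma = rng.uniform(0.15, 0.35)
                mu = _feature_mu(rng, sigma, config, None)
                mz = _declash(rng.uniform(100.0, 800.0), reserved)
                add_feature(fid, mz, rng.uniform(0.5, 24.5), "differential",
                            mu, sigma, differential=True)
                truth.differential_feature_ids.add(fid)
            # --- correlation clusters -----------------------------------
            for c in range(config.n_corr_clusters):
                members = set()
                for _ in range(config.cluster_size):
                    fid = next_id()
                    sigma = rng.uniform(0.15, 0.35)
                    mu = _feature_mu(rng, sigma, config, None)
                    mz = _declash(rng.uniform(100.0, 800.0), reserved)
                    add_feature(fid, mz, rng.uniform(0.5, 24.5), "cluster",
                                mu, sigma, cluster=c)
                    members.add(fid)
                truth.cluster_memberships.append(members)

        # --- background --------------------------------------------------
        while counter < n_base:
            fid = next_id()
            sigma = rng.uniform(0.15, 0.35)
            mu = _feature_mu(rng, sigma, config, censor)
            mz = _declash(rng.uniform(100.0, 800.0), reserved)
            add_feature(fid, mz, rng.uniform(0.5, 24.5), "background", mu, sigma)

        # --- rarely-detected features (fail the 70% frequency cutoff) ---
        n_rare = config.n_rare if mode == "positive" else config.n_rare // 2
        if config.mdl > 0:
            for _ in range(n_rare):
                fid = next_id()
                sigma = rng.uniform(0.15, 0.35)
                mu = _feature_mu(rng, sigma, config, 0.55)
                mz = _declash(rng.uniform(100.0, 800.0), reserved)
                add_feature(fid, mz, rng.uniform(0.5, 24.5), "rare", mu, sigma)
                truth.rare_feature_ids.add(fid)

        # --- blank-contaminated features --------------------------------
        n_bh = config.n_blank_high if mode == "positive" else config.n_blank_high // 2
        for _ in range(n_bh):
            fid = next_id()
            sigma = rng.uniform(0.15, 0.35)
            mu = float(rng.uniform(5.0, 6.5))
            mz = _declash(rng.uniform(100.0, 800.0), reserved)
            add_feature(fid, mz, rng.uniform(0.5, 24.5), "blank_high",
                        mu, sigma, blank_level=mu)
            truth.blank_high_ids.add(fid)

        # --- adduct satellites linked to parents ------------------------
        n_add = config.n_adducts if mode == "positive" else config.n_adducts // 2
        parent_pool = [r for r in records if r["role"] == "background"]
        sat_shift = 21.98194 if mode == "positive" else 20.97412  # Na adducts
        for i in range(min(n_add, len(parent_pool))):
            parent = parent_pool[i]
            fid = next_id()
            pidx = next(
                j for j, r in enumerate(records) if r["feature_id"] == parent["feature_id"]
            )
            sigma = 0.05
            mu = -0.5
            eps = rng.normal(0.0, 1.0, n_samp)
            vals = latent_rows[pidx] + mu + sigma * eps
            latent_rows.append(vals)
            blank_rows.append(rng.normal(3.2, 0.3, config.n_blanks))
            records.append(
                {
                    "feature_id": fid,
                    "mz": parent["mz"] + sat_shift,
                    "rt": parent["rt"],
                    "ion_mode": mode,
                    "adduct_link": parent["feature_id"],
                    "role": "adduct",
                }
            )
            truth.adduct_map[fid] = parent["feature_id"]

        # --- decoy near-pairs (violate exactly one merge tolerance) -----
        for i in range(config.n_decoy_pairs):
            fid = next_id()
            sigma = rng.uniform(0.15, 0.35)
            mu = _feature_mu(rng, sigma, config, None)
            neutral = decoy_neutrals[i]
            rt = decoy_rts[i]
            if mode == "positive":
                mz = neutral + HYDROGEN_MASS
            else:
                if i % 2 == 0:  # mass error 10-20 ppm, RT fine
                    mz = (neutral - HYDROGEN_MASS) * (1 + decoy_ppm[i] * 1e-6)
                else:           # mass fine, RT off by 0.6-1.0 min
                    mz = neutral - HYDROGEN_MASS
                    rt = rt + decoy_drt[i]
            add_feature(fid, mz, rt, "decoy", mu, sigma)
            if mode == "positive":
                truth.decoy_pairs.append((fid, None))

        feats = pd.DataFrame(records).set_index("feature_id")
        latent = pd.DataFrame(
            np.vstack(latent_rows), index=feats.index, columns=sample_ids
        )
        blanks = pd.DataFrame(
            np.vstack(blank_rows), index=feats.index, columns=blank_ids
        )
        return feats, latent, blanks

    # decoys: positive ids are generated first; seed the negative pass with
    # matched neutral masses by regenerating deterministically. Decoy neutral
    # masses are derived from the loop index, so pos/neg decoys line up by i.
    pos_feats, pos_latent, pos_blanks = build_mode("positive")
    neg_feats, neg_latent, neg_blanks = build_mode("negative")
    truth.decoy_pairs = [
        (pos_id, neg_id)
        for (pos_id, _), neg_id in zip(
            truth.decoy_pairs,
            [fid for fid, role in zip(neg_feats.index, neg_feats["role"]) if role == "decoy"],
        )
    ]

    blank_manifest = pd.DataFrame(
        {
            "participant": pd.NA,
            "matrix": "blank",
            "batch": 1,
            "outcome": pd.NA,
            "creatinine": np.nan,
        },
        index=pd.Index(blank_ids, name="sample_id"),
    )
    full_samples = pd.concat([manifest, blank_manifest])

    def censor_table(latent: pd.DataFrame, blanks: pd.DataFrame) -> pd.DataFrame:
        linear = np.power(10.0, latent.to_numpy())
        if config.mdl > 0:
            linear = np.where(linear < config.mdl, np.nan, linear)
        blank_linear = np.power(10.0, blanks.to_numpy())
        if config.mdl > 0:
            blank_linear = np.where(blank_linear < config.mdl, np.nan, blank_linear)
        out = np.hstack([linear, blank_linear])
        return pd.DataFrame(out, index=latent.index, columns=list(latent.columns) + blank_ids)

    pos_table = FeatureTable(
        pos_feats.drop(columns=["role"]),
        censor_table(pos_latent, pos_blanks),
        full_samples.copy(),
    ).validate()
    neg_table = FeatureTable(
        neg_feats.drop(columns=["role"]),
        censor_table(neg_latent, neg_blanks),
        full_samples.copy(),
    ).validate()

    truth.feature_meta = pd.concat(
        [pos_feats.assign(table="pos"), neg_feats.assign(table="neg")]
    )
    truth.latent = {"positive": pos_latent, "negative": neg_latent}
    return pos_table, neg_table, truth


# ---------------------------------------------------------------------------
# MS2 spectra and spectral library
# ---------------------------------------------------------------------------

#: planted annotation roles, cycled over the eligible features
_PLAN_CYCLE = ("level2", "level1", "level3", "level4", "one_fragment", "none")


def generate_spectra(
    config: SimConfig, truth: GroundTruth
) -> tuple[dict[str, Spectrum], list[SpectralLibraryEntry]]:
    """Attach MS2 spectra to features and build a matching library.

    The library plants every confidence outcome: exact copies (score 100,
    Level 2), exact copies from authentic standards with RT (Level 1),
    partially-overlapping near-misses (score in (50, 90], Level 3), features
    whose spectra have no library counterpart (Level 4), one-fragment
    spectra (excluded from annotation), and spectrum-free features
    (Level 5). Cluster members always receive exact matches so the network
    stage sees them: the first member of each cluster is tagged an
    endogenous metabolite, the rest exogenous contaminants.
    """
    if truth.feature_meta is None:
        raise ConfigError("generate_spectra requires feature tables to exist")
    rng = np.random.default_rng(config.seed + 2)
    meta = truth.feature_meta
    spectra: dict[str, Spectrum] = {}
    library: list[SpectralLibraryEntry] = []

    cluster_members = [sorted(m) for m in truth.cluster_memberships]
    cluster_sources: dict[str, frozenset] = {}
    for members in cluster_members:
        for j, fid in enumerate(members):
            cluster_sources[fid] = frozenset(
                {"endogenous_metabolite" if j == 0 else "exogenous_contaminant"}
            )

    source_cycle = (
        frozenset({"endogenous_metabolite"}),
        frozenset({"exogenous_contaminant"}),
        frozenset({"drug", "natural_product", "personal_care_product"}),
        frozenset(),
        frozenset({"natural_product"}),
    )

    def random_spectrum(precursor_mz: float, mode: str, n_frag: int) -> Spectrum:
        frag_mz = rng.uniform(50.0, max(60.0, precursor_mz - 1.0), size=n_frag)
        intensities = rng.uniform(10.0, 100.0, size=n_frag)
        return Spectrum(precursor_mz, mode, np.column_stack([frag_mz, intensities]))

    eligible = meta.index[~meta["role"].isin(["adduct", "decoy", "rare", "blank_high"])]
    plan_idx = 0
    for k, fid in enumerate(eligible):
        row = meta.loc[fid]
        mode = row["ion_mode"]
        if fid in cluster_sources:
            plan = "level2"
        else:
            plan = _PLAN_CYCLE[plan_idx % len(_PLAN_CYCLE)]
            plan_idx += 1
        if plan == "none":
            truth.annotation_plan[fid] = {"level": 5}
            continue
        if plan == "one_fragment":
            spectra[fid] = random_spectrum(row["mz"], mode, 1)
            truth.annotation_plan[fid] = {"level": 5, "note": "one fragment"}
            continue
        n_frag = int(rng.integers(3, 7))
        spec = random_spectrum(row["mz"], mode, n_frag)
        spectra[fid] = spec
        shift = HYDROGEN_MASS if mode == "positive" else -HYDROGEN_MASS
        neutral = row["mz"] - shift
        sources = cluster_sources.get(
            fid, source_cycle[k % len(source_cycle)]
        )
        name = f"compound_{fid}"
        if plan == "level1":
            library.append(
                SpectralLibraryEntry(
                    name=name,
                    spectrum=Spectrum(spec.precursor_mz, mode, spec.fragments.copy()),
                    neutral_mass=neutral,
                    rt=float(row["rt"]) + 0.02,
                    sources=sources,
                    is_authentic_standard=True,
                )
            )
            truth.annotation_plan[fid] = {"level": 1, "name": name, "sources": sources}
        elif plan == "level2":
            library.append(
                SpectralLibraryEntry(
                    name=name,
                    spectrum=Spectrum(spec.precursor_mz, mode, spec.fragments.copy()),
                    neutral_mass=neutral,
                    rt=None,
                    sources=sources,
                )
            )
            truth.annotation_plan[fid] = {"level": 2, "name": name, "sources": sources}
        elif plan == "level3":
            # share ~2/3 of fragments with equal intensities: cosine in (50, 90]
            n_keep = max(2, int(np.ceil(0.6 * n_frag)))
            frags = spec.fragments.copy()
            frags[:, 1] = 50.0
            spectra[fid] = Spectrum(spec.precursor_mz, mode, frags)
            lib_frags = frags.copy()
            moved = np.arange(n_keep, n_frag)
            lib_frags[moved, 0] = rng.uniform(
                30.0, 45.0, size=len(moved)
            )  # far outside fragment tolerance
            library.append(
                SpectralLibraryEntry(
                    name=name,
                    spectrum=Spectrum(spec.precursor_mz, mode, lib_frags),
                    neutral_mass=neutral,
                    rt=None,
                    sources=sources,
                )
            )
            truth.annotation_plan[fid] = {"level": 3, "name": name, "sources": sources}
        else:  # level4: spectrum exists, no library entry near its precursor
            truth.annotation_plan[fid] = {"level": 4}
    return spectra, library


def simulate(config: SimConfig):
    """Run all three generators; returns (manifest, pos, neg, spectra, library, truth)."""
    manifest, truth = generate_cohort(config)
    pos, neg, truth = generate_feature_tables(config, manifest, truth)
    spectra, library = generate_spectra(config, truth)
    return manifest, pos, neg, spectra, library, truth


def null_planted_matrix(
    rng: np.random.Generator,
    n_samples: int = 95,
    n_features: int = 1000,
    n_planted: int = 100,
    effect_log2fc: float = 2.0,
    n_group_a: int = 35,
    base_mu: float = 5.0,
    sigma: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimal two-group design for FDR calibration studies.

    Returns (linear abundance matrix features x samples, boolean group-A
    mask over samples, boolean planted mask over features).
    """
    groups = np.zeros(n_samples, dtype=bool)
    groups[:n_group_a] = True
    log_x = base_mu + rng.normal(0.0, sigma, size=(n_features, n_samples))
    planted = np.zeros(n_features, dtype=bool)
    planted[:n_planted] = True
    log_x[np.ix_(planted, groups)] += effect_log2fc * LOG2
    return np.power(10.0, log_x), groups, planted
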