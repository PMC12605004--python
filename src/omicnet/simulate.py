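"""Synthetic plasma multi-omic cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: three balanced study groups (ACPA– RA, ACPA+ RA, controls), a large
protein block and a smaller metabolite block, group mean-shifts planted at a
chosen Cohen's d on the latent log scale, latent-factor correlation among
features, optional covariate effects and group-conditional covariate
confounding, clinical inflammation markers coupled to the planted features,
and abundance-dependent (low-value) censoring of metabolites.

Abundances follow a lognormal model: everything is Gaussian on the log scale
and exported as exp(z), matching the multiplicative noise of both platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GROUPS, MED_FLAGS, OmicsMatrix, SampleMetadata

# Nominal covariate distributions (matched across groups unless confounding
# offsets are requested), patterned on a matched RA case-control cohort.
_COV_NOMINAL = {
    "sex_f_prob": 0.70,
    "age_mean": 58.0,
    "age_sd": 10.5,
    "bmi_mean": 29.5,
    "bmi_sd": 7.0,
    "smoking_current_prob": 0.06,
    "smoking_unknown_prob": 0.03,
    # medication prevalence among RA samples; controls are never medicated.
    # Co-prescription is the norm (combination therapy), modelled by a latent
    # "on treatment" state covering ~2/3 of RA patients (matching the reported
    # treatment-naive sub-cohort of 26/80), with specific drugs drawn inside
    # it so the marginal prevalences below are preserved.
    "treated": 0.675,
    "med_mtx": 0.51,
    "med_prednisone": 0.25,
    "med_bdmard": 0.21,
    "med_csdmard": 0.31,
}

_MARKERS = {
    # mean, sd, lower clip
    "esr": (13.0, 14.0, 0.0),
    "crp": (10.0, 15.0, 0.1),
    "das28crp": (3.5, 1.5, 0.5),
}

COVARIATE_KEYS = ("sex", "age", "bmi", "smoking_current", *MED_FLAGS)


def protein_id(i: int) -> str:
    """ID of the i-th synthetic protein (name|aptamer-barcode form)."""
    return f"PROT{i:04d}|SL{i + 1:05d}"


def metabolite_id(i: int) -> str:
    return f"MET{i:04d}"


@dataclass(frozen=True)
class PlantedEffect:
    """A group mean-shift planted on one feature, sized as Cohen's d."""

    feature_id: str
    groups: tuple[str, ...]
    target_d: float


def evenly_planted(
    n_effects: int,
    target_d: float,
    n_proteins: int,
    n_metabolites: int,
    groups: Sequence[str] = ("ACPA_NEG", "ACPA_POS"),
) -> tuple[PlantedEffect, ...]:
    """Plant ``n_effects`` shifts, alternating affected subgroup, split across
    the two omic blocks in proportion to their sizes."""
    n_prot_eff = min(n_proteins, round(n_effects * n_proteins / (n_proteins + n_metabolites)))
    ids = [protein_id(i) for i in range(n_prot_eff)]
    ids += [metabolite_id(i) for i in range(n_effects - n_prot_eff)]
    return tuple(
        PlantedEffect(fid, (groups[i % len(groups)],), target_d)
        for i, fid in enumerate(ids)
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the synthetic cohort.

    Defaults: 40 samples per group as in the study; feature dimensionality is
    scaled down ~25x (260 proteins + 40 metabolites, preserving the ~7:1
    protein:metabolite ratio) so that per-feature network inference stays
    desk-scale.
    """

    n_per_group: int = 40
    n_proteins: int = 260
    n_metabolites: int = 40
    planted: tuple[PlantedEffect, ...] = ()
    n_factors: int = 30
    loading_scale: float = 0.8
    # per-covariate SD of the per-feature coefficients (latent log scale);
    # age/sex/BMI are well-documented drivers of the plasma proteome and
    # metabolome, medication effects are smaller. Heterogeneous by design:
    # coefficients are drawn N(0, sd) per feature, so most features carry
    # little covariate signal and a minority carry a lot.
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.4, "bmi": 0.4, "sex": 0.4, "smoking_current": 0.3,
            "med_mtx": 0.2, "med_prednisone": 0.2, "med_bdmard": 0.2,
            "med_csdmard": 0.2,
        }
    )
    confounding: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    marker_coupling: float = 0.5
    missing_censor_frac: float = 0.10
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group, self.n_proteins, self.n_metabolites, self.n_factors) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.missing_censor_frac <= 0.5:
            raise ValueError("missing_censor_frac must be in [0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for eff in self.planted:
            if not np.isfinite(eff.target_d):
                raise ValueError(f"non-finite target_d for {eff.feature_id}")
            bad = set(eff.groups) - set(GROUPS)
            if bad:
                raise ValueError(f"unknown groups in planted effect: {sorted(bad)}")
        bad_cov = set(self.covariate_effects) - set(COVARIATE_KEYS)
        if bad_cov:
            raise ValueError(f"unknown covariate_effects keys: {sorted(bad_cov)}")

    @property
    def feature_ids(self) -> list[str]:
        return [protein_id(i) for i in range(self.n_proteins)] + [
            metabolite_id(i) for i in range(self.n_metabolites)
        ]


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    planted: tuple[PlantedEffect, ...]
    shifts: dict[str, float]  # feature -> latent-scale shift delta
    loadings: np.ndarray  # (p, n_factors)
    covariate_coefs: dict[str, np.ndarray]  # covariate -> (p,) coefficients
    feature_total_sd: np.ndarray  # (p,) latent sd used for d-calibration
    censored_mask: pd.DataFrame  # samples x metabolites, True where censored

    @property
    def planted_ids(self) -> list[str]:
        return [e.feature_id for e in self.planted]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [asdict(e) for e in self.planted],
            "shifts": self.shifts,
            "covariate_coefs": {k: v.tolist() for k, v in self.covariate_coefs.items()},
            "feature_total_sd": self.feature_total_sd.tolist(),
            "censored_cells": [
                [str(s), str(f)]
                for s, f in zip(*np.nonzero(self.censored_mask.to_numpy()))
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def calibrate_shift(target_d: float, total_sd: float) -> float:
    """Latent mean shift achieving a population Cohen's d of ``target_d``.

    Both groups share the same latent variance, so d = delta / total_sd and
    the required shift is simply their product.
    """
    if total_sd <= 0:
        raise ValueError(f"total_sd must be positive, got {total_sd}")
    if not np.isfinite(target_d):
        raise ValueError("target_d must be finite")
    return float(target_d) * float(total_sd)


def _covariate_indicator_variance(key: str) -> float:
    if key == "sex":
        p = _COV_NOMINAL["sex_f_prob"]
    elif key == "smoking_current":
        p = _COV_NOMINAL["smoking_current_prob"]
    else:  # med flags: cohort-wide prevalence is 2/3 of the RA prevalence
        p = 2 / 3 * _COV_NOMINAL[key]
    return p * (1 - p)


def _draw_metadata(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_per_group
    rows = []
    for g in GROUPS:
        conf = {c: offs.get(g, 0.0) for c, offs in cfg.confounding.items()}
        sex = np.where(rng.random(n) < _COV_NOMINAL["sex_f_prob"], "F", "M")
        age = np.clip(
            rng.normal(_COV_NOMINAL["age_mean"] + conf.get("age", 0.0),
                       _COV_NOMINAL["age_sd"], n), 30, 80,
        )
        bmi = np.clip(
            rng.normal(_COV_NOMINAL["bmi_mean"] + conf.get("bmi", 0.0),
                       _COV_NOMINAL["bmi_sd"], n), 17, 60,
        )
        u = rng.random(n)
        smoking = np.where(
            u < _COV_NOMINAL["smoking_current_prob"], "CURRENT",
            np.where(u < _COV_NOMINAL["smoking_current_prob"]
                     + _COV_NOMINAL["smoking_unknown_prob"], "UNKNOWN", "NEVER_FORMER"),
        )
        treated = rng.random(n) < _COV_NOMINAL["treated"]
        meds = {}
        for flag in MED_FLAGS:
            cond = min(_COV_NOMINAL[flag] / _COV_NOMINAL["treated"], 1.0)
            draw = treated & (rng.random(n) < cond)
            meds[flag] = draw if g != "CONTROL" else np.zeros(n, dtype=bool)
        for i in range(n):
            rows.append({
                "group": g, "sex": sex[i], "age": float(age[i]), "bmi": float(bmi[i]),
                "smoking": smoking[i], **{k: bool(v[i]) for k, v in meds.items()},
            })
    frame = pd.DataFrame(rows, index=[f"S{i + 1:03d}" for i in range(len(rows))])
    frame.index.name = "sample_id"
    return frame


def _standardized_covariates(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "sex": (frame["sex"] == "F").to_numpy(float) - _COV_NOMINAL["sex_f_prob"],
        "age": (frame["age"].to_numpy(float) - _COV_NOMINAL["age_mean"]) / _COV_NOMINAL["age_sd"],
        "bmi": (frame["bmi"].to_numpy(float) - _COV_NOMINAL["bmi_mean"]) / _COV_NOMINAL["bmi_sd"],
        "smoking_current": (frame["smoking"] == "CURRENT").to_numpy(float)
        - _COV_NOMINAL["smoking_current_prob"],
        # controls are never medicated, so the cohort-wide flag mean is 2/3
        # of the RA prevalence
        **{
            flag: frame[flag].to_numpy(float) - 2 / 3 * _COV_NOMINAL[flag]
            for flag in MED_FLAGS
        },
    }


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, SampleMetadata, GroundTruth]:
    """Simulate (protein block, metabolite block, metadata, ground truth).

    Latent log-abundance: z = baseline + loadings @ factors + planted group
    shift + covariate effects + Gaussian noise. Proteins are exported as
    exp(z) (RFU-like, complete); metabolites are exported per-feature
    median-scaled with the lowest ``missing_censor_frac`` of each feature's
    values censored to missing (MNAR). Clinical markers are generated for RA
    samples as linear combinations of the planted features' latent signal
    plus noise; controls have missing markers, as in routine care data.
    Identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    feature_ids = cfg.feature_ids
    id_to_col = {fid: j for j, fid in enumerate(feature_ids)}
    for eff in cfg.planted:
        if eff.feature_id not in id_to_col:
            raise ValueError(f"planted feature not generated: {eff.feature_id}")

    meta_frame = _draw_metadata(cfg, rng)
    n, p = len(meta_frame), len(feature_ids)
    group = meta_frame["group"].to_numpy()

    # latent structure: community-sparse loadings — each feature loads on a
    # single factor, giving pathway-like correlated blocks rather than one
    # global correlation soup
    loadings = np.zeros((p, cfg.n_factors))
    community = np.arange(p) % cfg.n_factors
    loadings[np.arange(p), community] = rng.normal(0.0, cfg.loading_scale, size=p)
    factors = rng.standard_normal((n, cfg.n_factors))
    covs = _standardized_covariates(meta_frame)
    cov_coefs = {
        key: rng.normal(0.0, sd, size=p) if sd > 0 else np.zeros(p)
        for key, sd in cfg.covariate_effects.items()
    }
    var = (loadings ** 2).sum(axis=1) + cfg.noise_sd ** 2
    for key, beta in cov_coefs.items():
        v = 1.0 if key in ("age", "bmi") else _covariate_indicator_variance(key)
        var = var + beta ** 2 * v
    total_sd = np.sqrt(var)

    baseline = np.concatenate([
        rng.normal(7.0, 1.0, cfg.n_proteins),  # log-RFU scale
        rng.normal(0.0, 1.0, cfg.n_metabolites),
    ])
    z = baseline[None, :] + factors @ loadings.T
    for key, beta in cov_coefs.items():
        z = z + np.outer(covs[key], beta)

    shifts: dict[str, float] = {}
    for eff in cfg.planted:
        j = id_to_col[eff.feature_id]
        delta = calibrate_shift(eff.target_d, total_sd[j])
        shifts[eff.feature_id] = delta
        affected = np.isin(group, eff.groups)
        z[affected, j] += delta

    z = z + rng.normal(0.0, cfg.noise_sd, size=(n, p))

    # clinical markers, coupled to the planted latent signal in RA samples
    is_ra = group != "CONTROL"
    if cfg.planted:
        cols = [id_to_col[e.feature_id] for e in cfg.planted]
        sig = ((z[:, cols] - z[:, cols].mean(0)) / z[:, cols].std(0)).mean(axis=1)
        sig = sig / max(sig.std(), 1e-12)
    else:
        sig = np.zeros(n)
    rho = float(np.clip(cfg.marker_coupling, -0.999, 0.999))
    for marker, (mu, sd, lo) in _MARKERS.items():
        noise = rng.standard_normal(n)
        vals = mu + sd * (rho * sig + np.sqrt(1 - rho ** 2) * noise)
        vals = np.clip(vals, lo, None)
        meta_frame[marker] = np.where(is_ra, vals, np.nan)

    meta = SampleMetadata(meta_frame)

    # protein block: exp(latent), complete
    prot_vals = pd.DataFrame(
        np.exp(z[:, : cfg.n_proteins]),
        index=meta_frame.index,
        columns=feature_ids[: cfg.n_proteins],
    )
    prot_info = pd.DataFrame(
        {
            "kind": "protein",
            "display_name": [f.split("|")[0] for f in prot_vals.columns],
            "platform_barcode": [f.split("|")[1] for f in prot_vals.columns],
        },
        index=pd.Index(prot_vals.columns, name="feature_id"),
    )
    prot = OmicsMatrix(prot_vals, prot_info)

    # metabolite block: censor the lowest values per feature, then median-scale
    met_raw = np.exp(z[:, cfg.n_proteins:])
    n_cens = int(round(cfg.missing_censor_frac * n))
    cens_mask = np.zeros_like(met_raw, dtype=bool)
    if n_cens > 0:
        order = np.argsort(met_raw, axis=0, kind="stable")
        cens_mask[order[:n_cens], np.arange(met_raw.shape[1])] = True
    met_vals = met_raw.copy()
    met_vals[cens_mask] = np.nan
    med = np.nanmedian(met_vals, axis=0)
    met_vals = met_vals / med
    met_frame = pd.DataFrame(
        met_vals, index=meta_frame.index, columns=feature_ids[cfg.n_proteins:]
    )
    met_info = pd.DataFrame(
        {"kind": "metabolite", "display_name": list(met_frame.columns),
         "platform_barcode": ""},
        index=pd.Index(met_frame.columns, name="feature_id"),
    )
    met = OmicsMatrix(met_frame, met_info)

    truth = GroundTruth(
        planted=cfg.planted,
        shifts=shifts,
        loadings=loadings,
        covariate_coefs=cov_coefs,
        feature_total_sd=total_sd,
        censored_mask=pd.DataFrame(
            cens_mask, index=met_frame.index, columns=met_frame.columns
        ),
    )
    return prot, met, meta, truth


def write_cohort(
    prot: OmicsMatrix,
    met: OmicsMatrix,
    meta: SampleMetadata,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the cohort in the same TSV formats the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    prot.to_tsv(paths["proteins"])
    met.to_tsv(paths["metabolites"])
    meta.to_tsv(paths["metadata"])
    truth.to_json(paths["ground_truth"])
    return paths
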