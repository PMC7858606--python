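"""Synthetic SWATH-MS study generator.

Emulates the statistical structure of a quantitative DIA proteomics
experiment on CLL patient samples: two IGHV clinical subgroups (3
unmutated + 3 mutated patients by default), three sample-preparation
days and three MS acquisitions per preparation — 54 acquisitions in the
default design — over thousands of proteins whose log2 abundances span
several orders of magnitude.

The generator injects, with full ground truth:

* a coefficient of variation that decays exponentially with log2 mean
  abundance (low-abundance proteins are noisier),
* additive prep-day batch offsets (a day-level shift plus per-protein
  jitter) and optional per-day multiplicative scale inflation of the
  measurement noise,
* small run-to-run noise,
* group fold-changes tied to IGHV status for a configurable fraction of
  proteins, a continuous %-IGHV covariate per patient straddling the 2%
  cutoff, and WBC / gender confounders,
* abundance-dependent (logistic) missingness on the raw scale.

Everything is reproducible bit-for-bit from a single master seed;
independent sub-streams per stage mean changing one parameter perturbs
only its own draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
    ighv_status_from_percent,
)
from .powermodel import cv_to_sigma_log2


class ConfigurationError(ValueError):
    """A synthetic-study configuration violates its invariants."""


@dataclass(frozen=True)
class CvCurveParams:
    """Exponential-decay CV-vs-abundance curve.

    CV(%) at log2 abundance ``x`` is
    ``cv_floor + cv_amplitude * exp(-cv_decay * (x - ref_log2))`` — the
    asymptotic floor is reached at high abundance, and the curve rises
    towards low abundance.  ``ref_log2`` anchors the amplitude: at
    ``x = ref_log2`` the CV is ``cv_floor + cv_amplitude``.
    """

    cv_floor: float = 5.0
    cv_amplitude: float = 60.0
    cv_decay: float = 0.5
    ref_log2: float = 8.0

    def validate(self) -> None:
        if self.cv_floor <= 0:
            raise ConfigurationError("cv_floor must be > 0")
        if self.cv_amplitude < 0 or self.cv_decay < 0:
            raise ConfigurationError("cv_amplitude and cv_decay must be >= 0")


def cv_at_abundance(params: CvCurveParams, mean_log2) -> np.ndarray | float:
    """Evaluate the injected CV (%) curve at a log2 mean abundance.

    Strictly decreasing in abundance when decay and amplitude are positive;
    never below ``cv_floor``.
    """
    params.validate()
    x = np.asarray(mean_log2, dtype=float)
    cv = params.cv_floor + params.cv_amplitude * np.exp(
        -params.cv_decay * (x - params.ref_log2)
    )
    return float(cv) if np.isscalar(mean_log2) else cv


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic SWATH-MS study.

    Defaults reproduce the study design: 3 patients per IGHV group, 3
    preparation days, 3 MS runs (54 acquisitions), abundances spanning
    several orders of magnitude, prep-day batch offsets of SD 0.5 log2,
    negligible run noise, 10% of proteins differentially expressed at a
    2-fold (1 log2 unit) IGHV effect, and mild abundance-dependent
    missingness capped at 5%.  ``prep_noise_sd`` is a per-preparation
    perturbation shared by the MS runs of one (patient, prep-day) block
    — the source of intra-block correlation among technical replicates.
    """

    n_patients_per_group: int = 3
    n_preps: int = 3
    n_runs: int = 3
    n_proteins: int = 5000
    log2_abundance_mean: float = 15.0
    log2_abundance_sd: float = 3.0
    cv_curve_params: CvCurveParams = field(default_factory=CvCurveParams)
    patient_sd: float = 0.3
    prep_noise_sd: float = 0.1
    prep_batch_sd_location: float = 0.5
    prep_batch_scale_range: tuple[float, float] = (1.0, 1.0)
    run_noise_sd: float = 0.05
    de_fraction: float = 0.10
    de_log2fc: float = 1.0
    missing_max_rate: float = 0.05
    missing_midpoint_log2: float | None = None
    missing_width_log2: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients_per_group", "n_preps", "n_runs", "n_proteins"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ConfigurationError("de_fraction must be in [0, 1)")
        if not 0.0 <= self.missing_max_rate < 1.0:
            raise ConfigurationError("missing_max_rate must be in [0, 1)")
        lo, hi = self.prep_batch_scale_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ConfigurationError("prep_batch_scale_range endpoints must be > 0, lo <= hi")
        if min(self.patient_sd, self.prep_noise_sd,
               self.prep_batch_sd_location, self.run_noise_sd) < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        self.cv_curve_params.validate()


@dataclass
class GroundTruth:
    """Latent parameters of a generated study, for downstream evaluation."""

    de_protein_ids: set
    true_log2fc: pd.Series            # per protein; UM minus M group difference
    batch_offsets: pd.DataFrame       # protein x prep day, log2 units
    batch_scales: pd.Series           # per prep day, noise-SD multiplier
    true_cv_curve: CvCurveParams
    ighv_percent: pd.Series           # per patient, %
    base_log2: pd.Series              # per protein latent mean abundance
    missing_midpoint_log2: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_protein_ids": sorted(self.de_protein_ids),
            "true_log2fc": self.true_log2fc.to_dict(),
            "batch_offsets": {
                str(day): self.batch_offsets[day].to_dict()
                for day in self.batch_offsets.columns
            },
            "batch_scales": {str(k): v for k, v in self.batch_scales.to_dict().items()},
            "true_cv_curve": asdict(self.true_cv_curve),
            "ighv_percent": self.ighv_percent.to_dict(),
            "base_log2": self.base_log2.to_dict(),
            "missing_midpoint_log2": self.missing_midpoint_log2,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        offsets = pd.DataFrame({int(k): pd.Series(v) for k, v in d["batch_offsets"].items()})
        return cls(
            de_protein_ids=set(d["de_protein_ids"]),
            true_log2fc=pd.Series(d["true_log2fc"]),
            batch_offsets=offsets,
            batch_scales=pd.Series({int(k): v for k, v in d["batch_scales"].items()}),
            true_cv_curve=CvCurveParams(**d["true_cv_curve"]),
            ighv_percent=pd.Series(d["ighv_percent"]),
            base_log2=pd.Series(d["base_log2"]),
            missing_midpoint_log2=d["missing_midpoint_log2"],
        )


def _patient_roster(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates per patient.

    M-CLL patients draw %-IGHV uniformly on (2.1, 15) and UM-CLL on
    (0, 1), straddling the 2% cutoff as in the observed cohort (range
    0-14%).  The first patient of each group is female, the last has a
    high WBC — fixed patterns that keep IGHV status, WBC class and gender
    mutually non-aliased in the joint model.
    """
    g = config.n_patients_per_group
    rows = []
    pct_m = rng.uniform(2.1, 15.0, size=g)
    pct_um = rng.uniform(0.0, 1.0, size=g)
    for group, pcts in (("M", pct_m), ("UM", pct_um)):
        for i in range(g):
            rows.append(
                {
                    "patient_id": f"P{len(rows) + 1}",
                    "group": group,
                    "ighv_percent": float(pcts[i]),
                    "gender": "F" if i == 0 else "M",
                    "wbc_class": "high" if i == g - 1 else "low",
                }
            )
    roster = pd.DataFrame(rows).set_index("patient_id")
    roster["ighv_status"] = [ighv_status_from_percent(p) for p in roster["ighv_percent"]]
    return roster


def generate_study(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Generate one synthetic study: raw matrix, metadata and ground truth.

    The log2 intensity of protein ``g`` in acquisition ``s`` (patient ``p``,
    prep day ``d``, run ``r``) is

    ``base_g + (fc_g / 2) * group_sign(p) + patient_{g,p} + batch_{g,d}
    + prep_{g,p,d} + scale_d * sigma_g * z + run-noise``

    where ``sigma_g`` is the log2 SD implied by the injected CV curve at
    ``base_g`` (log-normal identity), ``batch_{g,d}`` is a day-level shift
    plus per-protein jitter, and ``scale_d`` inflates the measurement noise
    multiplicatively.  Raw intensities are ``2**log2``; logistic dropout in
    abundance then masks values, capped at ``missing_max_rate``.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_ab, rng_fc, rng_pat, rng_batch, rng_noise, rng_drop, rng_ighv = (
        np.random.default_rng(s) for s in streams
    )

    G = config.n_proteins
    protein_ids = pd.Index([f"PROT{i + 1:05d}" for i in range(G)])

    roster = _patient_roster(config, rng_ighv)
    patients = roster.index.tolist()

    # acquisition layout: patient-major, then prep day, then run
    sample_rows = []
    for p in patients:
        for d in range(1, config.n_preps + 1):
            for r in range(1, config.n_runs + 1):
                sample_rows.append(
                    {
                        "acquisition_id": f"{p}_D{d}_R{r}",
                        "patient_id": p,
                        "prep_day": d,
                        "ms_run": r,
                        "ighv_status": roster.loc[p, "ighv_status"],
                        "ighv_percent": roster.loc[p, "ighv_percent"],
                        "wbc_class": roster.loc[p, "wbc_class"],
                        "gender": roster.loc[p, "gender"],
                    }
                )
    meta = pd.DataFrame(sample_rows).set_index("acquisition_id")
    S = len(meta)

    # latent per-protein abundance and noise scale
    base = rng_ab.normal(config.log2_abundance_mean, config.log2_abundance_sd, size=G)
    cv = cv_at_abundance(config.cv_curve_params, base)
    sigma = cv_to_sigma_log2(cv)

    # differential expression: fraction de_fraction, random sign, UM vs M
    n_de = int(round(config.de_fraction * G))
    de_idx = rng_fc.choice(G, size=n_de, replace=False)
    signs = rng_fc.choice([-1.0, 1.0], size=n_de)
    fc = np.zeros(G)
    fc[de_idx] = signs * config.de_log2fc
    group_sign = np.where(meta["ighv_status"].to_numpy() == "UM", 0.5, -0.5)

    # patient effects (protein x patient)
    pat_eff = rng_pat.normal(0.0, config.patient_sd, size=(G, len(patients)))
    pat_col = {p: j for j, p in enumerate(patients)}
    pat_idx = np.array([pat_col[p] for p in meta["patient_id"]])

    # prep-day batch structure
    day_shift = rng_batch.normal(0.0, config.prep_batch_sd_location, size=config.n_preps)
    jitter = rng_batch.normal(0.0, config.prep_batch_sd_location, size=(G, config.n_preps))
    lo, hi = config.prep_batch_scale_range
    scales = rng_batch.uniform(lo, hi, size=config.n_preps)
    day_idx = meta["prep_day"].to_numpy() - 1
    batch_offsets = day_shift[np.newaxis, :] + jitter  # (G, n_preps)

    # assemble log2 intensities
    log2_y = (
        base[:, np.newaxis]
        + fc[:, np.newaxis] * group_sign[np.newaxis, :]
        + pat_eff[:, pat_idx]
        + batch_offsets[:, day_idx]
    )
    # per-preparation noise: one draw per (protein, patient, day) block,
    # shared by that preparation's MS runs
    prep_noise = rng_noise.normal(
        0.0, config.prep_noise_sd, size=(G, len(patients), config.n_preps)
    )
    meas = rng_noise.normal(0.0, 1.0, size=(G, S)) * sigma[:, np.newaxis]
    meas *= scales[day_idx][np.newaxis, :]
    run_noise = rng_noise.normal(0.0, config.run_noise_sd, size=(G, S))
    log2_y = log2_y + prep_noise[:, pat_idx, day_idx] + meas + run_noise

    raw = np.power(2.0, log2_y)

    # abundance-dependent logistic dropout
    if config.missing_midpoint_log2 is None:
        midpoint = float(np.quantile(base, 0.10))
    else:
        midpoint = config.missing_midpoint_log2
    if config.missing_max_rate > 0:
        z = (base - midpoint) / config.missing_width_log2
        p_miss = config.missing_max_rate / (1.0 + np.exp(z))  # decreasing in abundance
        u = rng_drop.uniform(size=(G, S))
        miss = u < p_miss[:, np.newaxis]
        # guarantee >= 1 observed value per protein
        all_missing = miss.all(axis=1)
        if all_missing.any():
            keep = np.argmax(u[all_missing], axis=1)
            miss[np.flatnonzero(all_missing), keep] = False
        raw = raw.copy()
        raw[miss] = np.nan

    matrix = ExpressionMatrix(
        values=pd.DataFrame(raw, index=protein_ids, columns=meta.index),
        scale="raw",
    )
    metadata = SampleMetadata(meta)
    truth = GroundTruth(
        de_protein_ids=set(protein_ids[de_idx]),
        true_log2fc=pd.Series(fc, index=protein_ids),
        batch_offsets=pd.DataFrame(
            batch_offsets, index=protein_ids, columns=range(1, config.n_preps + 1)
        ),
        batch_scales=pd.Series(scales, index=range(1, config.n_preps + 1)),
        true_cv_curve=config.cv_curve_params,
        ighv_percent=roster["ighv_percent"].copy(),
        base_log2=pd.Series(base, index=protein_ids),
        missing_midpoint_log2=midpoint,
    )
    return matrix, metadata, truth
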