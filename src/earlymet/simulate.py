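"""Synthetic case-control expression cohorts.

Emulates the statistical structure of a nested case-control expression study
of early prostate-cancer metastasis after biochemical recurrence (BCR):

* a log2-scale expression matrix (features x samples) with additive per-batch
  offsets and planted case-vs-control differential expression;
* three outcome groups — NED (no evidence of disease), PSA (biochemical
  recurrence only) and MET (early clinical metastasis, the cases) — where NED
  and PSA expression is identical by construction, mirroring the near-absence
  of differential expression between those control groups in real cohorts;
* clinical covariates (Gleason score, pre-operative PSA, seminal vesicle
  invasion, margins, extra-capsular extension, nodal status, adjuvant/salvage
  therapy flags) correlated with case status;
* survival endpoints (metastasis, prostate-cancer-specific mortality, overall
  survival) in years from BCR, with case hazards scaled by each case's planted
  expression burden so that more aberrant tumours progress faster;
* technical-replicate profiles of a cell-line control (one per batch) used to
  flag features whose measurement is dominated by technical variance.

Ground truth needed by recovery tests (informative-feature flags, per-feature
technical noise scale) is carried in the feature annotation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = ["SimulationConfig", "generate_cohort", "generate_technical_replicates"]

#: P(Gleason category | class); categories are scores 6,7,8,9,10 with <=6
#: collapsed onto 6. Cases skew high-grade, controls low — the qualitative
#: pattern of real case-control registries.
_GLEASON_LEVELS = np.array([6, 7, 8, 9, 10])
_GLEASON_P_CASE = np.array([0.03, 0.36, 0.14, 0.43, 0.04])
_GLEASON_P_CTRL = np.array([0.16, 0.57, 0.12, 0.145, 0.005])

# marginal covariate rates, case vs control
_BINARY_RATES = {
    "svi": (0.50, 0.28),
    "sm_pos": (0.52, 0.46),
    "ece": (0.60, 0.43),
    "node_pos": (0.22, 0.08),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults give a desk-scale cohort: 5,000 features, 300 samples (110 cases,
    95 + 95 controls), 30 informative features, 19 batches, and a roughly
    two-thirds training split.
    """

    n_features: int = 5000
    n_informative: int = 30
    n_cases: int = 110
    n_ned: int = 95
    n_psa: int = 95
    n_batches: int = 19
    batch_sd: float = 0.3
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_tech_reps: int = 19
    tech_base_sd: float = 0.15
    tech_unreliable_frac: float = 0.02
    tech_inflation: float = 10.0
    frac_low_probe: float = 0.05
    frac_crosshyb: float = 0.03
    frac_missing_ppsa: float = 0.03
    train_frac: float = 359 / 545
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_features": self.n_features,
            "n_informative": self.n_informative,
            "n_cases": self.n_cases,
            "n_ned": self.n_ned,
            "n_psa": self.n_psa,
            "n_batches": self.n_batches,
            "n_tech_reps": self.n_tech_reps,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_informative > self.n_features:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds n_features ({self.n_features})"
            )
        for name in (
            "tech_unreliable_frac",
            "frac_low_probe",
            "frac_crosshyb",
            "frac_missing_ppsa",
            "train_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.batch_sd < 0 or self.effect_size < 0:
            raise ValueError("batch_sd and effect_size must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_ned + self.n_psa

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _feature_annotation(config: SimulationConfig) -> pd.DataFrame:
    rng = substream(config.seed, "features")
    p = config.n_features
    feature_ids = [f"F{i:06d}" for i in range(p)]
    probe_count = np.full(p, 4, dtype=int)
    extra = rng.integers(0, 5, size=p)  # 4..8 probes typical
    probe_count += extra
    low = rng.random(p) < config.frac_low_probe
    probe_count[low] = rng.integers(1, 4, size=int(low.sum()))
    crosshyb = rng.random(p) < config.frac_crosshyb
    informative = np.zeros(p, dtype=bool)
    # plant signal only on reliable features so filtering cannot discard it
    eligible = np.flatnonzero(~low & ~crosshyb)
    if config.n_informative > len(eligible):
        raise ValueError("not enough reliable features to plant the requested signal")
    informative[rng.choice(eligible, size=config.n_informative, replace=False)] = True
    direction = np.where(rng.random(p) < 0.5, 1.0, -1.0)
    tech_sd = np.full(p, config.tech_base_sd)
    unreliable = rng.random(p) < config.tech_unreliable_frac
    tech_sd[unreliable] *= config.tech_inflation
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "probe_count": probe_count,
            "crosshyb": crosshyb,
            "tech_variance": np.nan,  # filled by preprocessing
            "is_informative": informative,
            "effect_direction": direction,
            "tech_noise_sd": tech_sd,
        }
    ).set_index("feature_id")


def _clinical_annotation(
    config: SimulationConfig, burden: np.ndarray, groups: np.ndarray
) -> pd.DataFrame:
    rng = substream(config.seed, "clinical")
    n = config.n_samples
    is_case = groups == "MET"
    sample_ids = [f"S{i:04d}" for i in range(n)]

    gleason = np.empty(n, dtype=int)
    gleason[is_case] = rng.choice(_GLEASON_LEVELS, size=is_case.sum(), p=_GLEASON_P_CASE)
    gleason[~is_case] = rng.choice(_GLEASON_LEVELS, size=(~is_case).sum(), p=_GLEASON_P_CTRL)

    ppsa = 2.0 ** rng.normal(3.2, 1.2, size=n)  # median ~9 ng/mL, log-scale spread
    ppsa[rng.random(n) < config.frac_missing_ppsa] = np.nan

    cols: dict[str, np.ndarray] = {}
    for name, (p_case, p_ctrl) in _BINARY_RATES.items():
        p_vec = np.where(is_case, p_case, p_ctrl)
        cols[name] = rng.random(n) < p_vec

    adj_radiation = rng.random(n) < 0.10
    adj_adt = rng.random(n) < 0.20
    # salvage therapy presupposes a PSA rise: impossible in the NED group
    eligible = groups != "NED"
    salv_radiation = (rng.random(n) < 0.25) & eligible
    salv_adt = (rng.random(n) < 0.45) & eligible

    # survival (years from BCR); case hazards scale with planted burden
    censor = rng.uniform(5.0, 20.0, size=n)
    rel_burden = np.ones(n)
    if is_case.any():
        b = burden[is_case]
        spread = b.std()
        rel_burden[is_case] = np.exp((b - b.mean()) / (spread if spread > 0 else 1.0))
    mean_t_met = np.where(is_case, 3.0, 60.0) / rel_burden
    t_met_lat = rng.exponential(mean_t_met)
    e_met = t_met_lat < censor
    t_met = np.minimum(t_met_lat, censor)

    mean_gap = np.where(is_case, 4.0, 6.0) / rel_burden
    t_pcsm_lat = t_met_lat + rng.exponential(mean_gap)
    e_pcsm = e_met & (t_pcsm_lat < censor)
    t_pcsm = np.minimum(t_pcsm_lat, censor)

    t_other = rng.exponential(25.0, size=n)
    t_os_lat = np.minimum(np.where(e_pcsm, t_pcsm_lat, np.inf), t_other)
    e_os = t_os_lat < censor
    t_os = np.minimum(t_os_lat, censor)

    annot = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "is_case": is_case,
            "batch": np.zeros(n, dtype=int),  # filled below
            "split": "",
            "gleason": gleason,
            "ppsa": ppsa,
            **cols,
            "adj_radiation": adj_radiation,
            "adj_adt": adj_adt,
            "salv_radiation": salv_radiation,
            "salv_adt": salv_adt,
            "t_met": t_met,
            "e_met": e_met,
            "t_pcsm": t_pcsm,
            "e_pcsm": e_pcsm,
            "t_os": t_os,
            "e_os": e_os,
        }
    ).set_index("sample_id")

    rng2 = substream(config.seed, "assignment")
    annot["batch"] = rng2.integers(1, config.n_batches + 1, size=n)
    # stratified train/validation split
    split = np.array(["validation"] * n, dtype=object)
    for mask in (is_case, ~is_case):
        idx = np.flatnonzero(mask)
        n_train = int(round(config.train_frac * len(idx)))
        split[rng2.choice(idx, size=n_train, replace=False)] = "train"
    annot["split"] = split
    return annot


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (expression, feature annotation, cohort annotation).

    Expression is a features x samples DataFrame of log2 intensities. Cases
    (group MET) have informative features shifted by ``effect_size`` (signed
    per feature, scaled by a per-case severity factor); NED and PSA samples
    draw from the same distribution. Each (batch, feature) pair adds its own
    Gaussian offset of scale ``batch_sd``. Pure function of ``config``.
    """
    feats = _feature_annotation(config)
    p, n = config.n_features, config.n_samples
    groups = np.array(
        ["MET"] * config.n_cases + ["PSA"] * config.n_psa + ["NED"] * config.n_ned,
        dtype=object,
    )

    rng = substream(config.seed, "expression")
    baseline = rng.normal(7.0, 1.5, size=p)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(p, n))

    # per-case severity scales the planted shift; re-used to drive survival
    is_case = groups == "MET"
    severity = np.clip(rng.normal(1.0, 0.25, size=n), 0.05, None)
    inf_mask = feats["is_informative"].to_numpy()
    direction = feats["effect_direction"].to_numpy()
    if inf_mask.any() and is_case.any():
        shift = (
            config.effect_size
            * direction[inf_mask, None]
            * severity[None, is_case]
        )
        values[np.ix_(inf_mask, is_case)] += shift
    burden = np.where(is_case, severity, 0.0) * config.effect_size

    annot = _clinical_annotation(config, burden, groups)

    # additive per-(batch, feature) offsets
    rng_b = substream(config.seed, "batch")
    offsets = rng_b.normal(0.0, config.batch_sd, size=(p, config.n_batches))
    batch_idx = annot["batch"].to_numpy() - 1
    values += offsets[:, batch_idx]

    expr = pd.DataFrame(values, index=feats.index, columns=annot.index)
    return expr, feats, annot


def generate_technical_replicates(
    config: SimulationConfig, features: pd.DataFrame
) -> pd.DataFrame:
    """Technical-replicate expression profiles of a cell-line control.

    One replicate per batch (``n_tech_reps`` columns): a fixed ground-truth
    profile plus per-feature technical noise whose scale is taken from the
    ``tech_noise_sd`` annotation column. Features flagged unreliable at
    generation carry inflated noise and should land in the top variance
    decile with high probability.
    """
    if config.n_tech_reps < 2:
        raise ValueError("n_tech_reps must be >= 2: variance across replicates is undefined")
    rng = substream(config.seed, "techreps")
    p = len(features)
    profile = rng.normal(7.0, 1.5, size=p)
    sd = features["tech_noise_sd"].to_numpy(dtype=float)
    values = profile[:, None] + rng.normal(size=(p, config.n_tech_reps)) * sd[:, None]
    cols = [f"PC3_rep{j:02d}" for j in range(config.n_tech_reps)]
    return pd.DataFrame(values, index=features.index, columns=cols)
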