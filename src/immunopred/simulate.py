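"""Synthetic cohorts and immunome matrices with a planted response link.

Individual-level trial data of this kind are available only on request, so
every downstream stage of the pipeline is exercised on simulated inputs
whose *statistical structure* matches what the analysis assumes:

* a patient cohort with realistic marginals (stage, histology, PD-L1 TPS
  group, EGFR/ALK status), the no-surgery / incomplete-resection branches
  that determine MPR evaluability, a viable-tumor-percent mixture with an
  atom at 0 (pCR) and mass at or below 10 (MPR), and exponential survival
  with rates depending on MPR status;
* per-tube compositional immunomes built from a latent cell-population
  mixture: each population carries a fixed +/- signature per tube, patient
  weights are population base proportions perturbed by multiplicative
  log-normal noise and renormalized, and a combination's abundance is 100
  times the summed weight of matching populations — so the exhaustive
  signature partition of a tube sums to exactly 100 per sample;
* planted effects applied as a multiplicative tilt of a designated
  population's weight in MPR patients, renormalized exactly (closure is
  preserved because shifting one population necessarily shifts its
  complement) and calibrated so the realized mean shift of the feature's
  log abundance equals the requested effect size times its null log-scale
  SD — ``d`` is an honest Cohen's d on the multiplicative scale;
* optional zero inflation via a per-feature limit of detection: values
  below the feature's detection limit (the quantile matching its target
  detection probability) read as 0, without renormalization, mimicking
  assay dropout — closure holds before the mask only;
* per-patient variant counts and coverage footprints for TMB.

All randomness flows from one integer seed through ``numpy`` SeedSequence
spawning, so each generator can be re-run independently and reproducibly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import AbundanceMatrix
from .panel import PanelDefinition

__all__ = [
    "CohortProfile",
    "EffectSpec",
    "generate_cohort",
    "generate_immunome",
    "generate_mutation_data",
    "module_rng",
]

STAGES = ("IB", "IIA", "IIB", "IIIA", "IIIB")
TPS_GROUPS = ("<1%", "1-49%", ">=50%", "unknown")


def module_rng(seed: int, label: str) -> np.random.Generator:
    """A generator split off the global seed by a stable per-module label."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class CohortProfile:
    """Marginal distributions the cohort generator draws from.

    Defaults mirror the enrolled-population marginals of the trial this
    package models: 181 patients, stage weights 18/16/55/70/22 over
    IB-IIIB, 38% squamous, PD-L1 TPS group weights 69/28/49/35, ~9%
    EGFR/ALK-altered, 12% no surgery, ~4% incomplete resection among
    resected, pCR mass 0.056 and total MPR mass 0.203 on the
    viable-percent mixture.  Survival and censoring rates are invented
    (per-month exponential) but chosen so 3-year survival lands near the
    reported 72% DFS / 80% OS.
    """

    n_patients: int = 181
    stage_weights: dict = field(
        default_factory=lambda: {
            "IB": 18 / 181, "IIA": 16 / 181, "IIB": 55 / 181,
            "IIIA": 70 / 181, "IIIB": 22 / 181,
        }
    )
    squamous_fraction: float = 69 / 181
    tps_group_weights: dict = field(
        default_factory=lambda: {
            "<1%": 69 / 181, "1-49%": 28 / 181, ">=50%": 49 / 181,
            "unknown": 35 / 181,
        }
    )
    egfr_alk_fraction: float = 17 / 181
    no_surgery_fraction: float = 22 / 181
    incomplete_resection_fraction: float = 6 / 143
    pcr_mass: float = 0.056          # atom at viable = 0
    mpr_mass: float = 0.203          # total mass at viable <= 10 (incl. pCR)
    viable_beta_a: float = 2.0       # shape of the non-MPR tail on (10, 100]
    viable_beta_b: float = 1.2
    # per-month exponential event rates by MPR status, plus censoring
    dfs_rate_mpr: float = 0.0029
    dfs_rate_non_mpr: float = 0.0107
    os_rate_mpr: float = 0.0014
    os_rate_non_mpr: float = 0.0073
    censor_rate: float = 0.010

    def validate(self) -> None:
        for name in (
            "squamous_fraction", "egfr_alk_fraction", "no_surgery_fraction",
            "incomplete_resection_fraction", "pcr_mass", "mpr_mass",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0 <= v <= 1:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        for name in ("stage_weights", "tps_group_weights"):
            w = getattr(self, name)
            vals = np.asarray(list(w.values()), dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(f"{name} has non-finite or negative entries")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {vals.sum():.12f})")
        if self.pcr_mass > self.mpr_mass:
            raise ValueError("pcr_mass cannot exceed mpr_mass")
        for name in (
            "dfs_rate_mpr", "dfs_rate_non_mpr", "os_rate_mpr",
            "os_rate_non_mpr", "censor_rate", "viable_beta_a", "viable_beta_b",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")


@dataclass
class EffectSpec:
    """Planted associations between combination features and MPR.

    ``effects`` maps a feature id to a signed effect size on the Cohen's d
    scale: in MPR patients the feature's generating population is tilted
    (with exact compositional renormalization) so that the feature's mean
    log abundance shifts by ``d`` of its null log-scale standard
    deviations (positive d: higher abundance in responders).  ``base_detection`` pins a feature's marginal
    detection probability (its limit-of-detection quantile), e.g. to force
    a causal feature into the non-prevalent stratum.  ``detection_shift``
    additionally moves the detection probability by outcome, linking zero
    inflation itself to response beyond what the abundance shift induces.
    ``post_effects`` adds a further shift to the post-treatment draw of MPR
    patients (positive: expansion; negative: contraction).
    """

    effects: dict[str, float] = field(default_factory=dict)
    detection_shift: dict[str, float] = field(default_factory=dict)
    post_effects: dict[str, float] = field(default_factory=dict)
    base_detection: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for d in (self.effects, self.detection_shift, self.post_effects):
            for fid, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite effect for feature {fid!r}")
        for fid, v in self.base_detection.items():
            if not np.isfinite(v) or not 0 <= v <= 1:
                raise ValueError(
                    f"base_detection for {fid!r} must be a probability, got {v}"
                )

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls()


def _categorical(rng, n, weights: dict):
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=n, p=p)]


def generate_cohort(profile: CohortProfile, seed: int) -> pd.DataFrame:
    """Draw a per-patient clinical table from the profile's marginals.

    Returns a DataFrame with one row per patient: stage, histology, PD-L1
    TPS group, EGFR/ALK flag, surgery flag, resection status (R0, R1/R2 or
    none), viable tumor percent (missing iff no surgery), and DFS/OS times
    (months) with event flags.
    """
    profile.validate()
    rng = module_rng(seed, "cohort")
    n = profile.n_patients

    stage = _categorical(rng, n, profile.stage_weights)
    histology = np.where(
        rng.random(n) < profile.squamous_fraction, "squamous", "non-squamous"
    )
    tps = _categorical(rng, n, profile.tps_group_weights)
    egfr_alk = rng.random(n) < profile.egfr_alk_fraction
    surgery = rng.random(n) >= profile.no_surgery_fraction
    incomplete = rng.random(n) < profile.incomplete_resection_fraction
    resection = np.where(~surgery, "none", np.where(incomplete, "R1/R2", "R0"))

    # viable-percent mixture: atom at 0, mass on (0, 10], beta tail on (10, 100]
    u = rng.random(n)
    viable = np.empty(n)
    pcr = u < profile.pcr_mass
    mpr_tail = (~pcr) & (u < profile.mpr_mass)
    rest = ~pcr & ~mpr_tail
    viable[pcr] = 0.0
    viable[mpr_tail] = rng.uniform(0.0, 10.0, mpr_tail.sum())
    viable[rest] = 10.0 + 90.0 * rng.beta(
        profile.viable_beta_a, profile.viable_beta_b, rest.sum()
    )
    viable = np.where(surgery, viable, np.nan)

    is_mpr = surgery & (resection == "R0") & (viable <= 10.0)

    def _survival(rate_mpr, rate_other):
        rate = np.where(is_mpr, rate_mpr, rate_other)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.exponential(1.0 / profile.censor_rate, n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return np.maximum(time, 1e-6), event

    dfs_time, dfs_event = _survival(profile.dfs_rate_mpr, profile.dfs_rate_non_mpr)
    os_time, os_event = _survival(profile.os_rate_mpr, profile.os_rate_non_mpr)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "stage": stage,
            "histology": histology,
            "tps_group": tps,
            "egfr_alk_positive": egfr_alk.astype(int),
            "surgery": surgery.astype(int),
            "resection": resection,
            "viable_percent": viable,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "os_time": os_time,
            "os_event": os_event,
        }
    ).set_index("patient_id", drop=False)


def mpr_evaluable(cohort: pd.DataFrame) -> pd.Series:
    """Patients evaluable for MPR: had surgery and no EGFR/ALK alteration."""
    return (cohort["surgery"] == 1) & (cohort["egfr_alk_positive"] == 0)


def mpr_flag(cohort: pd.DataFrame, threshold: float = 10.0) -> pd.Series:
    """Binary MPR status: viable <= threshold with complete (R0) resection."""
    return (
        (cohort["surgery"] == 1)
        & (cohort["resection"] == "R0")
        & (cohort["viable_percent"] <= threshold)
    ).astype(int)


@dataclass
class _TubeModel:
    tube_id: str
    feature_ids: list[str]          # realized signatures, one per population group
    base_log_w: np.ndarray          # (n_features,) fixed log base proportions


def _build_tube_models(panel, n_populations, rng) -> list[_TubeModel]:
    models = []
    for tube in panel.tubes:
        k = len(tube.markers)
        seen: dict[tuple, int] = {}
        # draw population signatures; '+' prevalence ~ 35% per marker
        while len(seen) < min(n_populations, 2 ** k):
            signs = tuple("+" if rng.random() < 0.35 else "-" for _ in range(k))
            if signs not in seen:
                seen[signs] = len(seen)
        fids = []
        for signs in seen:
            combo = tube.combination(dict(zip(tube.markers, signs)))
            fids.append(combo.feature_id)
        base = rng.dirichlet(np.ones(len(fids)) * 2.0)
        models.append(
            _TubeModel(tube_id=tube.tube_id, feature_ids=fids,
                       base_log_w=np.log(base))
        )
    return models


def generate_immunome(
    cohort: pd.DataFrame,
    panel: PanelDefinition,
    effects: EffectSpec,
    seed: int,
    n_populations: int = 40,
    noise_sigma: float = 0.6,
    zero_inflated_fraction: float = 0.5,
    detection_prob_range: tuple[float, float] = (0.30, 0.95),
    post_noise_sigma: float = 0.25,
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Pre- and post-treatment abundance matrices for every cohort patient.

    Parameters
    ----------
    n_populations
        Latent cell populations drawn per tube; each realizes one distinct
        signature, so the observed feature space has roughly
        ``n_tubes * n_populations`` columns (capped at 2^k per tube).
    noise_sigma
        Log-scale SD of the multiplicative patient-level noise; planted
        effect sizes are expressed in units of this SD.
    zero_inflated_fraction
        Fraction of features given a detection probability below 1, drawn
        uniformly from ``detection_prob_range``, so the prevalence spectrum
        straddles the 85% threshold.
    post_noise_sigma
        Log-scale SD of the additional pre-to-post within-patient noise.

    Returns the (pre, post) pair.  Closure (per-tube abundance sum of 100)
    holds exactly before the zero-inflation mask; the mask sets masked
    entries to 0 without renormalizing, mirroring assay dropout.
    """
    effects.validate()
    rng_struct = module_rng(seed, "immunome-structure")
    rng_noise = module_rng(seed, "immunome-noise")
    rng_mask = module_rng(seed, "immunome-mask")

    models = _build_tube_models(panel, n_populations, rng_struct)
    all_fids = [fid for m in models for fid in m.feature_ids]
    fid_set = set(all_fids)
    for fid in {**effects.effects, **effects.detection_shift,
                **effects.post_effects}:
        if fid not in fid_set:
            raise ValueError(
                f"effect targets feature {fid!r} not realized in the panel's "
                "population model"
            )
        from .panel import parse_feature_id
        if panel.is_excluded(parse_feature_id(fid)):
            raise ValueError(f"effect targets excluded combination {fid!r}")

    patients = cohort["patient_id"].tolist()
    n = len(patients)
    y = mpr_flag(cohort).to_numpy()

    def _tilt(w: np.ndarray, j: int, d: float, affected: np.ndarray) -> None:
        """Shift feature j by d pooled SDs for affected patients, in place.

        The shift is a multiplicative tilt of population j's weight with
        exact renormalization of the tube composition (closure preserved).
        The tilt factor is solved so the realized mean shift of the
        feature's *log* abundance equals ``d`` times its null log-scale SD:
        percent abundances are lognormal-like, and a standardized shift on
        the multiplicative scale separates distributions consistently
        regardless of skew — the Cohen's d contract of EffectSpec.
        """
        lx0 = np.log(100.0 * w[:, j])
        sd0 = lx0.std(ddof=1)
        if sd0 == 0 or not affected.any():
            return
        target = lx0[affected].mean() + d * sd0
        target = min(target, math.log(100.0 - 1e-9))
        wj = w[affected, j]

        def realized_mean(log_t: float) -> float:
            t = math.exp(log_t)
            return float(np.mean(np.log(100.0 * wj * t / (1.0 + wj * (t - 1.0)))))

        lo, hi = -30.0, 30.0
        for _ in range(80):   # bisection; realized_mean is monotone in log_t
            mid = 0.5 * (lo + hi)
            if realized_mean(mid) < target:
                lo = mid
            else:
                hi = mid
        t = math.exp(0.5 * (lo + hi))
        denom = 1.0 + w[affected, j] * (t - 1.0)
        w[affected] = w[affected] / denom[:, None]
        w[affected, j] *= t

    def _compose(shift_extra: dict[str, float], eps_by_tube):
        affected = y.astype(bool)
        cols = {}
        for m, eps in zip(models, eps_by_tube):
            logw = m.base_log_w[None, :] + noise_sigma * eps
            w = np.exp(logw)
            w /= w.sum(axis=1, keepdims=True)
            for j, fid in enumerate(m.feature_ids):
                d = effects.effects.get(fid, 0.0) + shift_extra.get(fid, 0.0)
                if d:
                    _tilt(w, j, d, affected)
            for j, fid in enumerate(m.feature_ids):
                cols[fid] = 100.0 * w[:, j]
        return pd.DataFrame(cols, index=pd.Index(patients, name="patient_id"))

    eps_pre = [rng_noise.standard_normal((n, len(m.feature_ids))) for m in models]
    eps_post = [
        e + post_noise_sigma / noise_sigma
        * rng_noise.standard_normal(e.shape)
        for e in eps_pre
    ]

    pre = _compose({}, eps_pre)
    post = _compose(effects.post_effects, eps_post)

    # Zero inflation as a limit of detection: a zero-inflated feature has a
    # detection-limit threshold placed at the (1 - p) quantile of its
    # pre-treatment marginal distribution, and values below the limit read
    # as 0 (no renormalization).  Thresholding, unlike an independent
    # Bernoulli mask, couples dropout to abundance — a feature whose
    # abundance is shifted by outcome therefore also has outcome-linked
    # detection, which is what makes detection-based screening of
    # non-prevalent features meaningful downstream.
    det_p = np.ones(len(all_fids))
    inflated = rng_mask.random(len(all_fids)) < zero_inflated_fraction
    lo, hi = detection_prob_range
    det_p[inflated] = rng_mask.uniform(lo, hi, inflated.sum())
    for j, fid in enumerate(all_fids):
        if fid in effects.base_detection:
            det_p[j] = effects.base_detection[fid]
    pre_vals = pre.to_numpy()
    for j, fid in enumerate(all_fids):
        shift = effects.detection_shift.get(fid, 0.0)
        if det_p[j] >= 1.0 and shift == 0.0:
            continue
        # per-outcome detection probability -> per-outcome detection limit,
        # both quantiles of the same pre-treatment marginal
        p_by_y = np.clip(det_p[j] + shift * y, 0.0, 1.0)
        limits = np.quantile(pre_vals[:, j], 1.0 - p_by_y)
        for frame in (pre, post):
            x = frame[fid].to_numpy()
            frame[fid] = np.where(x >= limits, x, 0.0)

    return (
        AbundanceMatrix(data=pre, timepoint="pre"),
        AbundanceMatrix(data=post, timepoint="post"),
    )


def generate_immunome_unmasked(
    cohort, panel, effects, seed, **kwargs
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """As :func:`generate_immunome` but with no zero-inflation mask.

    Useful when the exact per-tube closure invariant must hold on the
    returned matrices themselves.
    """
    kwargs = dict(kwargs, zero_inflated_fraction=0.0)
    return generate_immunome(cohort, panel, effects, seed, **kwargs)


def generate_mutation_data(
    cohort: pd.DataFrame,
    seed: int,
    group_weights: tuple[float, float, float] = (60 / 85, 10 / 85, 15 / 85),
    rate_bins: tuple[tuple[float, float], ...] = ((0.5, 9.5), (10.0, 15.9), (16.0, 40.0)),
    mean_footprint_mb: float = 30.0,
    footprint_sd_mb: float = 2.0,
    rates: np.ndarray | float | None = None,
) -> pd.DataFrame:
    """Per-patient variant counts and coverage footprints for TMB.

    Each patient is assigned a latent mutation rate (mutations per Mb),
    drawn by first picking a TMB stratum (<10 / 10-15 / >=16 mut/Mb, with
    weights mirroring the 60:10:15 split of the modeled trial's exome
    cohort) and then a uniform rate within that stratum's range — unless
    ``rates`` pins the rate(s) directly.  Protein-affecting counts are
    Poisson with mean rate x footprint, so downstream TMB recovers the
    planted rate in expectation.  The footprint is the number of coding
    bases with at least 7x unique coverage.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rng = module_rng(seed, "mutations")
    n = len(cohort)

    if rates is None:
        w = np.asarray(group_weights, dtype=float)
        w = w / w.sum()
        grp = rng.choice(len(rate_bins), size=n, p=w)
        lam = np.array([rng.uniform(*rate_bins[g]) for g in grp])
    else:
        lam = np.broadcast_to(np.asarray(rates, dtype=float), (n,)).copy()
        if np.any(lam < 0) or not np.all(np.isfinite(lam)):
            raise ValueError("rates must be finite and nonnegative")

    footprint = np.maximum(
        rng.normal(mean_footprint_mb, footprint_sd_mb, n), 1.0
    ) * 1e6
    protein = rng.poisson(lam * footprint / 1e6)
    silent = rng.poisson(0.5 * lam * footprint / 1e6)

    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "protein_affecting_mutations": protein,
            "other_mutations": silent,
            "covered_coding_bases": footprint.round().astype(np.int64),
        }
    ).set_index("patient_id", drop=False)
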