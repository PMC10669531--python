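"""Synthetic survey cohorts with planted factor–depression dependence.

The study's raw data are not deposited, so this module generates cohorts with
the study's structure: the documented demographic marginals, six predictor
scales with calibrated internal consistency, and a logistic outcome model that
plants known dependence between risk-factor combinations and depression.

Generation proceeds in fixed stages, each on its own deterministic sub-stream
of the single integer seed (adding a stage never perturbs earlier draws):

1. demographics drawn independently from the marginals;
2. per-participant latent scale levels from a cross-scale Gaussian copula;
3. item responses by thresholding compound-symmetric latent item variables
   into each scale's discrete range (equiprobable categories);
4. provisional risk indicators from the quartile/flag criteria on this
   synthetic cohort itself;
5. depression status from the logistic outcome model on those indicators;
6. a DSRSC total consistent with status (truncated discretized normal above
   or below the screening threshold) decomposed into 18 item scores;
7. optional completely-at-random row-level missingness.

Calibration: the per-scale inter-item correlation targets come from inverting
the Spearman–Brown-type identity ``alpha = k*rho / (1 + (k-1)*rho)``, i.e.
``rho = alpha / (k - (k-1)*alpha)``.  Discretizing latent normals attenuates
correlations, so the generator divides each latent correlation by the squared
latent-to-score correlation of an equiprobable c-category discretization
before drawing items; simulated Cronbach's alpha then lands on the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from famschool.discretization import (
    _RISK_FLAGS,
    _RISK_QUARTILE,
    nearest_rank,
)
from famschool.survey_model import (
    Codebook,
    ParticipantRecord,
    default_codebook,
)

__all__ = [
    "DemographicMarginals",
    "OutcomeModel",
    "GeneratorConfig",
    "RuleMetricsEstimate",
    "ALPHA_TARGETS",
    "default_config",
    "inter_item_corr_for_alpha",
    "discretization_attenuation",
    "generate_participants",
    "planted_rule_oracle",
]

#: Cronbach's alpha calibration targets per scale (financial_strain is the
#: package's own choice; the others are the study's reported reliabilities).
ALPHA_TARGETS = {
    "cohesion": 0.82,
    "conflict": 0.63,
    "financial_strain": 0.75,
    "teacher_support": 0.80,
    "peer_support": 0.81,
    "autonomy_support": 0.76,
    "dsrsc": 0.84,
}

_SCALE_ORDER = (
    "cohesion",
    "conflict",
    "financial_strain",
    "teacher_support",
    "peer_support",
    "autonomy_support",
)

# named sub-streams of the master seed, one per generation stage
_STAGES = {
    "demographics": 0,
    "latent": 1,
    "items": 2,
    "outcome": 3,
    "dsrsc": 4,
    "missingness": 5,
    "oracle": 6,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGES[stage])))


@dataclass(frozen=True)
class DemographicMarginals:
    """Marginal distributions of the demographic and school-resource variables."""

    p_female: float = 0.528                      # 1292 / 2445
    p_middle_school: float = 1281 / 2445
    grade_dist_primary: tuple[float, ...] = (590 / 1164, 574 / 1164)   # grades 5, 6
    grade_dist_middle: tuple[float, ...] = (414 / 1281, 418 / 1281, 449 / 1281)
    p_left_behind: float = 0.356                 # 870 / 2445
    p_intact_family: float = 0.85
    p_parental_education_low: float = 0.40
    ranking_dist: tuple[float, float, float] = (0.25, 0.55, 0.20)  # top10/average/last10
    p_psych_courses: float = 0.60
    p_counselors: float = 0.50
    p_counseling_rooms: float = 0.55

    def __post_init__(self) -> None:
        probs = [
            self.p_female, self.p_middle_school, self.p_left_behind,
            self.p_intact_family, self.p_parental_education_low,
            self.p_psych_courses, self.p_counselors, self.p_counseling_rooms,
            *self.grade_dist_primary, *self.grade_dist_middle, *self.ranking_dist,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for dist in (self.grade_dist_primary, self.grade_dist_middle, self.ranking_dist):
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError("distributions must sum to 1")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for depression status on planted risk indicators.

    ``main_effects`` maps risk-item labels to log odds ratios;
    ``interactions`` maps frozen pairs of labels to an extra log odds ratio
    applied when both indicators hold.  The default intercept is calibrated so
    marginal depression prevalence is close to 0.30 under the default
    marginals and correlation structure.
    """

    intercept: float = -2.05
    main_effects: dict[str, float] = field(
        default_factory=lambda: {
            "low family cohesion": 1.1,
            "high family conflict": 1.1,
            "low peer support": 0.5,
            "low teacher support": 0.5,
        }
    )
    interactions: dict[frozenset[str], float] = field(
        default_factory=lambda: {
            frozenset({"low family cohesion", "high family conflict"}): 0.8,
        }
    )

    def zeroed(self) -> "OutcomeModel":
        """Null model: same intercept, all planted effects removed."""
        return OutcomeModel(intercept=self.intercept, main_effects={}, interactions={})


def inter_item_corr_for_alpha(alpha: float, k: int) -> float:
    """Invert ``alpha = k*rho / (1 + (k-1)*rho)`` for the inter-item rho."""
    return alpha / (k - (k - 1) * alpha)


def discretization_attenuation(n_categories: int) -> float:
    """Squared correlation between a standard normal and its equiprobable
    ``c``-category integer discretization (the correlation-attenuation factor).
    """
    c = n_categories
    taus = stats.norm.ppf(np.arange(1, c) / c)
    r = stats.norm.pdf(taus).sum() / math.sqrt((c * c - 1) / 12.0)
    return float(r * r)


def _default_cross_scale_corr() -> np.ndarray:
    """Latent correlations among the six predictor scale levels.

    Cohesion moves against conflict and strain and with the school-support
    scales; the three school-climate scales hang together.
    """
    labels = _SCALE_ORDER
    r = np.eye(6)
    pairs = {
        ("cohesion", "conflict"): -0.45,
        ("cohesion", "financial_strain"): -0.20,
        ("cohesion", "teacher_support"): 0.30,
        ("cohesion", "peer_support"): 0.30,
        ("cohesion", "autonomy_support"): 0.25,
        ("conflict", "financial_strain"): 0.20,
        ("conflict", "teacher_support"): -0.20,
        ("conflict", "peer_support"): -0.20,
        ("conflict", "autonomy_support"): -0.15,
        ("financial_strain", "teacher_support"): -0.10,
        ("financial_strain", "peer_support"): -0.10,
        ("financial_strain", "autonomy_support"): -0.10,
        ("teacher_support", "peer_support"): 0.45,
        ("teacher_support", "autonomy_support"): 0.45,
        ("peer_support", "autonomy_support"): 0.40,
    }
    idx = {s: i for i, s in enumerate(labels)}
    for (a, b), v in pairs.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return r


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 2445
    marginals: DemographicMarginals = field(default_factory=DemographicMarginals)
    #: per-scale inter-item correlation targets (on the discretized scores)
    inter_item_corr: dict[str, float] = field(default_factory=dict)
    cross_scale_corr: np.ndarray = field(default_factory=_default_cross_scale_corr)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    #: DSRSC total distributions conditional on status (mean, sd), discretized
    #: truncated normals below / at-or-above the screening threshold
    dsrsc_nondep: tuple[float, float] = (10.0, 2.8)
    dsrsc_dep: tuple[float, float] = (18.0, 2.8)
    dsrsc_threshold: int = 15
    missingness_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must lie in [0, 1)")
        r = np.asarray(self.cross_scale_corr, dtype=float)
        if r.shape != (6, 6) or not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ValueError("cross_scale_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValueError("cross_scale_corr must be positive semi-definite")


def default_config(n: int = 2445, seed: int = 0, missingness_rate: float = 0.0) -> GeneratorConfig:
    """The documented study conditions: marginals, calibrated reliabilities,
    and planted risk effects.
    """
    codebook = default_codebook()
    rho = {
        s.name: inter_item_corr_for_alpha(ALPHA_TARGETS[s.name], s.item_count)
        for s in codebook.scales
        if s.name in _SCALE_ORDER
    }
    return GeneratorConfig(n=n, inter_item_corr=rho, seed=seed, missingness_rate=missingness_rate)


def _draw_demographics(rng: np.random.Generator, n: int, m: DemographicMarginals):
    female = rng.random(n) < m.p_female
    middle = rng.random(n) < m.p_middle_school
    grade = np.empty(n, dtype=int)
    prim = ~middle
    grade[prim] = rng.choice([5, 6], size=int(prim.sum()), p=m.grade_dist_primary)
    grade[middle] = rng.choice([7, 8, 9], size=int(middle.sum()), p=m.grade_dist_middle)
    return {
        "female": female,
        "grade": grade,
        "left_behind": rng.random(n) < m.p_left_behind,
        "intact": rng.random(n) < m.p_intact_family,
        "edu_low": rng.random(n) < m.p_parental_education_low,
        "ranking": rng.choice(["top10", "average", "last10"], size=n, p=m.ranking_dist),
        "courses": rng.random(n) < m.p_psych_courses,
        "counselors": rng.random(n) < m.p_counselors,
        "rooms": rng.random(n) < m.p_counseling_rooms,
    }


def _draw_scale_items(
    rng: np.random.Generator,
    z: np.ndarray,
    codebook: Codebook,
    inter_item_corr: dict[str, float],
) -> dict[str, np.ndarray]:
    """Threshold compound-symmetric latent item variables into integer scores."""
    items: dict[str, np.ndarray] = {}
    for si, name in enumerate(_SCALE_ORDER):
        scale = codebook.scale(name)
        c = scale.response_max - scale.response_min + 1
        lam = inter_item_corr[name] / discretization_attenuation(c)
        lam = min(lam, 0.95)
        k = scale.item_count
        u = math.sqrt(lam) * z[:, si : si + 1] + math.sqrt(1.0 - lam) * rng.standard_normal(
            (z.shape[0], k)
        )
        taus = stats.norm.ppf(np.arange(1, c) / c)
        items[name] = scale.response_min + (u[:, :, None] > taus).sum(axis=2)
    return items


def _risk_indicators(items: dict[str, np.ndarray], demo: dict) -> dict[str, np.ndarray]:
    """The 12 risk-criterion indicator arrays on this synthetic cohort."""
    out: dict[str, np.ndarray] = {}
    for label, scale, side in _RISK_QUARTILE:
        totals = items[scale].sum(axis=1)
        srt = np.sort(totals)
        p25, p75 = nearest_rank(srt, 0.25), nearest_rank(srt, 0.75)
        out[label] = totals <= p25 if side == "low" else totals >= p75
    flags = {
        "family_structure": ~demo["intact"],
        "left_behind": demo["left_behind"],
        "parental_education": demo["edu_low"],
        "psych_courses": ~demo["courses"],
        "counselors": ~demo["counselors"],
        "counseling_rooms": ~demo["rooms"],
    }
    for label, var in _RISK_FLAGS:
        out[label] = flags[var]
    return out


def _draw_status(
    rng: np.random.Generator, indicators: dict[str, np.ndarray], model: OutcomeModel, n: int
) -> np.ndarray:
    lp = np.full(n, model.intercept, dtype=float)
    for label, beta in model.main_effects.items():
        if label not in indicators:
            raise KeyError(f"outcome model references unknown risk item {label!r}")
        lp += beta * indicators[label]
    for pair, beta in model.interactions.items():
        a, b = sorted(pair)
        if a not in indicators or b not in indicators:
            raise KeyError(f"outcome model references unknown risk item pair {a!r}, {b!r}")
        lp += beta * (indicators[a] & indicators[b])
    p = 1.0 / (1.0 + np.exp(-lp))
    return rng.random(n) < p


def _draw_dsrsc(rng: np.random.Generator, depressed: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Totals from truncated discretized normals consistent with status,
    decomposed into 18 item scores in {0, 1, 2} that sum to the total.
    """
    n = depressed.shape[0]
    totals = np.empty(n, dtype=int)
    thr = cfg.dsrsc_threshold
    for is_dep, (mu, sd), (lo, hi) in (
        (False, cfg.dsrsc_nondep, (0, thr - 1)),
        (True, cfg.dsrsc_dep, (thr, 36)),
    ):
        mask = depressed == is_dep
        m = int(mask.sum())
        if m == 0:
            continue
        a, b = (lo - 0.5 - mu) / sd, (hi + 0.5 - mu) / sd
        draw = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=m, random_state=rng)
        totals[mask] = np.clip(np.rint(draw).astype(int), lo, hi)
    items = np.empty((n, 18), dtype=int)
    base, rem = totals // 18, totals % 18
    items[:] = base[:, None]
    for i in range(n):
        if rem[i]:
            items[i, rng.choice(18, size=rem[i], replace=False)] += 1
    return items


def generate_participants(
    config: GeneratorConfig, codebook: Codebook | None = None
) -> list[ParticipantRecord]:
    """Generate a synthetic cohort; deterministic for a given config seed."""
    codebook = codebook or default_codebook()
    n, seed = config.n, config.seed
    if n == 0:
        return []
    demo = _draw_demographics(_stage_rng(seed, "demographics"), n, config.marginals)
    chol = np.linalg.cholesky(
        np.asarray(config.cross_scale_corr, dtype=float) + 1e-12 * np.eye(6)
    )
    z = _stage_rng(seed, "latent").standard_normal((n, 6)) @ chol.T
    rho = config.inter_item_corr or default_config().inter_item_corr
    items = _draw_scale_items(_stage_rng(seed, "items"), z, codebook, rho)
    indicators = _risk_indicators(items, demo)
    depressed = _draw_status(_stage_rng(seed, "outcome"), indicators, config.outcome_model, n)
    items["dsrsc"] = _draw_dsrsc(_stage_rng(seed, "dsrsc"), depressed, config)

    missing_at: dict[int, tuple[str, int]] = {}
    if config.missingness_rate > 0.0:
        mrng = _stage_rng(seed, "missingness")
        hit = mrng.random(n) < config.missingness_rate
        for i in np.flatnonzero(hit):
            scale = codebook.scales[mrng.integers(len(codebook.scales))]
            missing_at[int(i)] = (scale.name, int(mrng.integers(scale.item_count)))

    records = []
    for i in range(n):
        responses = {}
        for scale in codebook.scales:
            vals = [int(v) for v in items[scale.name][i]]
            if i in missing_at and missing_at[i][0] == scale.name:
                vals[missing_at[i][1]] = None
            responses[scale.name] = tuple(vals)
        records.append(
            ParticipantRecord(
                participant_id=f"S{i + 1:05d}",
                gender="female" if demo["female"][i] else "male",
                grade=int(demo["grade"][i]),
                left_behind=bool(demo["left_behind"][i]),
                family_structure_intact=bool(demo["intact"][i]),
                parental_education_low=bool(demo["edu_low"][i]),
                academic_ranking=str(demo["ranking"][i]),
                school_psych_courses=bool(demo["courses"][i]),
                school_counselors=bool(demo["counselors"][i]),
                school_counseling_rooms=bool(demo["rooms"][i]),
                item_responses=responses,
            )
        )
    return records


@dataclass(frozen=True)
class RuleMetricsEstimate:
    """Monte-Carlo estimate of a planted rule's support/confidence/lift."""

    support: float
    confidence: float
    lift: float
    se_support: float
    se_confidence: float
    se_lift: float
    reps: int


def planted_rule_oracle(
    config: GeneratorConfig, lhs_items, reps: int = 50, seed: int = 0
) -> RuleMetricsEstimate:
    """Estimate the metrics of ``lhs_items => depression`` by direct simulation.

    Independent of the mining code: for each replicate cohort the LHS
    indicators are recomputed from the generative quantities and the three
    metrics counted directly.  Returns means with standard errors of the mean
    across replicates.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    lhs = sorted(set(lhs_items))
    codebook = default_codebook()
    rho = config.inter_item_corr or default_config().inter_item_corr
    sup, conf, lift = [], [], []
    seeds = np.random.SeedSequence((int(seed), _STAGES["oracle"])).generate_state(reps)
    for rep_seed in seeds:
        cfg = replace(config, seed=int(rep_seed) % (2**31), missingness_rate=0.0)
        n = cfg.n
        demo = _draw_demographics(_stage_rng(cfg.seed, "demographics"), n, cfg.marginals)
        chol = np.linalg.cholesky(np.asarray(cfg.cross_scale_corr, float) + 1e-12 * np.eye(6))
        z = _stage_rng(cfg.seed, "latent").standard_normal((n, 6)) @ chol.T
        items = _draw_scale_items(_stage_rng(cfg.seed, "items"), z, codebook, rho)
        indicators = _risk_indicators(items, demo)
        indicators["female"] = demo["female"]
        indicators["male"] = ~demo["female"]
        indicators["middle school students"] = demo["grade"] >= 7
        indicators["primary school students"] = demo["grade"] <= 6
        unknown = [l for l in lhs if l not in indicators]
        if unknown:
            raise KeyError(f"unknown item labels: {unknown}")
        depressed = _draw_status(
            _stage_rng(cfg.seed, "outcome"), indicators, cfg.outcome_model, n
        )
        has_lhs = np.logical_and.reduce([indicators[l] for l in lhs])
        n_lhs = int(has_lhs.sum())
        n_dep = int(depressed.sum())
        n_both = int((has_lhs & depressed).sum())
        if n_lhs == 0 or n_dep == 0:
            continue
        sup.append(n_both / n)
        conf.append(n_both / n_lhs)
        lift.append((n_both / n_lhs) / (n_dep / n))
    if not sup:
        raise ValueError("LHS or outcome never occurred in any replicate")
    sup, conf, lift = map(np.asarray, (sup, conf, lift))
    m = len(sup)
    sem = lambda x: float(x.std(ddof=1) / math.sqrt(m)) if m > 1 else float("nan")
    return RuleMetricsEstimate(
        float(sup.mean()), float(conf.mean()), float(lift.mean()),
        sem(sup), sem(conf), sem(lift), m,
    )
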