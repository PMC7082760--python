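"""Synthetic cohorts from the causal graph the DLVM assumes.

The generator forward-simulates the model's own graph with known ground
truth: Bernoulli latent confounders z1 and Gaussian latents z2, noisy
discrete proxies x1 (bit flips) and continuous proxies x2 (linear views plus
Gaussian noise), a single confounder score c = w . (z1 - 1/2, z2) driving
both the binary intervention t and the baseline outcome, and potential
outcomes y(0), y(1) under a zero, constant or heterogeneous treatment
effect.  The latent continuous outcomes are affinely placed on the
Gleason-Score scale and rounded into [6, 10] for the observed column; the
continuous values are retained in the truth block so that effect-recovery
checks are free of discretization bias.

Defaults: 5 + 5 true latent dimensions, 20 discrete and 20 continuous
proxies, bit-flip rate 0.1, continuous proxy noise sd 0.5, confounding
strength 1.0, outcome noise sd 0.5 — small enough that a full experiment
runs in minutes on one CPU while leaving the effect genuinely confounded
(the treated group's baseline outcome is shifted through c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import CohortTable, FeatureSchema

__all__ = [
    "DGPParams",
    "generate_cohort",
    "generate_prad_like_fixture",
    "true_effects",
    "dgp_weights",
    "PRAD_ABERRATIONS",
]

_T_BASE_RATE = 0.35        # marginal treatment rate at zero confounding
_Y_BASE = 7.2              # baseline GS location of y(0) on the latent scale
_Y_CONF_COEF = 0.8         # effect of the confounder score on the outcome


@dataclass
class DGPParams:
    """Parameters of the synthetic data-generating process."""

    n: int = 1000
    dim_z1_true: int = 5
    dim_z2_true: int = 5
    n_discrete_proxies: int = 20
    n_continuous_proxies: int = 20
    flip_rate: float = 0.1
    proxy_noise_sd: float = 0.5
    confounding: float = 1.0
    effect_model: str = "constant"   # zero | constant | heterogeneous
    tau: float = 1.0
    outcome_noise_sd: float = 0.5
    #: (race label, stratum size, additive effect shift); default: two equal
    #: strata EA/AA with no differential effect.
    strata: tuple[tuple[str, int, float], ...] = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self):
        if self.strata is None:
            half = self.n // 2
            self.strata = (("EA", self.n - half, 0.0), ("AA", half, 0.0))
        self.strata = tuple((str(r), int(s), float(e)) for r, s, e in self.strata)
        if sum(s for _, s, _ in self.strata) != self.n:
            raise ValueError("stratum sizes must sum to n")
        if not (0.0 <= self.flip_rate < 0.5):
            raise ValueError("flip_rate must lie in [0, 0.5)")
        if self.proxy_noise_sd <= 0 or self.outcome_noise_sd <= 0:
            raise ValueError("noise scales must be positive")
        if min(s for _, s, _ in self.strata) <= 0:
            raise ValueError("stratum sizes must be positive")
        if self.effect_model not in ("zero", "constant", "heterogeneous"):
            raise ValueError("effect_model must be zero/constant/heterogeneous")


def dgp_weights(params: DGPParams) -> dict[str, np.ndarray]:
    """Deterministic mixing weights of the DGP (for independent oracles).

    ``w_conf`` defines the standardized confounder score over the centered
    latent vector (z1 - 1/2, z2); ``w_het`` an independent second projection
    modulating the heterogeneous effect; ``proxy_matrix`` the linear map from
    z2 to the continuous proxies; ``t_intercept`` the treatment intercept.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0x5EED]))
    d = params.dim_z1_true + params.dim_z2_true
    var_scale = np.concatenate([
        np.full(params.dim_z1_true, 0.25),   # Var(z1 - 1/2)
        np.ones(params.dim_z2_true),
    ])

    def standardized(w):
        return w / np.sqrt(float(np.sum(w**2 * var_scale)))

    w_conf = standardized(rng.standard_normal(d))
    w_het = standardized(rng.standard_normal(d))
    proxy_matrix = rng.standard_normal(
        (params.dim_z2_true, params.n_continuous_proxies)
    ) / np.sqrt(params.dim_z2_true)
    return {
        "w_conf": w_conf,
        "w_het": w_het,
        "proxy_matrix": proxy_matrix,
        "t_intercept": float(logit(_T_BASE_RATE)),
    }


def _effect(params: DGPParams, c_het: np.ndarray) -> np.ndarray:
    if params.effect_model == "zero":
        return np.zeros_like(c_het)
    if params.effect_model == "constant":
        return np.full_like(c_het, params.tau)
    return params.tau * (1.0 + 0.5 * np.tanh(c_het))


def _discretize(y_lat: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(y_lat), 6, 10).astype(int)


def generate_cohort(params: DGPParams) -> CohortTable:
    """Sample one cohort with full counterfactual ground truth.

    Deterministic given ``params.seed``.  The returned table carries the
    truth block (integer ``y0_true``/``y1_true`` consistent with the observed
    outcome, plus continuous ``y0_latent``/``y1_latent``).
    """
    w = dgp_weights(params)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0xDA7A]))
    n = params.n

    z1 = (rng.random((n, params.dim_z1_true)) < 0.5).astype(float)
    z2 = rng.standard_normal((n, params.dim_z2_true))
    latent = np.concatenate([z1 - 0.5, z2], axis=1)
    c = latent @ w["w_conf"]
    c_het = latent @ w["w_het"]

    # discrete proxies: copies of z1 components with independent bit flips
    cols = np.arange(params.n_discrete_proxies) % params.dim_z1_true
    flips = rng.random((n, params.n_discrete_proxies)) < params.flip_rate
    x1 = np.abs(z1[:, cols] - flips.astype(float)).astype(int)

    x2 = z2 @ w["proxy_matrix"] + params.proxy_noise_sd * rng.standard_normal(
        (n, params.n_continuous_proxies)
    )

    p_t = expit(params.confounding * c + w["t_intercept"])
    t = (rng.random(n) < p_t).astype(int)

    race = np.concatenate([[r] * s for r, s, _ in params.strata])
    shift = np.concatenate([[e] * s for r, s, e in params.strata])

    y0_lat = _Y_BASE + _Y_CONF_COEF * c + params.outcome_noise_sd * rng.standard_normal(n)
    y1_lat = y0_lat + _effect(params, c_het) + shift
    y0, y1 = _discretize(y0_lat), _discretize(y1_lat)
    y_obs = np.where(t == 1, y1, y0)

    frame = pd.DataFrame(
        {f"d{j:02d}": x1[:, j] for j in range(params.n_discrete_proxies)}
        | {f"x{j:02d}": x2[:, j] for j in range(params.n_continuous_proxies)}
    )
    frame["aberration"] = t
    frame["gleason_score"] = y_obs
    frame["race"] = race
    frame["y0_true"] = y0
    frame["y1_true"] = y1
    frame["y0_latent"] = y0_lat
    frame["y1_latent"] = y1_lat

    schema = FeatureSchema(
        discrete_columns=tuple(f"d{j:02d}" for j in range(params.n_discrete_proxies)),
        continuous_columns=tuple(f"x{j:02d}" for j in range(params.n_continuous_proxies)),
        treatment_column="aberration",
        outcome_column="gleason_score",
        race_column="race",
        aberration_expression_map={"aberration": ()},
    )
    return CohortTable(schema, frame)


@dataclass
class TrueEffects:
    """Ground-truth effects of a synthetic cohort (latent, pre-rounding)."""

    ite: np.ndarray
    ate: float
    by_race: dict[str, float] = field(default_factory=dict)


def true_effects(cohort: CohortTable) -> TrueEffects:
    """Per-patient true ITE and group ATEs from the truth block.

    Uses the continuous-scale potential outcomes when available (free of
    rounding), else the integer truth columns.
    """
    if not cohort.has_truth:
        raise ValueError("cohort has no truth block")
    cols = ("y1_latent", "y0_latent") if "y1_latent" in cohort.frame.columns else ("y1_true", "y0_true")
    ite = (cohort.frame[cols[0]] - cohort.frame[cols[1]]).to_numpy(dtype=float)
    race = cohort.race
    by_race = {r: float(ite[race == r].mean()) for r in np.unique(race)}
    return TrueEffects(ite=ite, ate=float(ite.mean()), by_race=by_race)


# -- prostate-cohort-shaped fixture ---------------------------------------

PRAD_ABERRATIONS = (
    "ERG_fusion",
    "SPOP_mut", "TP53_mut", "FOXA1_mut", "ATM_mut", "BRCA2_mut", "PTEN_mut",
    "BRCA1_germline", "BRCA2_germline",
    "LCP1_cna", "ERG_cna", "PTEN_cna", "FOXA1_cna",
)

_PRAD_FREQ = {
    "ERG_fusion": 0.40, "SPOP_mut": 0.11, "TP53_mut": 0.10, "FOXA1_mut": 0.09,
    "ATM_mut": 0.06, "BRCA2_mut": 0.05, "PTEN_mut": 0.05,
    "BRCA1_germline": 0.03, "BRCA2_germline": 0.04,
    "LCP1_cna": 0.10, "ERG_cna": 0.15, "PTEN_cna": 0.16, "FOXA1_cna": 0.09,
}

_PRAD_EXPR_MAP = {
    "ERG_fusion": ("ERG_expr",),
    "ERG_cna": ("ERG_expr",),
    "PTEN_mut": ("PTEN_expr",),
    "PTEN_cna": ("PTEN_expr",),
    "FOXA1_mut": ("FOXA1_expr",),
    "FOXA1_cna": ("FOXA1_expr",),
    "LCP1_cna": ("LCP1_expr",),
    "SPOP_mut": (), "TP53_mut": (), "ATM_mut": (), "BRCA2_mut": (),
    "BRCA1_germline": (), "BRCA2_germline": (),
}


def generate_prad_like_fixture(seed: int = 0) -> CohortTable:
    """A 313-patient cohort shaped like the motivating prostate study.

    Two race strata of 270 (EA) and 43 (AA) patients, the 13 canonical
    binary aberration columns, an expression block wired to the CNA/fusion
    aberrations through the schema's expression map, two continuous clinical
    fields, and integer Gleason Scores covering all three grade strata in
    both races.  Synthetic throughout: marginal frequencies are plausible,
    not matched to any real cohort.  No truth block (mirrors real data).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9AD]))
    sizes = {"EA": 270, "AA": 43}
    n = sum(sizes.values())
    race = np.concatenate([["EA"] * sizes["EA"], ["AA"] * sizes["AA"]])

    c = rng.standard_normal(n)  # shared latent aggressiveness score
    frame = pd.DataFrame({"race": race})
    for ab in PRAD_ABERRATIONS:
        base = logit(_PRAD_FREQ[ab])
        frame[ab] = (rng.random(n) < expit(base + 0.6 * c)).astype(int)

    genes = ("ERG", "PTEN", "FOXA1", "LCP1", "AR", "MYC")
    for g in genes:
        driver = np.zeros(n)
        for ab, cols in _PRAD_EXPR_MAP.items():
            if f"{g}_expr" in cols:
                driver = driver + frame[ab].to_numpy()
        frame[f"{g}_expr"] = 0.7 * c + 1.2 * driver + rng.standard_normal(n)
    frame["age"] = np.round(62 + 4 * c + 6 * rng.standard_normal(n), 1)
    frame["psa"] = np.round(np.exp(2.0 + 0.5 * c + 0.4 * rng.standard_normal(n)), 2)

    gs = _discretize(7.0 + 0.9 * c + 0.35 * frame["ERG_fusion"].to_numpy()
                     + 0.5 * rng.standard_normal(n))
    frame["gleason_score"] = gs

    # guarantee every (race, grade) cell is populated
    targets = {"low": 6, "intermediate": 7, "high": 9}
    for r, size in (("EA", sizes["EA"]), ("AA", sizes["AA"])):
        rows = np.flatnonzero(race == r)
        for k, (label, g_fix) in enumerate(targets.items()):
            in_cell = (frame.loc[rows, "gleason_score"] <= 6) if label == "low" else (
                (frame.loc[rows, "gleason_score"] == 7) if label == "intermediate"
                else (frame.loc[rows, "gleason_score"] >= 8)
            )
            if not in_cell.any():
                frame.loc[rows[k], "gleason_score"] = g_fix

    schema = FeatureSchema(
        discrete_columns=tuple(a for a in PRAD_ABERRATIONS if a != "ERG_fusion"),
        continuous_columns=tuple(f"{g}_expr" for g in genes) + ("age", "psa"),
        treatment_column="ERG_fusion",
        outcome_column="gleason_score",
        race_column="race",
        aberration_expression_map=dict(_PRAD_EXPR_MAP),
    )
    return CohortTable(schema, frame)
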