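"""Synthetic study generators with known latent ground truth.

Two presets mirror the structure of the packaged example studies:

``healthy_nordic`` — a matched case-control study of incident type 2
diabetes (T2D): 1000 observations forming 500 case-control pairs
matched on gender and age, with an 11-variable baseline table, a
31-variable plasma-metabolite table and a 17-variable food-intake table
(15 FFQ items plus two composite diet-index columns).

``camp`` — a cross-sectional study of 300 young adults: an 11-variable
clinical table (BMI, liver enzymes, lipids, glucose), a 20-variable
BMI-predictive metabolite table and an 11-variable FFQ food table.

Both presets are transparent latent-factor models.  Each subject
carries two latent diet factors; foods are ordinal-discretized (eight
FFQ-like categories by quantile cut) linear mixtures of the factors,
metabolites are continuous log-scale linear mixtures with communality
(share of variance from the latents) 0.4, and outcomes depend on the
factors with known coefficients, so parameter-recovery tests have an
exact truth to recover.  In the matched preset the unhealthy-diet
factor carries the T2D risk (default log-odds 0.5 per SD); in the
cross-sectional preset an adiposity factor drives BMI, liver enzymes
and an adverse lipid profile while a seafood/omega-3 factor lowers the
liver enzymes.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticStudy", "generate_healthy_nordic", "generate_camp",
           "save_study"]

N_FFQ_CATEGORIES = 8
METABOLITE_COMMUNALITY = 0.4
FACTOR_CORR_HND = -0.3

# --- healthy_nordic preset -------------------------------------------------
# F1 = healthy Nordic pattern, F2 = unhealthy pattern (corr -0.3).
# Nine index foods load F1, six non-index foods load F2; two composite
# index columns (Baltic Sea Diet Score-like, Healthy Nordic Food
# Index-like) are weighted sums of the index foods.
HND_INDEX_FOODS = [
    "wholegrain_bread", "oatmeal", "root_vegetables", "cabbages",
    "apples_pears", "berries", "fish", "shellfish", "lowfat_milk",
]
HND_OTHER_FOODS = [
    "margarine", "sausages", "poultry", "red_meat", "refined_grains",
    "sugary_drinks",
]
HND_FOOD_LOADINGS = {
    # food: (loading on F1, loading on F2)
    "wholegrain_bread": (0.8, 0.0), "oatmeal": (0.7, 0.0),
    "root_vegetables": (0.7, 0.0), "cabbages": (0.6, 0.0),
    "apples_pears": (0.6, -0.1), "berries": (0.7, 0.0),
    "fish": (0.7, 0.0), "shellfish": (0.5, 0.0), "lowfat_milk": (0.5, 0.0),
    "margarine": (0.0, 0.7), "sausages": (-0.1, 0.8), "poultry": (0.0, 0.6),
    "red_meat": (-0.1, 0.7), "refined_grains": (0.0, 0.7),
    "sugary_drinks": (0.0, 0.6),
}
HND_FOOD_NOISE_SD = 0.8
HND_N_MET_F1 = 21          # two-thirds of the 31 metabolites track F1
HND_EFFECT_BETA = (0.0, 0.5)

# --- camp preset -----------------------------------------------------------
# G1 = adiposity / meat & refined-grain pattern, G2 = seafood / omega-3.
CAMP_FOODS = {
    "red_meat": (0.8, 0.0), "processed_meat": (0.7, 0.0),
    "refined_grains": (0.7, 0.0), "fast_food": (0.6, 0.0),
    "sugary_drinks": (0.5, 0.0), "fruits": (0.3, 0.1),
    "vegetables": (-0.2, 0.2), "seafood": (0.0, 0.8), "fish": (0.0, 0.7),
    "whole_grains": (-0.3, 0.1), "dairy": (0.1, 0.0),
}
CAMP_N_MET_G1 = 14         # remaining 6 are marine-lipid-like (G2)
CAMP_CLIN_COEF = {
    # trait: (intercept, coef on G1, coef on G2, noise sd)
    "bmi": (23.0, 2.0, -0.2, 1.5),
    "ggt": (25.0, 8.0, -4.0, 8.0),
    "alt": (22.0, 7.0, -3.5, 7.0),
    "ast": (21.0, 5.0, -2.5, 5.0),
    "fasting_glucose": (4.9, 0.35, 0.0, 0.35),
    "triglycerides": (1.2, 0.45, -0.1, 0.4),
    "total_cholesterol": (4.6, 0.35, 0.1, 0.6),
    "hdl": (1.4, -0.18, 0.05, 0.2),
    "ldl": (2.7, 0.35, 0.0, 0.55),
}


@dataclass
class SyntheticStudy:
    """Three row-matched tables plus the generating ground truth."""

    baseline: pd.DataFrame     # baseline/clinical table
    metabolites: pd.DataFrame
    foods: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (list(self.baseline.index) == list(self.metabolites.index)
                == list(self.foods.index)):
            raise ValueError("tables are not row-wise matched")


def _ordinal_cut(values: np.ndarray, n_cat: int = N_FFQ_CATEGORIES
                 ) -> np.ndarray:
    """Quantile-discretize a continuous column into 1..n_cat."""
    ranks = values.argsort().argsort()
    return (ranks * n_cat // len(values)) + 1


def _metabolite_mixing(rng, n_met: int, n_f1: int) -> np.ndarray:
    """(n_met, 2) mixing matrix: first n_f1 rows load factor 1."""
    M = np.zeros((n_met, 2))
    M[:n_f1, 0] = rng.uniform(0.6, 1.0, n_f1) * rng.choice([1, -1], n_f1,
                                                           p=[0.8, 0.2])
    M[n_f1:, 1] = rng.uniform(0.6, 1.0, n_met - n_f1) * \
        rng.choice([1, -1], n_met - n_f1, p=[0.8, 0.2])
    return M


def _mix_metabolites(rng, F: np.ndarray, M: np.ndarray,
                     communality: float = METABOLITE_COMMUNALITY
                     ) -> np.ndarray:
    """Continuous log-scale metabolite matrix with given communality."""
    signal = F @ M.T
    sig_var = signal.var(axis=0, ddof=1)
    noise_sd = np.sqrt(sig_var * (1 - communality) / communality)
    return signal + rng.normal(0, noise_sd, signal.shape)


def generate_healthy_nordic(seed: int, n_pairs: int = 500,
                            effect_beta=HND_EFFECT_BETA) -> SyntheticStudy:
    """Matched T2D case-control study (500 pairs by default).

    Case status is drawn within each pair from the conditional logistic
    model with log-odds ``effect_beta`` on the latent factors (F1, F2);
    the default (0, +0.5) puts the risk on the unhealthy-diet factor.
    """
    effect_beta = np.asarray(effect_beta, dtype=float)
    if effect_beta.shape != (2,):
        raise ValueError("effect_beta must have length 2 (one per factor)")
    if n_pairs < 10:
        raise ValueError("n_pairs must be >= 10")
    rng = np.random.default_rng(seed)
    n = 2 * n_pairs
    cov = np.array([[1.0, FACTOR_CORR_HND], [FACTOR_CORR_HND, 1.0]])
    F = rng.multivariate_normal([0, 0], cov, size=n)

    # foods: 15 ordinal FFQ items + 2 composite diet indices
    food_names = HND_INDEX_FOODS + HND_OTHER_FOODS
    A = np.array([HND_FOOD_LOADINGS[f] for f in food_names])
    raw = F @ A.T + rng.normal(0, HND_FOOD_NOISE_SD, (n, len(food_names)))
    foods = pd.DataFrame(
        {name: _ordinal_cut(raw[:, j]) for j, name in enumerate(food_names)})
    bsds_w = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 1.0, 1.0, 1.0, 1.0])
    hnfi_w = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
    foods["bsds_index"] = foods[HND_INDEX_FOODS].to_numpy() @ bsds_w
    foods["hnfi_index"] = foods[HND_INDEX_FOODS].to_numpy() @ hnfi_w

    # metabolites: 31 continuous log-scale mixtures
    M = _metabolite_mixing(rng, 31, HND_N_MET_F1)
    mets = pd.DataFrame(_mix_metabolites(rng, F, M),
                        columns=[f"met_{i + 1:02d}" for i in range(31)])

    # pairing: members 2i, 2i+1 form a pair sharing gender, |age gap| <= 2
    gender = np.repeat(rng.integers(0, 2, n_pairs), 2)
    base_age = np.repeat(rng.integers(40, 61, n_pairs), 2).astype(float)
    age = base_age + rng.integers(-1, 2, n)  # within-pair gap <= 2 years
    set_id = np.repeat([f"set{i + 1}" for i in range(n_pairs)], 2)

    # case status within pair: conditional logistic draw on (F1, F2)
    eta = F @ effect_beta
    outcome = np.zeros(n, dtype=int)
    for i in range(n_pairs):
        a, b = 2 * i, 2 * i + 1
        p_first = 1.0 / (1.0 + np.exp(-(eta[a] - eta[b])))
        case = a if rng.random() < p_first else b
        outcome[case] = 1

    bmi = 25.0 + 1.0 * F[:, 1] - 0.3 * F[:, 0] + rng.normal(0, 2.5, n)
    smoking = (rng.random(n) < 1 / (1 + np.exp(-(-1.2 + 0.3 * F[:, 1])))
               ).astype(int)
    education = rng.integers(1, 4, n)
    physical_activity = np.clip(
        np.round(3 + 0.4 * F[:, 0] + rng.normal(0, 1, n)), 1, 5).astype(int)
    energy_intake = 2000 + 120 * F[:, 0] + 180 * F[:, 1] + \
        rng.normal(0, 350, n)
    baseline = pd.DataFrame({
        "set_id": set_id,
        "outcome": outcome,
        "gender": gender,
        "age": age,
        "bmi": bmi,
        "smoking": smoking,
        "education": education,
        "physical_activity": physical_activity,
        "energy_intake": energy_intake,
        "sample_storage_months": rng.integers(6, 120, n),
        "fasting_hours": rng.integers(8, 15, n),
    })

    obs_ids = [f"obs{i + 1}" for i in range(n)]
    for df in (baseline, mets, foods):
        df.index = pd.Index(obs_ids, name="obs_id")
    truth = {
        "factors": pd.DataFrame(F, index=obs_ids, columns=["F1", "F2"]),
        "food_mixing": pd.DataFrame(A, index=food_names,
                                    columns=["F1", "F2"]),
        "metabolite_mixing": pd.DataFrame(
            M, index=mets.columns, columns=["F1", "F2"]),
        "outcome_coefficients": {"F1": float(effect_beta[0]),
                                 "F2": float(effect_beta[1])},
        "matching_variables": ["gender", "age"],
        "factor_names": {"F1": "healthy Nordic pattern",
                         "F2": "unhealthy pattern"},
        "index_foods": HND_INDEX_FOODS,
        "seed": int(seed),
    }
    return SyntheticStudy(baseline=baseline, metabolites=mets, foods=foods,
                          truth=truth)


def generate_camp(seed: int, n_obs: int = 300) -> SyntheticStudy:
    """Cross-sectional metabolic-phenotype study (300 subjects default)."""
    if n_obs < 30:
        raise ValueError("n_obs must be >= 30")
    rng = np.random.default_rng(seed)
    G = rng.multivariate_normal([0, 0], np.eye(2), size=n_obs)

    food_names = list(CAMP_FOODS)
    A = np.array([CAMP_FOODS[f] for f in food_names])
    raw = G @ A.T + rng.normal(0, HND_FOOD_NOISE_SD, (n_obs, len(food_names)))
    foods = pd.DataFrame(
        {name: _ordinal_cut(raw[:, j]) for j, name in enumerate(food_names)})

    M = _metabolite_mixing(rng, 20, CAMP_N_MET_G1)
    met_names = [f"met_{i + 1:02d}" for i in range(CAMP_N_MET_G1)] + \
        [f"pc_marine_{i + 1}" for i in range(20 - CAMP_N_MET_G1)]
    mets = pd.DataFrame(_mix_metabolites(rng, G, M), columns=met_names)

    clin = pd.DataFrame({
        "age": rng.integers(18, 36, n_obs),
        "gender": rng.integers(0, 2, n_obs),
    })
    for trait, (b0, b1, b2, sd) in CAMP_CLIN_COEF.items():
        clin[trait] = b0 + b1 * G[:, 0] + b2 * G[:, 1] + \
            rng.normal(0, sd, n_obs)

    obs_ids = [f"obs{i + 1}" for i in range(n_obs)]
    for df in (clin, mets, foods):
        df.index = pd.Index(obs_ids, name="obs_id")
    truth = {
        "factors": pd.DataFrame(G, index=obs_ids, columns=["G1", "G2"]),
        "food_mixing": pd.DataFrame(A, index=food_names,
                                    columns=["G1", "G2"]),
        "metabolite_mixing": pd.DataFrame(M, index=met_names,
                                          columns=["G1", "G2"]),
        "clinical_coefficients": CAMP_CLIN_COEF,
        "marine_lipid_metabolites": met_names[CAMP_N_MET_G1:],
        "factor_names": {"G1": "adiposity / meat & refined grains",
                         "G2": "seafood / omega-3"},
        "seed": int(seed),
    }
    return SyntheticStudy(baseline=clin, metabolites=mets, foods=foods,
                          truth=truth)


def save_study(study: SyntheticStudy, path, prefix: str = "") -> None:
    """Write the three tables as TSV plus a ``truth.json`` to ``path``."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    study.baseline.to_csv(path / f"{prefix}baseline.tsv", sep="\t")
    study.metabolites.to_csv(path / f"{prefix}metabolites.tsv", sep="\t")
    study.foods.to_csv(path / f"{prefix}foods.tsv", sep="\t")
    truth = {}
    for key, val in study.truth.items():
        if isinstance(val, pd.DataFrame):
            truth[key] = {"index": list(map(str, val.index)),
                          "columns": list(map(str, val.columns)),
                          "values": val.to_numpy().tolist()}
        else:
            truth[key] = val
    (path / f"{prefix}truth.json").write_text(json.dumps(truth, indent=2))
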