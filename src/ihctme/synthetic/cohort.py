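"""Synthetic cohort tables with the group/association structure of a
melanocytic-lesion IHC study.

One row per lesion across six histological groups (benign nevi,
dysplastic nevi, in situ melanoma, thin pT1 and deep pT4 primary
melanoma, lymph-node metastasis pN1), carrying hotspot marker values,
semi-quantitative IDO tumor scores, clinicopathological covariates and
survival fields.  The generative model:

* hotspot counts — means of 3 (non-invasive) or 5 (invasive) per-field
  negative-binomial draws with group-specific means and a shared
  dispersion, giving overdispersed, often half-integer sample values;
* IDO tumor coverage — a per-group categorical over the five coverage
  bins, with the continuous fraction drawn uniformly inside the bin;
* recurrence (invasive groups) — logistic in IDO positivity with a
  configurable odds ratio on top of group-specific baselines;
* survival — exponential death times whose hazard is multiplied by a
  configurable ratio for recurrent cases; independent exponential
  censoring; recurrence-free survival uses the earlier of recurrence
  and death.

`CohortSimParams.null()` switches every effect off (equal means, equal
coverage distributions, odds ratio 1, hazard ratio 1), which is the
configuration for type-I-error calibration of the downstream tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..datatypes import GROUPS, INVASIVE_GROUPS
from .. import scoring

_COVERAGE_BIN_EDGES = [(0.0, 0.01), (0.01, 0.05), (0.05, 0.10), (0.10, 0.20), (0.20, 1.0)]


def _default_group_sizes() -> dict[str, int]:
    return {"benign": 25, "dysplastic": 27, "in_situ": 15, "pT1": 36, "pT4": 39, "pN1": 41}


def _default_treg_means() -> dict[str, float]:
    return {"benign": 12.0, "dysplastic": 18.0, "in_situ": 30.0, "pT1": 45.0, "pT4": 65.0, "pN1": 75.0}


def _default_ido_stromal_means() -> dict[str, float]:
    return {"benign": 8.0, "dysplastic": 12.0, "in_situ": 22.0, "pT1": 30.0, "pT4": 48.0, "pN1": 60.0}


def _default_coverage_probs() -> dict[str, list[float]]:
    return {
        "benign": [0.92, 0.05, 0.02, 0.01, 0.00],
        "dysplastic": [0.88, 0.07, 0.03, 0.02, 0.00],
        "in_situ": [0.75, 0.12, 0.07, 0.04, 0.02],
        "pT1": [0.65, 0.15, 0.10, 0.06, 0.04],
        "pT4": [0.45, 0.20, 0.15, 0.12, 0.08],
        "pN1": [0.35, 0.22, 0.18, 0.14, 0.11],
    }


def _default_recurrence_probs() -> dict[str, float]:
    return {"pT1": 0.12, "pT4": 0.45, "pN1": 0.80}


def _default_covariate_probs() -> dict[str, dict[str, float]]:
    return {
        "ulceration": {"pT1": 0.15, "pT4": 0.60, "pN1": 0.50},
        "nodular_growth": {"pT1": 0.25, "pT4": 0.55, "pN1": 0.50},
        "mitoses_present": {"pT1": 0.40, "pT4": 0.80, "pN1": 0.70},
        "capsule_rupture": {"pN1": 0.35},
    }


@dataclass
class CohortSimParams:
    """Generative parameters for one synthetic cohort."""

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    treg_count_means: dict[str, float] = field(default_factory=_default_treg_means)
    ido_stromal_means: dict[str, float] = field(default_factory=_default_ido_stromal_means)
    count_dispersion: float = 4.0
    ido_coverage_probs: dict[str, list[float]] = field(default_factory=_default_coverage_probs)
    effect_ido_on_recurrence: float = 4.0  # odds ratio
    baseline_recurrence_probs: dict[str, float] = field(default_factory=_default_recurrence_probs)
    covariate_probs: dict[str, dict[str, float]] = field(default_factory=_default_covariate_probs)
    baseline_hazard: float = 0.08  # per year
    hazard_ratio_recurrence: float = 2.0
    recurrence_time_rate: float = 0.25  # per year, for recurrent cases
    censoring_rate: float = 0.30
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must not be empty")
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown histological group {g!r}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        for name, means in (("treg", self.treg_count_means), ("ido_stromal", self.ido_stromal_means)):
            if any(m <= 0 for m in means.values()):
                raise ValueError(f"{name} count means must be positive")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive")
        for g, probs in self.ido_coverage_probs.items():
            if len(probs) != 5 or any(p < 0 for p in probs):
                raise ValueError(f"coverage probabilities for {g!r} must be 5 non-negative values")
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"coverage probabilities for {g!r} must sum to 1")
        if self.effect_ido_on_recurrence < 0:
            raise ValueError("effect_ido_on_recurrence must be >= 0")
        if self.baseline_hazard <= 0 or self.hazard_ratio_recurrence <= 0:
            raise ValueError("hazards must be positive")
        if not 0 <= self.censoring_rate < 1 or not 0 <= self.missing_rate < 1:
            raise ValueError("rates must lie in [0, 1)")

    @classmethod
    def null(cls, n_per_group: int = 30, seed: int = 0) -> "CohortSimParams":
        """All effects off: the configuration for type-I-error calibration."""
        flat_cov = [0.50, 0.20, 0.15, 0.10, 0.05]
        return cls(
            group_sizes={g: n_per_group for g in GROUPS},
            treg_count_means={g: 45.0 for g in GROUPS},
            ido_stromal_means={g: 35.0 for g in GROUPS},
            ido_coverage_probs={g: list(flat_cov) for g in GROUPS},
            effect_ido_on_recurrence=1.0,
            baseline_recurrence_probs={g: 0.45 for g in INVASIVE_GROUPS},
            covariate_probs={
                "ulceration": {g: 0.5 for g in INVASIVE_GROUPS},
                "nodular_growth": {g: 0.5 for g in INVASIVE_GROUPS},
                "mitoses_present": {g: 0.5 for g in INVASIVE_GROUPS},
                "capsule_rupture": {"pN1": 0.5},
            },
            hazard_ratio_recurrence=1.0,
            seed=seed,
        )


def _nb_mean_of_fields(rng, mu: float, dispersion: float, k_fields: int) -> float:
    """Mean of k per-field negative-binomial counts (NB2: var = mu + mu^2/r)."""
    r = dispersion
    p = r / (r + mu)
    return float(rng.negative_binomial(r, p, size=k_fields).mean())


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Draw one cohort table; deterministic in ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []
    idx = 0
    for group in GROUPS:
        n = params.group_sizes.get(group, 0)
        invasive = group in INVASIVE_GROUPS
        k_fields = 5 if invasive else 3
        for _ in range(n):
            idx += 1
            row: dict = {"sample_id": f"S{idx:04d}", "group": group}
            row["treg_count"] = _nb_mean_of_fields(
                rng, params.treg_count_means[group], params.count_dispersion, k_fields
            )
            row["ido_stromal_count"] = _nb_mean_of_fields(
                rng, params.ido_stromal_means[group], params.count_dispersion, k_fields
            )

            cat = int(rng.choice(5, p=params.ido_coverage_probs[group]))
            lo, hi = _COVERAGE_BIN_EDGES[cat]
            frac = float(rng.uniform(lo, hi))
            intensity = int(rng.choice([1, 2, 3], p=[0.45, 0.35, 0.20])) if cat >= 1 else None
            score = scoring.score_tumor(frac, intensity_category=intensity)
            row["ido_coverage_fraction"] = score.coverage_fraction
            row["ido_coverage_category"] = score.coverage_category
            row["ido_intensity_category"] = score.intensity_category
            row["ido_status"] = score.ido_status
            row["ido_intensity_group"] = score.intensity_group

            row["sex"] = "male" if rng.random() < 0.56 else "female"
            row["age_years"] = float(np.clip(rng.normal(59.0, 16.0), 15, 95))

            if group == "pT1":
                row["breslow_mm"] = float(rng.uniform(0.29, 1.0))
            elif group == "pT4":
                row["breslow_mm"] = float(4.0 + rng.exponential(4.5))
            elif group == "pN1":
                row["breslow_mm"] = float(
                    rng.uniform(0.29, 1.0) if rng.random() < 0.5 else 4.0 + rng.exponential(4.5)
                )
            else:
                row["breslow_mm"] = np.nan

            for cov, probs in params.covariate_probs.items():
                row[cov] = float(rng.random() < probs[group]) if group in probs else np.nan

            if invasive:
                p0 = params.baseline_recurrence_probs[group]
                logit = np.log(p0 / (1 - p0))
                if score.ido_status == scoring.IDO_POSITIVE and params.effect_ido_on_recurrence > 0:
                    logit += np.log(params.effect_ido_on_recurrence)
                p_rec = 1.0 / (1.0 + np.exp(-logit))
                recurrent = rng.random() < p_rec

                h0 = params.baseline_hazard
                hazard = h0 * (params.hazard_ratio_recurrence if recurrent else 1.0)
                t_death = rng.exponential(1.0 / hazard)
                c_rate = h0 * params.censoring_rate / max(1.0 - params.censoring_rate, 1e-9)
                t_cens = rng.exponential(1.0 / c_rate) if c_rate > 0 else np.inf
                follow_up = min(t_death, t_cens)
                event_death = t_death <= t_cens

                t_rec = rng.exponential(1.0 / params.recurrence_time_rate) if recurrent else np.inf
                observed_rec = recurrent and t_rec <= follow_up
                rfs_time = min(t_rec, follow_up)
                event_rfs = observed_rec or event_death

                row["recurrence"] = float(observed_rec)
                if observed_rec:
                    loco = rng.random() < 0.60
                    distal = rng.random() < 0.60
                    if not (loco or distal):
                        loco = True
                    row["locoregional_recurrence"] = float(loco)
                    row["distal_recurrence"] = float(distal)
                else:
                    row["locoregional_recurrence"] = 0.0
                    row["distal_recurrence"] = 0.0
                row["follow_up_years"] = float(follow_up)
                row["event_death_melanoma"] = float(event_death)
                row["rfs_years"] = float(rfs_time)
                row["event_recurrence_free"] = float(event_rfs)
            else:
                for c in (
                    "recurrence", "locoregional_recurrence", "distal_recurrence",
                    "follow_up_years", "event_death_melanoma", "rfs_years",
                    "event_recurrence_free",
                ):
                    row[c] = np.nan
            rows.append(row)

    df = pd.DataFrame(rows)

    if params.missing_rate > 0 and len(df):
        miss_cols = [
            "age_years", "breslow_mm", "ulceration", "nodular_growth",
            "mitoses_present", "capsule_rupture",
        ]
        for col in miss_cols:
            mask = rng.random(len(df)) < params.missing_rate
            df.loc[mask, col] = np.nan

    df.attrs["provenance"] = {"seed": params.seed, "params": asdict(params)}
    return df


def simulate_survival(
    n: int,
    hazard_ratio: float = 2.0,
    baseline_hazard: float = 0.08,
    censoring_rate: float = 0.30,
    covariate_p: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival benchmark with a binary covariate of known hazard ratio.

    Death times are exponential with hazard ``baseline_hazard *
    hazard_ratio**x`` for covariate ``x`` ∈ {0, 1}; censoring is an
    independent exponential calibrated to the requested rate in the
    baseline arm.  Used for Cox parameter-recovery checks.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < covariate_p).astype(float)
    hazard = baseline_hazard * hazard_ratio**x
    t_death = rng.exponential(1.0 / hazard)
    c_rate = baseline_hazard * censoring_rate / max(1.0 - censoring_rate, 1e-9)
    t_cens = rng.exponential(1.0 / c_rate, size=n) if c_rate > 0 else np.full(n, np.inf)
    return pd.DataFrame(
        {
            "time": np.minimum(t_death, t_cens),
            "event": (t_death <= t_cens).astype(float),
            "recurrence": x,
        }
    )


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    """Write the cohort CSV plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    prov = df.attrs.get("provenance")
    if prov is not None:
        Path(str(path) + ".provenance.json").write_text(json.dumps(prov, indent=1))
    return path
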