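"""Simulated cohort tables with the structure the nigral-volume analysis assumes.

Each subject row carries a group label, demographic covariates (age, sex,
imaging site, total brain volume) and clinical scores, plus an SNc volume in
mm³ drawn as

    volume = group_mean + covariate effects (mean-centred) + Gaussian residual

with the residual variance chosen so the marginal group standard deviation
matches the group specification. Covariate effects default to zero, so the
marginal distributions equal the group means/SDs; nonzero effects are opt-in
for ANCOVA power experiments.

Two ready-made cohort specifications mirror the published PPMI study
structure: a five-group control/prodromal/PD cohort (n = 50/217/76/194/26)
and a three-group non-manifest-carrier cohort (n = 50/46/44).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "simulate_cohort",
    "pathology_cohort_spec",
    "nmc_cohort_spec",
    "GROUP_LABELS",
]

GROUP_LABELS = ("control", "NMC-LRRK2", "NMC-GBA1", "hyposmia", "RBD",
                "de-novo-PD", "moderate-PD")

CLINICAL_VARS = ("mds_updrs3", "moca", "upsit", "education",
                 "disease_duration", "levodopa_equivalents")


@dataclass
class GroupSpec:
    """One group's sample size and marginal distributions.

    ``clinical`` maps a clinical variable name to its (mean, sd); variables
    not listed are emitted as NaN (e.g. UPSIT unavailable in moderate PD).
    """

    label: str
    n: int
    volume_mean: float
    volume_sd: float
    age_mean: float = 63.0
    age_sd: float = 10.0
    male_fraction: float = 0.5
    clinical: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.volume_sd < 0 or self.age_sd < 0:
            raise ValueError(f"group {self.label!r}: sds must be >= 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError(f"group {self.label!r}: male_fraction must lie in [0, 1]")
        for name, (_, sd) in self.clinical.items():
            if sd < 0:
                raise ValueError(f"group {self.label!r}: sd of {name!r} must be >= 0")


@dataclass
class CohortSpec:
    groups: list[GroupSpec] = field(default_factory=list)
    site_labels: tuple = ("site_A", "site_B", "site_C", "site_D")
    site_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    tbv_mean: float = 1.15e6
    tbv_sd: float = 1.1e5
    # Additive effects on volume; all default to zero so marginal group
    # means/sds equal the GroupSpec values exactly.
    effect_age: float = 0.0
    effect_male: float = 0.0
    effect_tbv: float = 0.0
    effect_site: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        if len(self.site_labels) != len(self.site_probs):
            raise ValueError("site_labels and site_probs must align")
        if abs(sum(self.site_probs) - 1.0) > 1e-9:
            raise ValueError("site_probs must sum to 1")
        if self.tbv_sd < 0:
            raise ValueError("tbv_sd must be >= 0")
        unknown = set(self.effect_site) - set(self.site_labels)
        if unknown:
            raise ValueError(f"effect_site refers to unknown sites {sorted(unknown)}")


def _site_effect_moments(spec: CohortSpec):
    eff = np.array([spec.effect_site.get(s, 0.0) for s in spec.site_labels])
    p = np.asarray(spec.site_probs, dtype=float)
    mean = float(eff @ p)
    var = float(((eff - mean) ** 2) @ p)
    return eff, mean, var


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table. Identical seeds give identical tables."""
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    site_eff, site_mean, site_var = _site_effect_moments(spec)
    rows = []
    sid = 0
    for g in spec.groups:
        # Residual variance after removing the covariate-effect variance so the
        # marginal group sd matches the specification.
        fx_var = (spec.effect_age**2 * g.age_sd**2
                  + spec.effect_male**2 * g.male_fraction * (1 - g.male_fraction)
                  + spec.effect_tbv**2 * spec.tbv_sd**2
                  + site_var)
        resid_sd = np.sqrt(max(g.volume_sd**2 - fx_var, 0.0))
        for _ in range(g.n):
            age = rng.normal(g.age_mean, g.age_sd)
            male = rng.random() < g.male_fraction
            site_idx = rng.choice(len(spec.site_labels), p=spec.site_probs)
            tbv = rng.normal(spec.tbv_mean, spec.tbv_sd)
            vol = (g.volume_mean
                   + spec.effect_age * (age - g.age_mean)
                   + spec.effect_male * (float(male) - g.male_fraction)
                   + spec.effect_tbv * (tbv - spec.tbv_mean)
                   + (site_eff[site_idx] - site_mean)
                   + (rng.normal(0.0, resid_sd) if resid_sd > 0 else 0.0))
            row = {
                "subject_id": f"S{sid:05d}",
                "group": g.label,
                "age": age,
                "sex": "M" if male else "F",
                "site": spec.site_labels[site_idx],
                "total_brain_volume": tbv,
                "snc_volume": max(vol, 0.0),
            }
            for name in CLINICAL_VARS:
                if name in g.clinical:
                    mean, sd = g.clinical[name]
                    row[name] = rng.normal(mean, sd) if sd > 0 else float(mean)
                else:
                    row[name] = np.nan
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)


def pathology_cohort_spec(rng_seed: int = 0) -> CohortSpec:
    """Five-group control / prodromal / PD cohort (n = 50/217/76/194/26)."""
    groups = [
        GroupSpec("control", 50, 395.2, 117.0, age_mean=62.4, age_sd=11.9,
                  male_fraction=31 / 50,
                  clinical={"mds_updrs3": (1.7, 2.1), "moca": (27.7, 2.0),
                            "upsit": (34.6, 4.1), "education": (16.9, 3.4),
                            "disease_duration": (0.0, 0.0),
                            "levodopa_equivalents": (0.0, 0.0)}),
        GroupSpec("hyposmia", 217, 332.1, 100.7, age_mean=68.5, age_sd=5.7,
                  male_fraction=81 / 217,
                  clinical={"mds_updrs3": (5.1, 5.4), "moca": (26.8, 2.1),
                            "upsit": (23.2, 7.4), "education": (16.8, 2.8),
                            "disease_duration": (0.0, 0.0),
                            "levodopa_equivalents": (0.0, 0.0)}),
        GroupSpec("RBD", 76, 336.0, 96.6, age_mean=67.5, age_sd=5.4,
                  male_fraction=57 / 76,
                  clinical={"mds_updrs3": (4.1, 4.0), "moca": (26.5, 2.7),
                            "upsit": (23.6, 7.8), "education": (16.8, 2.8),
                            "disease_duration": (0.0, 0.0),
                            "levodopa_equivalents": (0.0, 0.0)}),
        GroupSpec("de-novo-PD", 194, 309.4, 100.0, age_mean=63.0, age_sd=10.0,
                  male_fraction=122 / 194,
                  clinical={"mds_updrs3": (23.2, 9.7), "moca": (27.2, 2.3),
                            "upsit": (23.7, 7.7), "education": (16.8, 3.2),
                            "disease_duration": (1.0, 0.9),
                            "levodopa_equivalents": (12.4, 67.9)}),
        GroupSpec("moderate-PD", 26, 291.2, 118.3, age_mean=68.0, age_sd=7.6,
                  male_fraction=14 / 26,
                  clinical={"mds_updrs3": (28.9, 11.9), "moca": (26.1, 2.9),
                            "education": (16.3, 3.6),
                            "disease_duration": (6.7, 2.1),
                            "levodopa_equivalents": (698.3, 454.1)}),
    ]
    return CohortSpec(groups=groups, rng_seed=rng_seed)


def nmc_cohort_spec(rng_seed: int = 0) -> CohortSpec:
    """Control vs non-manifest LRRK2/GBA1 carrier cohort (n = 50/46/44)."""
    groups = [
        GroupSpec("control", 50, 395.2, 117.0, age_mean=62.4, age_sd=11.9,
                  male_fraction=31 / 50,
                  clinical={"mds_updrs3": (1.7, 2.1), "moca": (27.7, 2.0),
                            "education": (17.2, 3.5)}),
        GroupSpec("NMC-LRRK2", 46, 381.0, 102.0, age_mean=65.3, age_sd=6.8,
                  male_fraction=19 / 46,
                  clinical={"mds_updrs3": (2.0, 2.5), "moca": (28.0, 1.6),
                            "education": (17.5, 2.3)}),
        GroupSpec("NMC-GBA1", 44, 379.0, 83.0, age_mean=64.8, age_sd=6.0,
                  male_fraction=19 / 44,
                  clinical={"mds_updrs3": (2.5, 2.4), "moca": (27.5, 2.1),
                            "education": (18.4, 2.5)}),
    ]
    return CohortSpec(groups=groups, rng_seed=rng_seed)
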