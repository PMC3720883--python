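"""Synthetic cohort generator.

Emulates the second-order structure a metabolic covariance analysis assumes
in regional FDG-PET uptake: strong correlation between left/right homologous
regions, block correlation within lobes, weak background correlation
elsewhere, group-specific mean reductions (hypometabolism) in configurable
region sets, and linear covariate effects (age, sex, age x sex, regional
volume) that the preprocessing stage is expected to regress out.

Subjects are drawn from a multivariate normal whose correlation matrix is
assembled from those blocks and repaired to be positive semi-definite by
eigenvalue clipping.  The generator does not simulate PET physics,
partial-volume effects, or longitudinal drift.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .atlas import GROUPS, CohortTable, RegionAtlas

log = logging.getLogger(__name__)

#: Region sets with planted group hypometabolism (fractional mean reduction).
#: The AD set follows the canonical temporo-parietal / posterior-cingulate /
#: occipital-associative pattern; MCI gets a milder subset of it.
DEFAULT_HYPOMETABOLIC: dict[str, tuple[tuple[str, ...], float]] = {
    "AD": (
        (
            "HIP.L", "HIP.R", "PHG.L", "PHG.R", "PCG.L", "PCG.R",
            "ANG.L", "ANG.R", "ITG.L", "ITG.R", "MTG.L", "MTG.R",
            "CUN.L", "MOG.L", "FFG.L",
        ),
        0.15,
    ),
    "MCI": (
        ("PCG.L", "PCG.R", "PHG.L", "PHG.R", "ITG.L", "ITG.R"),
        0.07,
    ),
}


@dataclass
class CovariateEffects:
    """Linear coefficients of the planted confounds, in uptake units.

    ``age`` is per year of centered age, ``sex`` the female-male offset,
    ``age_sex`` per year of the centered-age x sex interaction, ``volume``
    per standardized unit of log regional volume.
    """

    age: float = -0.003
    sex: float = 0.03
    age_sex: float = 0.0015
    volume: float = 0.02


@dataclass
class CohortSpec:
    """Generator configuration; the defaults define the simulated study.

    Group sizes default to the 69/62/68 AD/MCI/NC split of a typical
    single-site FDG-PET cohort.  Correlation targets (homologous 0.7,
    within-lobe 0.4, background 0.1) reproduce the dominant empirical
    pattern: the strongest covariations sit between homologous pairs.
    """

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"NC": 68, "MCI": 62, "AD": 69}
    )
    seed: int = 0
    base_mean: float = 1.2
    homologous_r: float = 0.7
    lobe_block_r: float = 0.4
    background_r: float = 0.1
    noise_sd: float = 0.1
    hypometabolic_regions: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: dict(DEFAULT_HYPOMETABOLIC)
    )
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    #: optional (region_a, region_b, r) entries overriding the block pattern,
    #: optionally per group: {group: [...]} or a flat list applied to all.
    extra_edges: dict[str, list[tuple[str, str, float]]] | list[tuple[str, str, float]] = field(
        default_factory=list
    )
    #: per-group overrides of the three block correlations, e.g.
    #: {"AD": {"lobe_block_r": 0.25}}
    group_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for g, n in self.n_subjects.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 4:
                raise ValueError(
                    f"n_subjects[{g!r}] = {n} < 4: correlations downstream degenerate"
                )
        for name in ("homologous_r", "lobe_block_r", "background_r"):
            v = getattr(self, name)
            if not abs(v) < 1:
                raise ValueError(f"{name} = {v} must satisfy |r| < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g, (regions, frac) in self.hypometabolic_regions.items():
            if not 0 <= frac < 1:
                raise ValueError(f"reduction for {g!r} must be in [0, 1)")

    def extra_edges_for(self, group: str) -> list[tuple[str, str, float]]:
        if isinstance(self.extra_edges, dict):
            return list(self.extra_edges.get(group, []))
        return list(self.extra_edges)

    def block_params(self, group: str) -> tuple[float, float, float]:
        ov = self.group_overrides.get(group, {})
        return (
            ov.get("homologous_r", self.homologous_r),
            ov.get("lobe_block_r", self.lobe_block_r),
            ov.get("background_r", self.background_r),
        )


def build_covariance(
    spec: CohortSpec, atlas: RegionAtlas, group: str | None = None
) -> np.ndarray:
    """Assemble the N x N covariance implied by the spec's block targets.

    Off-diagonal structure: background everywhere, within-lobe blocks on
    top, homologous pairs on top of that, explicit extra edges last.  The
    result is repaired to PSD by clipping negative eigenvalues at zero and
    rescaling the diagonal back to ``noise_sd**2``; a repair beyond
    tolerance (entries moved by more than 0.05) raises.
    """
    spec.validate()
    N = atlas.n
    hom_r, lobe_r, bg_r = spec.block_params(group) if group else (
        spec.homologous_r,
        spec.lobe_block_r,
        spec.background_r,
    )
    R = np.full((N, N), bg_r)
    lobes = atlas.lobe_labels
    same_lobe = lobes[:, None] == lobes[None, :]
    R[same_lobe] = lobe_r
    for i, j in atlas.homologous_pairs():
        R[i, j] = R[j, i] = hom_r
    for a, b, r in spec.extra_edges_for(group) if group else (
        spec.extra_edges if isinstance(spec.extra_edges, list) else []
    ):
        if not abs(r) < 1:
            raise ValueError(f"extra edge ({a}, {b}) target |r| must be < 1")
        i, j = atlas.index_of(a), atlas.index_of(b)
        R[i, j] = R[j, i] = r
    np.fill_diagonal(R, 1.0)

    w, V = np.linalg.eigh(R)
    if w.min() < -1e-10:
        log.info("covariance repair: clipping min eigenvalue %.3e at zero", w.min())
        R_psd = (V * np.clip(w, 0, None)) @ V.T
        d = np.sqrt(np.diag(R_psd))
        R_psd = R_psd / np.outer(d, d)
        if np.abs(R_psd - R).max() > 0.05:
            raise ValueError(
                "covariance repair moved correlations beyond tolerance; "
                "requested block structure is too far from PSD"
            )
        R = R_psd
    return spec.noise_sd**2 * R


def _group_rng(seed: int, group: str) -> np.random.Generator:
    # independent stream per (seed, group): adding a group never perturbs others
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(group.encode())])
    )


def generate_cohort(spec: CohortSpec, atlas: RegionAtlas) -> CohortTable:
    """Draw a multi-group cohort from the spec.

    Per group: latent uptake ~ MVN(mean vector, block covariance) where the
    mean is the baseline minus the planted hypometabolic reduction; linear
    covariate effects are added on top; the emitted raw uptake is the
    structured value multiplied by the subject's (positive) brainstem
    reference so that reference normalization recovers the structure.
    """
    spec.validate()
    N = atlas.n
    eff = spec.covariate_effects
    parts: list[dict] = []
    for g in GROUPS:
        if g not in spec.n_subjects:
            continue
        n = spec.n_subjects[g]
        rng = _group_rng(spec.seed, g)
        cov = build_covariance(spec, atlas, group=g)
        mean = np.full(N, spec.base_mean)
        if g in spec.hypometabolic_regions:
            regions, frac = spec.hypometabolic_regions[g]
            mean[atlas.indices_of(regions)] *= 1.0 - frac

        age = rng.uniform(55, 90, n)
        sex = rng.integers(0, 2, n)  # 0 = M, 1 = F
        education = np.clip(rng.normal(15, 3, n), 6, 22)
        volumes = rng.lognormal(mean=np.log(8000.0), sigma=0.15, size=(n, N))
        latent = rng.multivariate_normal(mean, cov, size=n, method="eigh")

        age_c = age - 72.5
        log_vol = np.log(volumes)
        vol_std = (log_vol - np.log(8000.0)) / 0.15
        structured = (
            latent
            + (eff.age * age_c + eff.sex * sex + eff.age_sex * age_c * sex)[:, None]
            + eff.volume * vol_std
        )
        reference = np.clip(rng.normal(1.0, 0.03, n), 0.8, None)
        parts.append(
            dict(
                ids=[f"{g}{k:03d}" for k in range(n)],
                group=np.full(n, g, dtype=object),
                age=age,
                sex=np.where(sex == 1, "F", "M"),
                education=education,
                cmrgl=structured * reference[:, None],
                volumes=volumes,
                reference=reference,
            )
        )
    if not parts:
        raise ValueError("spec defines no groups")
    return CohortTable(
        atlas=atlas,
        subject_ids=[s for p in parts for s in p["ids"]],
        group=np.concatenate([p["group"] for p in parts]),
        age=np.concatenate([p["age"] for p in parts]),
        sex=np.concatenate([p["sex"] for p in parts]),
        education=np.concatenate([p["education"] for p in parts]),
        cmrgl=np.vstack([p["cmrgl"] for p in parts]),
        volumes=np.vstack([p["volumes"] for p in parts]),
        reference_value=np.concatenate([p["reference"] for p in parts]),
    )
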