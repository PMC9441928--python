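"""Synthetic multi-environment phenotype data with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: several experiments with contrasting drought effect sizes,
positively intercorrelated root anatomical traits (Gaussian copula),
genotype + treatment + G×T variance components, latent genotype archetypes
(integrated-phenotype-like trait profiles), and power-law scaling links with
configurable exponents.  Truth records (archetype labels, generating
parameters) are written alongside but are never read by any analysis stage —
only by tests.

Every draw flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so output tables are byte-identical
across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AllometricLink",
    "Archetype",
    "ExperimentConfig",
    "TraitModel",
    "SyntheticConfig",
    "default_config",
    "archetype_recovery_config",
    "generate_dataset",
    "generate_allometric_pair",
]


@dataclass(frozen=True)
class AllometricLink:
    """Power-law link y = y_mean · (x/x_mean)^alpha · e^ε, ε ~ N(0, sd²)."""

    y_trait: str
    x_trait: str
    alpha: float
    log_noise_sd: float
    y_mean: float
    #: log-units applied per z-unit of an archetype profile offset on y
    offset_scale: float = 0.3


@dataclass(frozen=True)
class Archetype:
    """A latent genotype class: per-trait offsets in z-units and a mixing weight.

    ``drought_tolerance`` exponentiates the experiment's biomass drought
    multiplier for genotypes of this archetype (effective multiplier
    m^tolerance): below 1 the class loses less biomass than the experiment
    average, above 1 more.  This is what makes performance groups and
    cluster biomass rankings differ under drought while well-watered biomass
    stays archetype-comparable.
    """

    label: str
    profile: dict[str, float]
    weight: float
    drought_tolerance: float = 1.0


@dataclass(frozen=True)
class ExperimentConfig:
    """One trial: its size, drought effect multipliers and G×T noise.

    ``treatment_effect`` maps trait → multiplicative drought effect
    (drought value = multiplier × well-watered value); traits not listed are
    unaffected.  ``depth_proxy`` selects which rooting-depth measurement the
    experiment records (maximum depth, emergence angle, or deep-root length
    proportion), mirroring how different facilities measure depth.
    """

    name: str
    n_genotypes: int
    n_reps: int
    treatment_effect: dict[str, float] = field(default_factory=dict)
    gxt_sd: float = 0.1
    depth_proxy: str = "root_depth"


def _default_correlation(traits: list[str]) -> pd.DataFrame:
    """Positive anatomical intercorrelation, weaker root–shoot coupling."""
    anatomical = ["RXSA", "TSA", "percAA", "MXA", "MXV"]
    corr = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            if a in anatomical and b in anatomical:
                r = 0.2 if "percAA" in (a, b) else 0.5
            else:
                r = 0.15
            corr.loc[a, b] = corr.loc[b, a] = r
    return corr


@dataclass
class TraitModel:
    """Marginal scales, copula correlation and power-law links of the traits.

    Continuous traits are lognormal (``log_means``/``log_sds`` on the
    natural-log scale); percentage traits pass through a scaled logistic so
    they stay in [0, 100]; count traits are rounded at the end.
    """

    log_means: dict[str, float]
    log_sds: dict[str, float]
    #: percent-trait name → (center %, logistic slope per z-unit)
    percent_traits: dict[str, tuple[float, float]]
    count_traits: frozenset[str]
    correlation: pd.DataFrame
    links: list[AllometricLink] = field(default_factory=list)
    cortical_fraction: float = 0.85

    @property
    def copula_traits(self) -> list[str]:
        return list(self.correlation.index)

    def cholesky(self) -> np.ndarray:
        C = self.correlation.to_numpy(dtype=float)
        if not np.allclose(C, C.T):
            raise ValueError("correlation matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(C)
        if eigvals.min() < -1e-10:
            clipped = np.linalg.eigh(C)
            V, w = clipped.eigenvectors, np.clip(clipped.eigenvalues, 0, None)
            nearest = V @ np.diag(w) @ V.T
            d = np.sqrt(np.diag(nearest))
            nearest = nearest / np.outer(d, d)
            raise ValueError(
                "correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g}); nearest PSD correlation:\n{nearest}"
            )
        # small jitter handles exactly-singular PSD matrices
        return np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))


def _default_trait_model() -> TraitModel:
    traits = ["RXSA", "TSA", "percAA", "MXA", "MXV", "root_depth", "biomass", "tillers"]
    return TraitModel(
        log_means={
            "RXSA": math.log(0.8),       # mm^2
            "TSA": math.log(0.12),       # mm^2
            "MXA": math.log(0.0025),     # mm^2
            "MXV": math.log(5.0),
            "root_depth": math.log(60.0),  # cm
            "biomass": math.log(3.0),    # g
            "tillers": math.log(10.0),
        },
        log_sds={
            "RXSA": 0.25, "TSA": 0.25, "MXA": 0.30, "MXV": 0.25,
            "root_depth": 0.20, "biomass": 0.35, "tillers": 0.25,
        },
        percent_traits={"percAA": (20.0, 0.8)},
        count_traits=frozenset({"MXV", "tillers", "nodal_root_number"}),
        correlation=_default_correlation(traits),
        links=[AllometricLink("nodal_root_number", "biomass", alpha=0.9,
                              log_noise_sd=0.12, y_mean=120.0)],
    )


#: archetype trait profiles paraphrasing the recurring integrated phenotypes:
#: IP1 — many deep roots, large cross-section, abundant aerenchyma;
#: IP2 — many deep roots, small cross-section and small metaxylem;
#: IP5 — few shallow roots, small everything.
_DEFAULT_ARCHETYPES = (
    Archetype("IP1", {"nodal_root_number": 1.2, "root_depth": 1.2, "RXSA": 1.2,
                      "percAA": 1.0, "TSA": 0.8, "MXA": 0.8, "MXV": 0.5},
              0.35, drought_tolerance=0.55),
    Archetype("IP2", {"nodal_root_number": 1.2, "root_depth": 1.2, "RXSA": -1.2,
                      "percAA": 0.2, "TSA": -0.8, "MXA": -1.2, "MXV": -0.8},
              0.35, drought_tolerance=0.60),
    Archetype("IP5", {"nodal_root_number": -1.2, "root_depth": -1.2, "RXSA": -0.8,
                      "percAA": -0.8, "TSA": -0.6, "MXA": -0.6, "MXV": -0.5},
              0.30, drought_tolerance=2.0),
)


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic multi-environment study."""

    experiments: list[ExperimentConfig]
    archetypes: list[Archetype]
    trait_model: TraitModel
    seed: int = 0
    genotype_sd: float = 0.5   # z-units of genotype scatter around its archetype
    rep_sd: float = 0.3        # z-units of replicate (within-plot) noise
    round_counts: bool = True

    def validate(self) -> None:
        w = sum(a.weight for a in self.archetypes)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"archetype weights must sum to 1 (got {w})")
        if self.genotype_sd < 0 or self.rep_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        for e in self.experiments:
            if e.gxt_sd < 0:
                raise ValueError("gxt_sd must be nonnegative")
        self.trait_model.cholesky()  # raises on non-PSD


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default four-experiment study.

    Two greenhouse trials (14 and 32 genotypes, 4 replicates) and two
    rainout-shelter trials (14 genotypes × 4 reps; 140 genotypes × 3 reps)
    with contrasting drought severities: shoot biomass multipliers 0.30,
    0.50, 0.52 and 0.65 (70, 50, 48 and 35% reductions) and nodal-root
    multipliers from 0.16 (84% reduction) to 0.51 (49%).  One rainout
    experiment records root angle and the other deep-root length proportion
    instead of maximum root depth.
    """
    common = dict(RXSA=0.85, TSA=0.95, percAA=1.05, MXA=0.90, MXV=0.95)
    experiments = [
        ExperimentConfig("GH-A", 14, 4, {**common, "biomass": 0.30, "tillers": 0.70,
                                         "nodal_root_number": 0.16, "root_depth": 0.90}),
        ExperimentConfig("ROS-B", 14, 4, {"biomass": 0.50, "tillers": 0.53,
                                          "nodal_root_number": 0.35, "root_depth": 0.95,
                                          "TSA": 1.10, "MXA": 1.15, "percAA": 1.05},
                         depth_proxy="deep_root_prop"),
        ExperimentConfig("GH-C", 32, 4, {**common, "biomass": 0.52, "tillers": 0.65,
                                         "nodal_root_number": 0.30, "root_depth": 0.90}),
        ExperimentConfig("ROS-D", 140, 3, {"biomass": 0.65, "tillers": 0.90,
                                           "nodal_root_number": 0.51, "root_depth": 0.95,
                                           "RXSA": 1.05, "TSA": 1.20, "MXA": 1.20, "percAA": 0.90},
                         gxt_sd=0.15, depth_proxy="root_angle"),
    ]
    return SyntheticConfig(experiments=experiments, archetypes=list(_DEFAULT_ARCHETYPES),
                           trait_model=_default_trait_model(), seed=seed)


def archetype_recovery_config(
    n_archetypes: int,
    separation: float = 3.0,
    n_genotypes: int = 40,
    n_reps: int = 3,
    seed: int = 0,
    genotype_sd: float = 0.5,
    rep_sd: float = 0.3,
) -> SyntheticConfig:
    """A single-experiment config with well-separated latent archetypes.

    Archetype i is offset by ``separation`` z-units on its own block of
    clustering traits, giving pairwise profile separation ≥ separation.
    Used by cluster-recovery tests with truth labels.
    """
    model = _default_trait_model()
    blocks = [["RXSA", "TSA"], ["MXA", "MXV"], ["percAA", "root_depth"]]
    if n_archetypes > len(blocks):
        raise ValueError(f"at most {len(blocks)} archetypes supported here")
    archetypes = []
    for i in range(n_archetypes):
        profile = {t: separation for t in blocks[i]}
        archetypes.append(Archetype(f"A{i + 1}", profile, 1.0 / n_archetypes))
    exp = ExperimentConfig("SIM", n_genotypes, n_reps,
                           {"biomass": 0.5, "nodal_root_number": 0.4}, gxt_sd=0.05)
    return SyntheticConfig(experiments=[exp], archetypes=archetypes, trait_model=model,
                           seed=seed, genotype_sd=genotype_sd, rep_sd=rep_sd)


def _logistic_percent(center: float, slope: float, z: np.ndarray) -> np.ndarray:
    a = math.log(center / (100.0 - center))
    return 100.0 / (1.0 + np.exp(-(a + slope * z)))


def generate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the plant-level phenotype table and its truth record.

    Per plant: the genotype's archetype fixes a latent trait profile;
    correlated z-scores are drawn around it (genotype scatter plus replicate
    noise through the copula Cholesky factor); continuous traits
    back-transform through lognormal marginals and percentages through a
    scaled logistic; drought plants get per-trait multiplicative effects and
    lognormal G×T noise; linked traits follow their power laws.  Cortical
    area is built as a fixed fraction of non-stele area and aerenchyma as
    percAA × TCA / 100, so RXSA ≥ AA + MXA and 0 ≤ percAA ≤ 100 hold by
    construction.

    Returns ``(table, truth)``: the tidy table of primary measurements and a
    per-genotype truth frame with archetype labels.
    """
    config.validate()
    model = config.trait_model
    traits = model.copula_traits
    L = model.cholesky()
    p = len(traits)
    weights = np.array([a.weight for a in config.archetypes])

    seqs = np.random.SeedSequence(config.seed).spawn(len(config.experiments))
    tables, truths = [], []
    for exp, seq in zip(config.experiments, seqs):
        rng = np.random.default_rng(seq)
        ng, nr = exp.n_genotypes, exp.n_reps
        genotypes = [f"g{i + 1:03d}" for i in range(ng)]
        arch_idx = rng.choice(len(config.archetypes), size=ng, p=weights)

        profile_mat = np.zeros((ng, p))
        link_offsets = {lk.y_trait: np.zeros(ng) for lk in model.links}
        for gi, ai in enumerate(arch_idx):
            prof = config.archetypes[ai].profile
            for ti, t in enumerate(traits):
                profile_mat[gi, ti] = prof.get(t, 0.0)
            for lk in model.links:
                link_offsets[lk.y_trait][gi] = prof.get(lk.y_trait, 0.0)

        z_geno = profile_mat + config.genotype_sd * (rng.standard_normal((ng, p)) @ L.T)
        tolerance = np.array([config.archetypes[ai].drought_tolerance for ai in arch_idx])
        gxt = {
            t: np.exp(exp.gxt_sd * rng.standard_normal(ng)) if exp.gxt_sd > 0 else np.ones(ng)
            for t in traits + [lk.y_trait for lk in model.links]
        }

        rows = []
        for trt in ("WW", "D"):
            for r in range(nr):
                z = z_geno + config.rep_sd * (rng.standard_normal((ng, p)) @ L.T)
                base = {}
                for ti, t in enumerate(traits):
                    if t in model.percent_traits:
                        center, slope = model.percent_traits[t]
                        base[t] = _logistic_percent(center, slope, z[:, ti])
                    else:
                        base[t] = np.exp(model.log_means[t] + model.log_sds[t] * z[:, ti])
                # power-law links from the pre-multiplier driver values
                link_noise = {}
                for lk in model.links:
                    eps = (lk.log_noise_sd * rng.standard_normal(ng)
                           if lk.log_noise_sd > 0 else np.zeros(ng))
                    x_mean = math.exp(model.log_means[lk.x_trait])
                    base[lk.y_trait] = lk.y_mean * (base[lk.x_trait] / x_mean) ** lk.alpha \
                        * np.exp(lk.offset_scale * link_offsets[lk.y_trait] + eps)
                    link_noise[lk.y_trait] = eps

                values = {}
                for t, v in base.items():
                    if trt == "D":
                        mult = exp.treatment_effect.get(t, 1.0)
                        mult = mult**tolerance if t == "biomass" else mult
                        v = v * mult * gxt[t]
                    values[t] = v
                if "percAA" in values:
                    values["percAA"] = np.clip(values["percAA"], 0.0, 100.0)

                # structural areas, consistent by construction
                tsa = np.minimum(values["TSA"], 0.6 * values["RXSA"])
                tca = model.cortical_fraction * (values["RXSA"] - tsa)
                aa = values["percAA"] / 100.0 * tca
                mxa = np.minimum(values["MXA"], 0.5 * (values["RXSA"] - aa))
                values["TSA"], values["TCA"], values["AA"], values["MXA"] = tsa, tca, aa, mxa
                del values["percAA"]  # derived downstream as AA/TCA*100

                # depth proxy: the experiment records depth, angle, or deep fraction
                if exp.depth_proxy != "root_depth":
                    z_depth = (np.log(values["root_depth"]) - model.log_means["root_depth"]) \
                        / model.log_sds["root_depth"]
                    if exp.depth_proxy == "root_angle":
                        values["root_angle"] = np.clip(50.0 + 15.0 * z_depth, 8.0, 90.0)
                    elif exp.depth_proxy == "deep_root_prop":
                        values["deep_root_prop"] = 1.0 / (1.0 + np.exp(-(-1.6 + 0.8 * z_depth)))
                    else:
                        raise ValueError(f"unknown depth proxy {exp.depth_proxy!r}")
                    del values["root_depth"]

                if config.round_counts:
                    for t in model.count_traits:
                        if t in values:
                            values[t] = np.maximum(np.round(values[t]), 0.0)

                frame = pd.DataFrame(values)
                frame.insert(0, "experiment", exp.name)
                frame.insert(1, "genotype", genotypes)
                frame.insert(2, "treatment", trt)
                frame.insert(3, "replicate", f"r{r + 1}")
                rows.append(frame)
        tables.append(pd.concat(rows, ignore_index=True))
        truths.append(pd.DataFrame({
            "experiment": exp.name,
            "genotype": genotypes,
            "archetype": [config.archetypes[ai].label for ai in arch_idx],
        }))

    table = pd.concat(tables, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return table, truth


def generate_allometric_pair(
    alpha: float,
    intercept: float = 0.0,
    n: int = 60,
    log_noise_sd: float = 0.1,
    seed: int = 0,
    x_range: tuple[float, float] = (0.5, 10.0),
    log_base: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw (x, y) from an exact power law with lognormal scatter.

    x is log-uniform over ``x_range``; log_b(y) = intercept + alpha·log_b(x)
    + ε with ε ~ N(0, sd²) in the given log base.  Returns the pair and a
    truth dict with the generating parameters.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    lo, hi = math.log(x_range[0]), math.log(x_range[1])
    x = np.exp(rng.uniform(lo, hi, size=n))
    lb = math.log(log_base)
    log_x = np.log(x) / lb
    eps = log_noise_sd * rng.standard_normal(n) if log_noise_sd > 0 else np.zeros(n)
    log_y = intercept + alpha * log_x + eps
    y = np.power(log_base, log_y)
    return x, y, dict(alpha=alpha, intercept=intercept, log_noise_sd=log_noise_sd,
                      n=n, seed=seed, log_base=log_base)
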