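"""Synthetic dairy-herd generator for feed-efficiency evaluation.

Real feed-intake datasets of this kind (research herds with weekly dry-matter
intake, milk composition, body weight and condition scores, plus a genotyped
nucleus pedigree) are proprietary, so the generator emulates one: by default
~790 recorded primiparous cows with 28 weekly records each across 4 herds and
~24 production years, a shallow selected pedigree, a genotyped subset, and the
effect structure every downstream model assumes:

* energy sinks (ECM, MBW, latent daily BW change, BCS) are drawn around
  realistic herd means with lactation-stage curves expressed in the Legendre
  basis and herd-year (HPY), test-group (HTM), permanent-environment, additive
  genetic and residual components;
* BW loss and gain are the sign split of the latent BW change, so one of the
  two is structurally zero in every record;
* DMI is built as eDMI(sinks) × (α_HPY + β_HTM + pe_i + a_i) + e, i.e. the
  regression-on-expected-intake structure holds by construction, with the
  efficiency components on the regression-slope scale;
* MEI = DMI × dietary energy density (10.94 MJ ME/kg DM by default);
* genotypes are gene-dropped through the pedigree from Hardy–Weinberg
  founders, so genomic and pedigree relationships agree in expectation.

True breeding values and generating parameters are retained for
parameter-recovery and validation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .components import VarianceComponents
from .genomic import GenotypeMatrix
from .metrics import DEFAULT_ENERGY_DENSITY, derive_columns, edmi_rdc
from .model import legendre_basis
from .pedigree import Pedigree


class SimulationError(ValueError):
    pass


SINKS = ("ecm", "mbw", "dbw", "bcs")

#: generating efficiency variance components, regression-slope scale
DEFAULT_EFFICIENCY_VC = {
    "htm": 4.0e-4,
    "pe": 0.00333,
    "animal": 0.00303,
    "residual_weighted": 2.502,
    "residual_pattern": (1.20, 1.10, 1.05, 0.92, 0.85),
}

DEFAULT_SINK_MEANS = {"dmi": 19.4, "ecm": 29.0, "mbw": 119.7, "bwl": 0.35, "bwg": 0.35, "bcs": 3.17}

#: lactation-stage mean curves, coefficients on plain Legendre P0..P4
DEFAULT_SINK_CURVES = {
    "ecm": (0.0, -2.5, -1.5, 0.8, 0.0),
    "mbw": (0.0, 3.0, 0.5, 0.0, 0.0),
    "dbw": (0.22, 0.50, -0.10, 0.0, 0.0),
    "bcs": (0.0, 0.22, 0.12, 0.0, 0.0),
}


def make_cov(sds, corr=None) -> np.ndarray:
    """Covariance matrix from standard deviations and a correlation matrix."""
    sds = np.asarray(sds, dtype=float)
    k = sds.shape[0]
    if corr is None:
        corr = np.eye(k)
    corr = np.asarray(corr, dtype=float)
    return corr * np.outer(sds, sds)


def _default_sink_covariances() -> dict:
    """Plausible 4×4 sink covariances (ECM, MBW, dBW, BCS) by effect level.

    These are the package's own defaults — no published values exist for this
    decomposition.  Marginal totals approximate observed phenotypic SDs
    (ECM ≈ 4.5 kg, MBW ≈ 9 kg^0.75, daily BW change ≈ 0.38 kg, BCS ≈ 0.33);
    the split is 25 % genetic, 20 % permanent environment, 5 % test group and
    50 % residual, with moderate correlations.
    """
    total_sd = np.array([4.46, 8.91, 0.38, 0.33])
    corr_g = np.array(
        [
            [1.00, 0.25, -0.30, -0.20],
            [0.25, 1.00, 0.10, 0.40],
            [-0.30, 0.10, 1.00, 0.30],
            [-0.20, 0.40, 0.30, 1.00],
        ]
    )
    corr_e = np.array(
        [
            [1.00, 0.10, -0.15, 0.05],
            [0.10, 1.00, 0.05, 0.10],
            [-0.15, 0.05, 1.00, 0.10],
            [0.05, 0.10, 0.10, 1.00],
        ]
    )
    return {
        "V_a": make_cov(total_sd * np.sqrt(0.25), corr_g),
        "P": make_cov(total_sd * np.sqrt(0.20), corr_g),
        "M": make_cov(total_sd * np.sqrt(0.05), corr_e),
        "R": make_cov(total_sd * np.sqrt(0.50), corr_e),
    }


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    The defaults are the emulated study conditions: a 264-founder nucleus
    pedigree with two descendant generations of three offspring per mating
    (≈790 recorded cows), 28 weekly records per cow in 4 herds across a
    24-year window, about half of the cows genotyped at 1,000 SNPs, and
    efficiency variance components on the regression-slope scale.
    """

    n_founders: int = 264
    n_generations: int = 2
    offspring_per_mating: int = 3
    n_snps: int = 1000
    maf_range: tuple = (0.05, 0.5)
    n_herds: int = 4
    n_years: int = 24
    weeks_per_cow: int = 28
    genotyped_fraction: float = 0.55
    base_year: int = 1995
    variance_components: dict = field(default_factory=lambda: dict(DEFAULT_EFFICIENCY_VC))
    sink_means: dict = field(default_factory=lambda: dict(DEFAULT_SINK_MEANS))
    sink_curves: dict = field(default_factory=lambda: dict(DEFAULT_SINK_CURVES))
    sink_covariances: dict = field(default_factory=_default_sink_covariances)
    sink_hpy_sd: tuple = (1.0, 2.0, 0.02, 0.05)
    alpha_sd: float = 0.05
    energy_density: float = DEFAULT_ENERGY_DENSITY
    pasture_gap: bool = False
    inbred_mendelian: bool = False
    week_range: tuple = (1, 44)
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2 or self.n_generations < 1 or self.offspring_per_mating < 1:
            raise SimulationError("invalid pedigree counts")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        if self.weeks_per_cow > 44:
            raise SimulationError("weeks_per_cow must not exceed 44 (305 days in milk)")
        for key, v in self.sink_covariances.items():
            v = np.asarray(v, dtype=float)
            if not np.allclose(v, v.T) or np.linalg.eigvalsh(v).min() < -1e-10:
                raise SimulationError(f"sink covariance {key!r} must be symmetric PSD")

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """A small, fast study (~190 cows × 10 weeks) for replicated checks."""
        defaults = dict(
            n_founders=64,
            n_generations=2,
            offspring_per_mating=3,
            n_snps=400,
            n_years=12,
            weeks_per_cow=10,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def residual_variances(self) -> np.ndarray:
        """Per-period residual variances scaled to the weighted-average target.

        Weights are the records a cow contributes to each period class given
        ``weeks_per_cow``; period classes without records keep the pattern
        value scaled by the same factor.
        """
        from .metrics import DEFAULT_PERIOD_BREAKS, lactation_period_class

        pattern = np.asarray(self.variance_components["residual_pattern"], dtype=float)
        target = float(self.variance_components["residual_weighted"])
        if target == 0.0:
            return np.zeros_like(pattern)
        weeks = np.arange(1, self.weeks_per_cow + 1)
        classes = lactation_period_class(weeks)
        weights = np.array([(classes == p).sum() for p in range(1, len(pattern) + 1)], float)
        avg = np.average(pattern, weights=np.maximum(weights, 1e-12))
        return pattern * (target / avg)

    def true_varcomp(self) -> VarianceComponents:
        """Generating efficiency components (slope scale) as a component set."""
        return VarianceComponents(
            random={
                "htm": float(self.variance_components["htm"]),
                "pe": float(self.variance_components["pe"]),
                "animal": float(self.variance_components["animal"]),
            },
            residual=self.residual_variances(),
        )


@dataclass
class SimulatedStudy:
    """A complete synthetic dataset plus the truth that generated it."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    records: pd.DataFrame
    true_breeding_values: pd.DataFrame
    true_parameters: VarianceComponents
    config: SimConfig
    sex: np.ndarray
    genotyped_ids: list

    @property
    def cows(self) -> list:
        return sorted(set(self.records["cow"]))


# ------------------------------------------------------------------ pedigree
def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None):
    """Generate a founder + descendant-generations pedigree.

    Females born in generation g−1 are the dams of generation g; sires are
    sampled (with replacement) from all earlier-born males.  Offspring sexes
    cycle female, male, female, … within a mating, so two thirds of offspring
    are female at the default three offspring per mating.  Birth years are
    monotone in generation.  Returns (Pedigree, sex array) with sex coded
    "F"/"M".
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[0])
    n0, G, opm = config.n_founders, config.n_generations, config.offspring_per_mating
    ids, sire, dam, byear, sex = [], [], [], [], []
    span = max((config.n_years - 2) // G, 1)
    for i in range(n0):
        ids.append(i + 1)
        sire.append(-1)
        dam.append(-1)
        byear.append(config.base_year + (i % 2))
        sex.append("M" if i % 2 == 0 else "F")
    males = [i for i in range(n0) if sex[i] == "M"]
    prev_females = [i for i in range(n0) if sex[i] == "F"]
    nxt = n0 + 1
    for g in range(1, G + 1):
        if not prev_females or not males:
            raise SimulationError("pedigree died out: need males and females each generation")
        y0 = config.base_year + 2 + (g - 1) * span
        new_females, new_males = [], []
        for d in prev_females:
            s = int(rng.choice(males))
            year = int(y0 + rng.integers(0, span))
            for k in range(opm):
                pos = len(ids)
                ids.append(nxt)
                nxt += 1
                sire.append(s)
                dam.append(d)
                byear.append(year)
                if k % 2 == 0:
                    sex.append("F")
                    new_females.append(pos)
                else:
                    sex.append("M")
                    new_males.append(pos)
        males = males + new_males
        prev_females = new_females
    order = np.lexsort((np.arange(len(ids)), np.asarray(byear)))
    # construction already yields parents-first ordering; birth years are
    # monotone by generation so the lexsort is stable w.r.t. construction
    remap = {old: new for new, old in enumerate(order)}
    ped = Pedigree(
        [ids[i] for i in order],
        np.array([remap[sire[i]] if sire[i] >= 0 else -1 for i in order]),
        np.array([remap[dam[i]] if dam[i] >= 0 else -1 for i in order]),
        np.array([byear[i] for i in order]),
        ["nucleus"] * len(ids),
    )
    return ped, np.array([sex[i] for i in order])


def gene_drop(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Drop founder alleles through the pedigree; returns 0/1/2 allele counts.

    Founder genotypes are Hardy–Weinberg draws at per-locus frequencies from
    ``maf_range``; every descendant receives one random allele from each
    parent per locus (no linkage).  An unknown parent contributes a fresh
    Hardy–Weinberg allele.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[1])
    n, L = len(pedigree), config.n_snps
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=L)
    hap = np.zeros((n, 2, L), dtype=np.int8)
    for i in range(n):
        for k, parent in enumerate((pedigree.sire[i], pedigree.dam[i])):
            if parent < 0:
                hap[i, k] = rng.random(L) < p
            else:
                pick = rng.integers(0, 2, size=L)
                hap[i, k] = hap[parent, pick, np.arange(L)]
    codes = hap.sum(axis=1).astype(np.int8)
    return GenotypeMatrix(list(pedigree.ids), codes)


def simulate_breeding_values(
    pedigree: Pedigree,
    V_a: np.ndarray,
    rng: np.random.Generator | None = None,
    trait_names=None,
    inbred: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Multivariate breeding values down a pedigree.

    Founders ~ N(0, V_a); descendants are the parent average plus a Mendelian
    sampling deviation with covariance d_i·V_a, where d_i = 1/2 by default (an
    unknown parent raises d_i to 3/4 or 1) and the inbreeding-adjusted
    d_i = 1/2 − (F_s + F_d)/4 behind ``inbred=True``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    V_a = np.atleast_2d(np.asarray(V_a, dtype=float))
    T = V_a.shape[0]
    evals, evecs = np.linalg.eigh(V_a)
    if evals.min() < -1e-10:
        raise SimulationError("genetic covariance must be PSD")
    Lchol = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0)))
    n = len(pedigree)
    d = pedigree.mendelian_variance_weights(inbred=inbred)
    z = rng.standard_normal((n, T)) @ Lchol.T
    u = np.zeros((n, T))
    for i in range(n):
        s, dd = pedigree.sire[i], pedigree.dam[i]
        pa = np.zeros(T)
        if s >= 0:
            pa += 0.5 * u[s]
        if dd >= 0:
            pa += 0.5 * u[dd]
        u[i] = pa + np.sqrt(d[i]) * z[i]
    if trait_names is None:
        trait_names = [f"trait{t}" for t in range(T)] if T > 1 else ["trait0"]
    return pd.DataFrame(u, index=pd.Index(pedigree.ids, name="animal"), columns=list(trait_names))


# ------------------------------------------------------------------- records
def simulate_records(
    pedigree: Pedigree,
    sex: np.ndarray,
    breeding_values: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Weekly lactation records for every non-founder female.

    See the module docstring for the generative structure.  Returns the full
    phenotype table with derived columns (ECM, MBW, BWL/BWG, both eDMI
    formulations, ECE, period class) already appended.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[3])
    var_htm = float(config.variance_components["htm"])
    var_pe = float(config.variance_components["pe"])
    res_var = config.residual_variances()
    cows_pos = [i for i in range(len(pedigree)) if sex[i] == "F" and pedigree.sire[i] >= 0]
    if not cows_pos:
        raise SimulationError("no recorded cows: pedigree has no non-founder females")
    n_cows = len(cows_pos)
    weeks = np.arange(1, config.weeks_per_cow + 1)
    W = weeks.shape[0]
    basis = legendre_basis(weeks, order=4, week_range=config.week_range)  # (W, 5)
    from .metrics import lactation_period_class

    period = lactation_period_class(weeks)

    curves = {s: basis @ np.asarray(config.sink_curves[s], dtype=float) for s in SINKS}
    cov = config.sink_covariances
    chol = {k: np.linalg.cholesky(np.asarray(v) + 1e-12 * np.eye(4)) for k, v in cov.items()}

    herd = rng.integers(1, config.n_herds + 1, size=n_cows)
    calving_month = rng.integers(1, 13, size=n_cows)

    u_sinks = breeding_values[list(SINKS)].to_numpy()
    u_eff = breeding_values["eff"].to_numpy()
    pe_sinks = rng.standard_normal((len(pedigree), 4)) @ chol["P"].T
    pe_eff = rng.normal(0.0, np.sqrt(var_pe), size=len(pedigree))

    # contemporary-group effects are drawn lazily per observed level
    hpy_alpha: dict = {}
    hpy_sink: dict = {}
    htm_beta: dict = {}
    htm_sink: dict = {}
    sink_hpy_sd = np.asarray(config.sink_hpy_sd, dtype=float)

    rows = []
    for c, pos in enumerate(cows_pos):
        animal = pedigree.ids[pos]
        byear = int(pedigree.birth_year[pos])
        prod_year = byear + 2
        h = int(herd[c])
        hpy = f"h{h}y{prod_year}"
        if hpy not in hpy_alpha:
            hpy_alpha[hpy] = 1.0 + rng.normal(0.0, config.alpha_sd)
            hpy_sink[hpy] = rng.normal(0.0, sink_hpy_sd)
        dim = 7 * weeks - 2
        month = ((calving_month[c] - 1) + dim // 30) % 12 + 1
        bimonth = (month - 1) // 2 + 1
        keep = np.ones(W, dtype=bool)
        if config.pasture_gap and calving_month[c] >= 9:
            keep = ~np.isin(month, (6, 7, 8))
        e_sink = rng.standard_normal((W, 4)) @ chol["R"].T
        e_dmi = rng.normal(0.0, np.sqrt(res_var[period - 1]))
        fat = 44.3 + rng.normal(0.0, 2.0, size=W)
        protein = 36.3 + rng.normal(0.0, 1.5, size=W)
        lactose = 45.0 + rng.normal(0.0, 1.0, size=W)
        for wi in range(W):
            if not keep[wi]:
                continue
            htm = f"h{h}t{prod_year}b{bimonth[wi]}"
            if htm not in htm_beta:
                htm_beta[htm] = rng.normal(0.0, np.sqrt(var_htm))
                htm_sink[htm] = rng.standard_normal(4) @ chol["M"].T
            sink = (
                np.array([config.sink_means["ecm"], config.sink_means["mbw"], 0.0, config.sink_means["bcs"]])
                + np.array([curves[s][wi] for s in SINKS])
                + hpy_sink[hpy]
                + htm_sink[htm]
                + pe_sinks[pos]
                + u_sinks[pos]
                + e_sink[wi]
            )
            ecm_v = max(sink[0], 1.0)
            mbw_v = max(sink[1], 60.0)
            dbw_v = sink[2]
            bcs_v = float(np.clip(sink[3], 1.0, 5.0))
            bwl_v, bwg_v = max(0.0, -dbw_v), max(0.0, dbw_v)
            edmi = edmi_rdc(ecm_v, mbw_v, bwl_v, bwg_v)
            slope = hpy_alpha[hpy] + htm_beta[htm] + pe_eff[pos] + u_eff[pos]
            dmi = slope * edmi + e_dmi[wi]
            denom = 38.30 * fat[wi] + 24.20 * protein[wi] + 16.54 * lactose[wi] + 20.7
            rows.append(
                {
                    "cow": animal,
                    "herd": h,
                    "birth_year": byear,
                    "production_year": prod_year,
                    "hpy": hpy,
                    "htm": htm,
                    "week": int(weeks[wi]),
                    "dim": int(dim[wi]),
                    "milk": ecm_v * 3140.0 / denom,
                    "fat": fat[wi],
                    "protein": protein[wi],
                    "lactose": lactose[wi],
                    "bw": mbw_v ** (4.0 / 3.0),
                    "delta_bw": dbw_v,
                    "bcs": bcs_v,
                    "dmi": dmi,
                    "mei": dmi * config.energy_density,
                }
            )
    records = pd.DataFrame(rows)
    return derive_columns(records, energy_density=config.energy_density)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a full study: pedigree, genotypes, records, truth.

    A single seed fans out into independent child streams for the pedigree,
    gene drop, breeding values, records and genotyping status, so each stage
    is reproducible on its own.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in seeds]
    ped, sex = simulate_pedigree(config, rngs[0])
    geno_all = gene_drop(ped, config, rngs[1])

    Va_sinks = np.asarray(config.sink_covariances["V_a"], dtype=float)
    V = np.zeros((5, 5))
    V[:4, :4] = Va_sinks
    V[4, 4] = float(config.variance_components["animal"])
    bvs = simulate_breeding_values(
        ped, V, rngs[2], trait_names=list(SINKS) + ["eff"], inbred=config.inbred_mendelian
    )
    records = simulate_records(ped, sex, bvs, config, rngs[3])

    # genotyped subset: founder males plus cows, late-born cows near-certainly
    rng = rngs[4]
    cow_ids = set(records["cow"])
    late = int(ped.birth_year.max()) - 2
    genotyped = []
    for i, a in enumerate(ped.ids):
        if sex[i] == "M" and ped.sire[i] < 0:
            genotyped.append(a)
        elif a in cow_ids:
            pr = 0.95 if ped.birth_year[i] >= late else config.genotyped_fraction
            if rng.random() < pr:
                genotyped.append(a)
    pos = ped.positions(genotyped)
    genotypes = GenotypeMatrix(genotyped, geno_all.codes[pos])

    return SimulatedStudy(
        pedigree=ped,
        genotypes=genotypes,
        records=records,
        true_breeding_values=bvs,
        true_parameters=config.true_varcomp(),
        config=config,
        sex=sex,
        genotyped_ids=genotyped,
    )
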