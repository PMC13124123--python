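"""Forward validation and metric comparison.

Implements the LR (linear-regression) forward-validation method: breeding
values predicted from the full dataset are regressed on those predicted from a
reduced dataset (validation animals' and their daughters' records removed) for
a group of young genotyped animals,

    EBV_full = b0 + b1 · EBV_reduced + ε,

where b0 estimates bias, b1 dispersion (1 = none) and the Pearson correlation
is the prediction accuracy (PAC).  Standard errors come from an ordinary
nonparametric bootstrap over validation animals.  The module also provides
adjusted benchmark-trait phenotypes (observations minus all fitted effects
except the additive genetic one, averaged per cow) and cross-metric
Pearson/Spearman GEBV correlation matrices, plus ``run_comparison`` — the full
multi-metric × kernel × dataset orchestration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .components import VarianceComponents, heritability, index_variances
from .indices import rfi_index, rzfe
from .model import FitResult, build_kernel_inverse, fit_metric
from .pedigree import Pedigree

METRIC_ORDER = ("refi_rdc", "refi_nrc2021", "rfi_index", "rzfe", "rfi", "ece")


class ValidationError(ValueError):
    pass


@dataclass
class ValidationGroup:
    """Young genotyped animals used for forward validation."""

    ids: list
    cutoff_birth_year: int
    n_daughters_removed: int = 0

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class LRResult:
    """Bias (b0), dispersion (b1) and prediction accuracy from LR validation."""

    b0: float
    b1: float
    corr: float
    n_validation: int
    se_b0: float | None = None
    se_b1: float | None = None
    se_corr: float | None = None
    bias_in_genetic_sd: float | None = None

    def as_dict(self) -> dict:
        return {
            "b0": self.b0,
            "b1": self.b1,
            "corr": self.corr,
            "se_b0": self.se_b0,
            "se_b1": self.se_b1,
            "se_corr": self.se_corr,
            "n": self.n_validation,
            "bias_in_genetic_sd": self.bias_in_genetic_sd,
        }


def split_forward(
    records: pd.DataFrame,
    pedigree: Pedigree,
    cutoff_birth_year: int,
    genotyped_ids,
) -> tuple[pd.DataFrame, pd.DataFrame, ValidationGroup]:
    """Forward split: full records, reduced records, validation group.

    The group contains genotyped animals born at or after the cutoff that have
    records; the reduced dataset removes their records and the records of
    their daughters, so no group member has information of its own in the
    reduced data.
    """
    genotyped = set(genotyped_ids)
    with_records = set(records["cow"])
    byear = {a: int(y) for a, y in zip(pedigree.ids, pedigree.birth_year)}
    group_ids = sorted(
        a for a in with_records if a in genotyped and byear.get(a, -(10**9)) >= cutoff_birth_year
    )
    if not group_ids:
        raise ValidationError(f"no genotyped animals with records born >= {cutoff_birth_year}")
    group_set = set(group_ids)
    daughters = set()
    for i, a in enumerate(pedigree.ids):
        s = pedigree.ids[pedigree.sire[i]] if pedigree.sire[i] >= 0 else None
        d = pedigree.ids[pedigree.dam[i]] if pedigree.dam[i] >= 0 else None
        if (s in group_set or d in group_set) and a in with_records:
            daughters.add(a)
    drop = group_set | daughters
    reduced = records[~records["cow"].isin(drop)].copy()
    if reduced.empty:
        raise ValidationError("reduced dataset is empty after removing validation records")
    group = ValidationGroup(group_ids, cutoff_birth_year, n_daughters_removed=len(daughters))
    return records, reduced, group


def lr_validation(
    ebv_full: pd.Series,
    ebv_reduced: pd.Series,
    group: ValidationGroup,
    var_g: float | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> LRResult:
    """Regress full-data EBVs on reduced-data EBVs over the validation group."""
    ids = list(group.ids)
    if len(ids) < 3:
        raise ValidationError("need at least 3 validation animals")
    missing = [a for a in ids if a not in ebv_full.index or a not in ebv_reduced.index]
    if missing:
        raise ValidationError(f"EBV tables do not cover validation animals {missing[:5]}")
    x = ebv_reduced.loc[ids].to_numpy(dtype=float)
    y = ebv_full.loc[ids].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValidationError("reduced-data EBVs have zero variance in the group")
    b1, b0 = np.polyfit(x, y, 1)
    corr = float(np.corrcoef(x, y)[0, 1])
    res = LRResult(float(b0), float(b1), corr, len(ids))
    if var_g is not None and var_g > 0:
        res.bias_in_genetic_sd = abs(res.b0) / float(np.sqrt(var_g))
    if n_boot:
        pairs = np.column_stack([x, y])
        res.se_b0 = bootstrap_se(pairs, "b0", n_boot, seed)
        res.se_b1 = bootstrap_se(pairs, "b1", n_boot, seed)
        res.se_corr = bootstrap_se(pairs, "corr", n_boot, seed)
    return res


_STATS = {
    "b0": lambda x, y: np.polyfit(x, y, 1)[1],
    "b1": lambda x, y: np.polyfit(x, y, 1)[0],
    "corr": lambda x, y: np.corrcoef(x, y)[0, 1],
    "pearson": lambda x, y: np.corrcoef(x, y)[0, 1],
    "spearman": lambda x, y: stats.spearmanr(x, y).statistic,
}


def bootstrap_se(pairs, statistic: str, n_boot: int = 1000, seed: int = 0) -> float:
    """Ordinary nonparametric bootstrap SE of an LR/correlation statistic.

    Animal pairs are resampled with replacement; resamples in which either
    column is constant (statistic undefined) are skipped.  Deterministic for a
    given seed.
    """
    if statistic not in _STATS:
        raise ValidationError(f"unknown statistic {statistic!r}; choose from {sorted(_STATS)}")
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100 for a usable SE")
    pairs = np.asarray(pairs, dtype=float)
    n = pairs.shape[0]
    fn = _STATS[statistic]
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        x, y = pairs[idx, 0], pairs[idx, 1]
        if np.var(x) == 0 or np.var(y) == 0:
            continue
        vals.append(fn(x, y))
    if not vals:
        return 0.0
    return float(np.std(vals, ddof=1))


def adjusted_phenotypes(fit: FitResult, data: pd.DataFrame, trait: str = "ece") -> pd.Series:
    """Per-cow phenotypes adjusted for every fitted effect except the genetic one.

    Subtracts the fitted contributions of all non-genetic terms from each
    observation and averages within cow — the yield-deviation analogue used to
    benchmark the efficiency metrics.
    """
    terms = [t for t in fit._system.layout if t != fit.spec.genetic_term]
    contrib = fit.contribution(terms)[:, 0]
    sub = data.loc[fit._system.data_index]
    adj = sub[trait].to_numpy(dtype=float) - contrib
    return pd.Series(adj, index=sub["cow"]).groupby(level=0).mean().rename(f"adjusted_{trait}")


def metric_correlations(tables: dict, adjusted: pd.Series | None = None) -> dict:
    """Pairwise Pearson (and Spearman) correlations of per-animal metric EBVs.

    ``tables`` maps metric name → Series indexed by animal; the intersection
    of animal sets must be non-trivial and is used throughout.  Returns a dict
    with 'pearson' and 'spearman' DataFrames and, when ``adjusted`` phenotypes
    are supplied, their correlation with each metric's EBVs.
    """
    names = list(tables)
    common = None
    for s in tables.values():
        common = set(s.index) if common is None else common & set(s.index)
    if not common:
        raise ValidationError("metric EBV tables share no animals")
    common = sorted(common)
    M = np.column_stack([tables[n].loc[common].to_numpy(dtype=float) for n in names])
    pearson = pd.DataFrame(np.corrcoef(M, rowvar=False), index=names, columns=names)
    if len(names) == 2:
        r = float(stats.spearmanr(M[:, 0], M[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.atleast_2d(stats.spearmanr(M).statistic)
    spearman = pd.DataFrame(rho, index=names, columns=names)
    out = {"pearson": pearson, "spearman": spearman}
    if adjusted is not None:
        ids = sorted(set(common) & set(adjusted.index))
        out["adjusted"] = pd.Series(
            {
                n: float(np.corrcoef(tables[n].loc[ids], adjusted.loc[ids])[0, 1])
                for n in names
            },
            name="corr_with_adjusted_phenotype",
        )
    return out


# ------------------------------------------------------------- orchestration
def default_metric_varcomp(study) -> dict:
    """Working variance components per metric implied by a synthetic study.

    The ReFI models use the generating slope-scale components; the one-step
    RFI model uses them rescaled by the squared mean expected intake; ECE and
    the multi-trait model use components implied by the generator's sink
    structure (approximate — they serve as the fixed components under which
    BLUP/ssGBLUP breeding values are predicted).
    """
    cfg = study.config
    truth = study.true_parameters
    mean_edmi = float(study.records["edmi_rdc"].mean())
    res = truth.residual
    vcs = {
        "refi_rdc": truth,
        "refi_nrc2021": truth,
        "rfi": VarianceComponents(
            random={
                "htm": truth.scalar("htm") * mean_edmi**2,
                "pe": truth.scalar("pe") * mean_edmi**2,
                "animal": truth.scalar("animal") * mean_edmi**2,
            },
            residual=res.copy(),
        ),
    }
    v_ece = float(study.records["ece"].var())
    vcs["ece"] = VarianceComponents(
        random={"htm": 0.04 * v_ece, "pe": 0.30 * v_ece, "animal": 0.22 * v_ece},
        residual=np.full(truth.n_periods, 0.44 * v_ece),
    )
    vcs["multitrait"] = multitrait_varcomp(cfg, mean_edmi)
    return vcs


def multitrait_varcomp(config, mean_edmi: float = 20.0) -> VarianceComponents:
    """Five-trait (DMI, ECM, MBW, BWL, BWG) components implied by the generator.

    The latent sinks (ECM, MBW, dBW, BCS) plus the efficiency slope map
    linearly onto the observed traits; BWL/BWG are approximated as ∓dBW/2,
    and a 10 % diagonal inflation keeps each matrix positive definite despite
    the structural BWL/BWG anticorrelation.
    """
    def lift(sink_cov, extra_dmi_var, dmi_scale):
        # rows: dmi, ecm, mbw, bwl, bwg; cols: ecm, mbw, dbw, bcs, extra
        # `extra` is the efficiency channel: slope-scale for genetic/pe/HTM
        # components (hence dmi_scale = mean eDMI), already on the DMI scale
        # for residuals (dmi_scale = 1).
        T = np.array(
            [
                [0.456, 0.0508, 3.25, 0.0, dmi_scale],
                [1.0, 0.0, 0.0, 0.0, 0.0],
                [0.0, 1.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, -0.5, 0.0, 0.0],
                [0.0, 0.0, 0.5, 0.0, 0.0],
            ]
        )
        V = np.zeros((5, 5))
        V[:4, :4] = np.asarray(sink_cov, dtype=float)
        V[4, 4] = extra_dmi_var
        out = T @ V @ T.T
        return out + 0.10 * np.diag(np.maximum(np.diag(out), 1e-6))

    cov = config.sink_covariances
    ev = {k: float(config.variance_components[k]) for k in ("htm", "pe", "animal")}
    res_var = config.residual_variances()
    residual = np.stack([lift(cov["R"], rv, 1.0) for rv in res_var])
    return VarianceComponents(
        random={
            "htm": lift(cov["M"], ev["htm"], mean_edmi),
            "pe": lift(cov["P"], ev["pe"], mean_edmi),
            "animal": lift(cov["V_a"], ev["animal"], mean_edmi),
        },
        residual=residual,
        traits=("dmi", "ecm", "mbw", "bwl", "bwg"),
    )


def _metric_ebvs(data, vcs, kernel_inverse, pedigree) -> dict:
    """Fit all base models on one dataset/kernel; return metric → EBV Series."""
    out = {}
    fits = {}
    for m in ("refi_rdc", "refi_nrc2021", "rfi", "ece"):
        fit = fit_metric(m, data, vcs[m], kernel_inverse=kernel_inverse)
        fits[m] = fit
        scale = float(data[f"edmi_{m.split('_')[1]}"].mean()) if m.startswith("refi") else None
        out[m] = fit.breeding_values(scale=scale)
    mt = fit_metric("multitrait", data, vcs["multitrait"], kernel_inverse=kernel_inverse)
    fits["multitrait"] = mt
    bvs = mt.breeding_values()
    out["rfi_index"] = rfi_index(bvs)
    out["rzfe"] = rzfe(bvs)
    return out, fits


def run_comparison(
    study,
    vcs: dict | None = None,
    cutoff_birth_year: int | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """Full comparison pipeline on a (synthetic or real) study.

    For each efficiency metric × {pedigree BLUP, ssGBLUP} the models are fitted
    on the full and forward-reduced datasets, LR validation statistics are
    computed over the young genotyped validation group, and cross-metric
    GEBV correlations (plus correlations with adjusted benchmark phenotypes)
    are reported.  Returns a dict of DataFrames: ``lr``, ``pearson``,
    ``spearman``, ``adjusted``, ``ratios``.
    """
    records, ped = study.records, study.pedigree
    if vcs is None:
        vcs = default_metric_varcomp(study)
    if cutoff_birth_year is None:
        cutoff_birth_year = int(ped.birth_year.max()) - 2
    full, reduced, group = split_forward(records, ped, cutoff_birth_year, study.genotyped_ids)

    kernels = {
        "blup": build_kernel_inverse("pedigree", ped),
        "ssgblup": build_kernel_inverse("ssgblup", ped, study.genotypes),
    }
    ebvs = {}
    fits = {}
    for kname, kinv in kernels.items():
        for dname, data in (("full", full), ("reduced", reduced)):
            ebvs[(kname, dname)], fits[(kname, dname)] = _metric_ebvs(data, vcs, kinv, ped)

    mean_edmi = float(records["edmi_rdc"].mean())
    var_g = {
        "refi_rdc": vcs["refi_rdc"].scalar("animal") * mean_edmi**2,
        "refi_nrc2021": vcs["refi_nrc2021"].scalar("animal")
        * float(records["edmi_nrc2021"].mean()) ** 2,
        "rfi": vcs["rfi"].scalar("animal"),
        "ece": vcs["ece"].scalar("animal"),
        "rfi_index": index_variances(
            np.array([1.0, -0.456, 0.0508, -3.25, 3.25]), vcs["multitrait"]
        ).scalar("animal"),
        "rzfe": index_variances(
            np.array([-1.0, 0.4, 0.0, -4.5, 4.5]), vcs["multitrait"]
        ).scalar("animal"),
    }
    lr_rows = []
    for metric in METRIC_ORDER:
        for kname in ("blup", "ssgblup"):
            res = lr_validation(
                ebvs[(kname, "full")][metric],
                ebvs[(kname, "reduced")][metric],
                group,
                var_g=var_g[metric],
                n_boot=n_boot,
                seed=seed,
            )
            lr_rows.append({"metric": metric, "model": kname, **res.as_dict()})
    lr = pd.DataFrame(lr_rows)

    phenotyped = sorted(set(records["cow"]))
    gebv_tables = {
        m: ebvs[("ssgblup", "full")][m].loc[
            [a for a in phenotyped if a in ebvs[("ssgblup", "full")][m].index]
        ]
        for m in METRIC_ORDER
    }
    adj = adjusted_phenotypes(fits[("ssgblup", "full")]["ece"], full, trait="ece")
    corr = metric_correlations(gebv_tables, adjusted=adj)

    return {
        "lr": lr,
        "pearson": corr["pearson"],
        "spearman": corr["spearman"],
        "adjusted": corr["adjusted"],
        "group": group,
        "ebvs": ebvs,
        "varcomp": vcs,
    }
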