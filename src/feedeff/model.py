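"""Mixed-model engine: design matrices, MME assembly and solving.

Henderson's mixed-model equations (MME) for a multi-trait linear mixed model

    y = X b + Σ_j Z_j u_j + e,   u_j ~ N(0, K_j ⊗ V_j),   e ~ N(0, ⊕_i R_p(i))

are assembled sparsely as  C s = r  with

    C = W' Ω W + ⊕_j (K_j⁻¹ ⊗ V_j⁻¹),   r = W' Ω y,

where W = [X Z], Ω is the block-diagonal inverse residual covariance with one
T × T block per record (period-specific residual variances R_p), and K_j is a
relationship kernel (identity, pedigree A, or single-step H — supplied as its
inverse).  Univariate models are the T = 1 case.

Six ready-made model specifications cover the feed-efficiency metrics:

* ``refi_rdc`` / ``refi_nrc2021`` — random-regression of DMI on expected DMI:
  a fixed regression per herd × production-year, plus random regressions for
  herd × trial × test-month (HTM), cow permanent environment, and the additive
  genetic effect.  There is deliberately no general intercept or lactation
  curve: the fixed eDMI regression absorbs level differences.
* ``rfi`` — one-step residual feed intake: DMI on the four energy-sink
  covariates plus HPY fixed classes, with random HTM / pe / animal intercepts.
* ``ece`` — energy conversion efficiency with a fixed lactation-week effect
  replacing the energy sinks.
* ``multitrait`` — the five-trait (DMI, ECM, MBW, BWL, BWG) random-regression
  model with a fourth-order Legendre lactation curve nested within herd.

The public surface is both functional (``build_spec`` / ``assemble_mme`` /
``solve_mme`` / ``fit_metric``) and object-style
(:class:`FeedEfficiencyModel` → :class:`FeedEfficiencyResults`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import eval_legendre

from .components import VarianceComponents
from .genomic import GenotypeMatrix, a22_from_pedigree, blend_G, h_inverse, vanraden_G
from .metrics import lactation_period_class
from .pedigree import Pedigree, RelationshipMatrix, a_inverse


class ModelError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


DEFAULT_WEEK_RANGE = (1, 44)

#: the five traits of the multi-trait model, in canonical order
MULTITRAIT_TRAITS = ("dmi", "ecm", "mbw", "bwl", "bwg")

METRICS = ("refi_rdc", "refi_nrc2021", "multitrait", "rfi", "ece")


def legendre_basis(week, order: int = 4, week_range=DEFAULT_WEEK_RANGE) -> np.ndarray:
    """Plain Legendre polynomials P0..P_order at standardised lactation week.

    Week w in [w_min, w_max] maps to t = 2(w − w_min)/(w_max − w_min) − 1 and
    the returned array has shape (..., order+1).
    """
    w = np.asarray(week, dtype=float)
    w0, w1 = week_range
    if np.any((w < w0) | (w > w1)):
        raise ModelError(f"lactation week outside range {week_range}")
    t = 2.0 * (w - w0) / (w1 - w0) - 1.0
    return np.stack([eval_legendre(k, t) for k in range(order + 1)], axis=-1)


# --------------------------------------------------------------------- terms
@dataclass
class FixedTerm:
    """One fixed term of a model specification.

    kind: "intercept" | "class" | "covariates" | "nested_covariate" |
    "legendre".  ``drop_first`` marks identifiability constraints: "overall"
    zeroes the first level, "within:<col>" zeroes the first level inside each
    class of <col>.
    """

    name: str
    kind: str
    columns: tuple = ()
    class_column: str | None = None
    order: int = 4
    week_range: tuple = DEFAULT_WEEK_RANGE
    drop_first: str | None = None

    def design(self, data: pd.DataFrame):
        """Return (levels, col_idx (n,q), values (n,q)) for this term."""
        n = len(data)
        if self.kind == "intercept":
            return ["(intercept)"], np.zeros((n, 1), dtype=int), np.ones((n, 1))
        if self.kind == "class":
            cat = pd.Categorical(data[self.class_column])
            return (
                list(cat.categories),
                cat.codes.reshape(-1, 1).astype(int),
                np.ones((n, 1)),
            )
        if self.kind == "covariates":
            vals = data[list(self.columns)].to_numpy(dtype=float)
            idx = np.tile(np.arange(len(self.columns)), (n, 1))
            return list(self.columns), idx, vals
        if self.kind == "nested_covariate":
            cat = pd.Categorical(data[self.class_column])
            vals = data[self.columns[0]].to_numpy(dtype=float).reshape(-1, 1)
            return list(cat.categories), cat.codes.reshape(-1, 1).astype(int), vals
        if self.kind == "legendre":
            cat = pd.Categorical(data[self.class_column])
            basis = legendre_basis(data["week"], self.order, self.week_range)
            k = self.order + 1
            idx = cat.codes.reshape(-1, 1) * k + np.arange(k)
            levels = [f"{c}:P{j}" for c in cat.categories for j in range(k)]
            return levels, idx.astype(int), basis
        raise ModelError(f"unknown fixed-term kind {self.kind!r}")

    def constrained_levels(self, data: pd.DataFrame, levels) -> list[int]:
        """Level indices pinned to zero for identifiability."""
        if self.drop_first is None:
            return []
        if self.drop_first == "overall":
            return [0]
        if self.drop_first.startswith("within:"):
            col = self.drop_first.split(":", 1)[1]
            cat = pd.Categorical(data[self.class_column])
            # first level of this term inside each class of `col`
            nester = pd.Categorical(data[col])
            first = {}
            frame = pd.DataFrame({"lvl": cat.codes, "nest": nester.codes})
            for nest, grp in frame.groupby("nest"):
                first[nest] = int(grp["lvl"].min())
            return sorted(set(first.values()))
        raise ModelError(f"unknown drop_first rule {self.drop_first!r}")


@dataclass
class RandomTerm:
    """One random term: intercept or slope per level, iid or genetic kernel."""

    name: str
    level_column: str
    slope_column: str | None = None  # None -> random intercept
    kernel: str = "iid"  # "iid" | "genetic"

    def design(self, data: pd.DataFrame, levels=None):
        n = len(data)
        if levels is None:
            cat = pd.Categorical(data[self.level_column])
            levels, codes = list(cat.categories), cat.codes.astype(int)
        else:
            lookup = {a: i for i, a in enumerate(levels)}
            try:
                codes = np.array([lookup[a] for a in data[self.level_column]], dtype=int)
            except KeyError as err:
                raise ModelError(
                    f"level {err.args[0]!r} of {self.name} missing from kernel index"
                ) from err
        if self.slope_column is None:
            vals = np.ones((n, 1))
        else:
            vals = data[self.slope_column].to_numpy(dtype=float).reshape(-1, 1)
        return list(levels), codes.reshape(-1, 1), vals


@dataclass
class ModelSpec:
    """Traits, fixed terms, random terms and residual structure of one model."""

    name: str
    traits: tuple
    fixed: list
    random: list
    response_description: str = ""
    edmi_column: str | None = None  # set for the ReFI random-regression models
    genetic_term: str = "animal"

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def build_spec(metric_name: str, week_range=DEFAULT_WEEK_RANGE) -> ModelSpec:
    """Model specification for one of the five efficiency metrics or ECE."""
    m = metric_name.lower()
    if m in ("refi_rdc", "refi_nrc2021"):
        col = "edmi_rdc" if m == "refi_rdc" else "edmi_nrc2021"
        return ModelSpec(
            name=m,
            traits=("dmi",),
            fixed=[FixedTerm("alpha", "nested_covariate", (col,), class_column="hpy")],
            random=[
                RandomTerm("htm", "htm", slope_column=col),
                RandomTerm("pe", "cow", slope_column=col),
                RandomTerm("animal", "cow", slope_column=col, kernel="genetic"),
            ],
            response_description=f"DMI regressed on {col}",
            edmi_column=col,
        )
    if m == "rfi":
        return ModelSpec(
            name=m,
            traits=("dmi",),
            fixed=[
                FixedTerm("sinks", "covariates", ("ecm", "mbw", "bwl", "bwg")),
                FixedTerm("hpy", "class", class_column="hpy"),
            ],
            random=[
                RandomTerm("htm", "htm"),
                RandomTerm("pe", "cow"),
                RandomTerm("animal", "cow", kernel="genetic"),
            ],
            response_description="DMI on energy sinks (one-step residual feed intake)",
        )
    if m == "ece":
        return ModelSpec(
            name=m,
            traits=("ece",),
            fixed=[
                FixedTerm("lwk", "class", class_column="week"),
                FixedTerm("hpy", "class", class_column="hpy", drop_first="overall"),
            ],
            random=[
                RandomTerm("htm", "htm"),
                RandomTerm("pe", "cow"),
                RandomTerm("animal", "cow", kernel="genetic"),
            ],
            response_description="energy conversion efficiency",
        )
    if m == "multitrait":
        return ModelSpec(
            name=m,
            traits=MULTITRAIT_TRAITS,
            fixed=[
                FixedTerm(
                    "curve", "legendre", class_column="herd", order=4, week_range=week_range
                ),
                FixedTerm("hpy", "class", class_column="hpy", drop_first="within:herd"),
            ],
            random=[
                RandomTerm("htm", "htm"),
                RandomTerm("pe", "cow"),
                RandomTerm("animal", "cow", kernel="genetic"),
            ],
            response_description="five-trait random-regression model",
        )
    raise ModelError(f"unknown metric {metric_name!r}; choose from {METRICS}")


# ------------------------------------------------------------------ assembly
@dataclass
class MMESystem:
    """Assembled mixed-model equations C s = r plus layout metadata."""

    C: sp.csc_matrix
    rhs: np.ndarray
    W: sp.csr_matrix  # observation design, (n·T) × n_eq
    y: np.ndarray  # stacked observations, record-major
    layout: dict  # term -> (offset, levels)
    traits: tuple
    spec: ModelSpec
    constrained: np.ndarray  # equation indices pinned to zero
    period: np.ndarray  # per-record residual class (1-based)
    vc: VarianceComponents
    data_index: pd.Index

    @property
    def n_eq(self) -> int:
        return self.C.shape[0]


def _residual_inverse(period: np.ndarray, vc: VarianceComponents, T: int) -> sp.csr_matrix:
    """Block-diagonal Ω = ⊕_i R_p(i)⁻¹ over records (T×T blocks)."""
    n = period.shape[0]
    if T == 1:
        sig = vc.residual_array(1).reshape(-1)
        return sp.diags(1.0 / sig[period - 1], format="csr")
    R = vc.residual_array(T)  # (n_periods, T, T)
    Rinv = np.array([np.linalg.inv(R[p]) for p in range(R.shape[0])])
    blocks = Rinv[period - 1]  # (n, T, T)
    base = np.arange(n)[:, None, None] * T
    rows = (base + np.broadcast_to(np.arange(T)[:, None], (T, T))).reshape(-1)
    cols = (base + np.broadcast_to(np.arange(T)[None, :], (T, T))).reshape(-1)
    return sp.coo_matrix((blocks.reshape(-1), (rows, cols)), shape=(n * T, n * T)).tocsr()


def _expand_multitrait(col_idx, vals, T, offset, n):
    """Expand per-record design entries to trait-stacked rows/cols/values.

    Equation layout within a term is level-major then trait; observation rows
    are record-major then trait.  The same design entry applies to each trait.
    """
    q = col_idx.shape[1]
    rows = (np.arange(n)[:, None, None] * T + np.arange(T)[None, None, :])
    rows = np.broadcast_to(rows, (n, q, T)).reshape(-1)
    cols = (offset + col_idx[:, :, None] * T + np.arange(T)[None, None, :]).reshape(-1)
    v = np.broadcast_to(vals[:, :, None], (n, q, T)).reshape(-1)
    return rows, cols, v


def assemble_mme(
    spec: ModelSpec,
    data: pd.DataFrame,
    vc: VarianceComponents,
    kernel_inverse: RelationshipMatrix | None = None,
) -> MMESystem:
    """Assemble the sparse mixed-model equations for one specification.

    ``kernel_inverse`` supplies K⁻¹ for genetic random terms (pedigree A⁻¹ or
    single-step H⁻¹); its index defines the genetic-effect levels, so breeding
    values are produced for every pedigree animal.
    """
    T = spec.n_traits
    n = len(data)
    if n == 0:
        raise ModelError("empty data")
    for t in spec.traits:
        if t not in data.columns:
            raise ModelError(f"response column {t!r} missing")
    if "period" in data.columns:
        period = data["period"].to_numpy(dtype=int)
    elif "week" in data.columns:
        period = lactation_period_class(data["week"].to_numpy())
    else:
        period = np.ones(n, dtype=int)
    vc.check_periods(int(period.max()))

    y = data[list(spec.traits)].to_numpy(dtype=float).reshape(-1)

    rows_all, cols_all, vals_all = [], [], []
    layout: dict = {}
    offset = 0
    constrained: list[int] = []
    for term in spec.fixed:
        levels, col_idx, vals = term.design(data)
        layout[term.name] = (offset, levels)
        r, c, v = _expand_multitrait(col_idx, vals, T, offset, n)
        rows_all.append(r), cols_all.append(c), vals_all.append(v)
        for lvl in term.constrained_levels(data, levels):
            constrained.extend(offset + lvl * T + t for t in range(T))
        offset += len(levels) * T

    aug_blocks = []  # (offset, sparse K⁻¹ ⊗ V⁻¹)
    for term in spec.random:
        if term.kernel == "genetic":
            if kernel_inverse is None:
                raise ModelError("genetic random term requires a kernel inverse")
            levels = list(kernel_inverse.ids) + list(kernel_inverse.group_ids)
            Kinv = sp.csr_matrix(kernel_inverse.values)
        else:
            levels = None
            Kinv = None
        lv, col_idx, vals = term.design(data, levels=levels)
        layout[term.name] = (offset, lv)
        r, c, v = _expand_multitrait(col_idx, vals, T, offset, n)
        rows_all.append(r), cols_all.append(c), vals_all.append(v)
        if Kinv is None:
            Kinv = sp.identity(len(lv), format="csr")
        Vinv = vc.inverse_of(term.name, T)
        aug = sp.kron(Kinv, sp.csr_matrix(Vinv), format="csr")
        aug_blocks.append((offset, aug))
        offset += len(lv) * T

    n_eq = offset
    W = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n * T, n_eq),
    ).tocsr()
    Om = _residual_inverse(period, vc, T)
    C = (W.T @ Om @ W).tocsr()
    rhs = W.T @ (Om @ y)
    for off, aug in aug_blocks:
        aug_coo = aug.tocoo()
        C = C + sp.coo_matrix(
            (aug_coo.data, (aug_coo.row + off, aug_coo.col + off)), shape=C.shape
        ).tocsr()
    constrained = np.array(sorted(set(constrained)), dtype=int)
    if constrained.size:
        mask = np.ones(n_eq, dtype=bool)
        mask[constrained] = False
        D = sp.diags(mask.astype(float), format="csr")
        C = D @ C @ D + sp.diags((~mask).astype(float), format="csr")
        rhs = rhs * mask
    return MMESystem(
        C=C.tocsc(),
        rhs=rhs,
        W=W,
        y=y,
        layout=layout,
        traits=tuple(spec.traits),
        spec=spec,
        constrained=constrained,
        period=period,
        vc=vc,
        data_index=data.index,
    )


# ------------------------------------------------------------------- results
class FitResult:
    """Solutions of one mixed-model fit, indexed by term, level and trait."""

    def __init__(self, system: MMESystem, solutions: np.ndarray, diagnostics: dict):
        self._system = system
        self.solutions_vector = solutions
        self.diagnostics = diagnostics
        self.spec = system.spec
        self.traits = system.traits

    def solution(self, term: str):
        """Solutions for one term: Series (1 trait) or DataFrame (levels × traits)."""
        off, levels = self._system.layout[term]
        T = len(self.traits)
        block = self.solutions_vector[off : off + len(levels) * T].reshape(len(levels), T)
        if T == 1:
            return pd.Series(block[:, 0], index=levels, name=term)
        return pd.DataFrame(block, index=levels, columns=list(self.traits))

    @property
    def fitted(self) -> np.ndarray:
        """Fitted values on the observation scale (record-major × trait)."""
        return (self._system.W @ self.solutions_vector).reshape(-1, len(self.traits))

    @property
    def residuals(self) -> np.ndarray:
        return self._system.y.reshape(-1, len(self.traits)) - self.fitted

    def contribution(self, terms) -> np.ndarray:
        """Per-observation contribution of a subset of terms (record × trait)."""
        mask = np.zeros(self._system.n_eq)
        for term in terms:
            off, levels = self._system.layout[term]
            mask[off : off + len(levels) * len(self.traits)] = 1.0
        s = self.solutions_vector * mask
        return (self._system.W @ s).reshape(-1, len(self.traits))

    def breeding_values(self, scale: float | None = None) -> pd.DataFrame | pd.Series:
        """Additive-genetic solutions for every kernel animal.

        For the ReFI random-regression models the genetic effect is a slope
        per unit expected DMI; pass ``scale`` (the data-mean eDMI) to put the
        breeding values on the DMI scale.
        """
        sol = self.solution(self.spec.genetic_term)
        if scale is not None:
            sol = sol * scale
        # drop unknown-parent-group pseudo-levels if present
        keep = [lvl for lvl in sol.index if not (isinstance(lvl, str) and lvl.startswith("upg"))]
        return sol.loc[keep]

    def edmi_fit(self) -> np.ndarray:
        """Expected DMI per record from the one-step RFI model's fixed part.

        The sum of the fitted energy-sink regression and the herd ×
        production-year level (the model has no global intercept, so HPY
        carries the intake level).
        """
        if self.spec.name != "rfi":
            raise ModelError("edmi_fit is defined for the one-step RFI model")
        return self.contribution(["sinks", "hpy"])[:, 0]

    def summary(self) -> str:
        lines = [
            f"Mixed-model fit: {self.spec.name} ({self.spec.response_description})",
            f"  traits: {', '.join(self.traits)}",
            f"  equations: {self._system.n_eq}  records: {len(self._system.period)}",
            f"  solver: {self.diagnostics.get('method')}  "
            f"relative residual: {self.diagnostics.get('rel_residual'):.2e}",
        ]
        for term in self._system.layout:
            off, levels = self._system.layout[term]
            lines.append(f"  term {term}: {len(levels)} levels")
        return "\n".join(lines)


def solve_mme(
    system: MMESystem,
    method: str = "auto",
    direct_threshold: int = 60_000,
    tol: float = 1e-10,
    max_iter: int = 20_000,
) -> FitResult:
    """Solve C s = r: sparse LU below ``direct_threshold`` equations, else
    Jacobi-preconditioned conjugate gradients."""
    C, rhs = system.C, system.rhs
    if method == "auto":
        method = "direct" if system.n_eq <= direct_threshold else "cg"
    if method == "direct":
        try:
            lu = spla.splu(C)
        except RuntimeError as err:
            raise SolverError(f"direct factorisation failed: {err}") from err
        s = lu.solve(rhs)
        iters = 1
    elif method == "cg":
        d = C.diagonal()
        d[d == 0] = 1.0
        M = spla.LinearOperator(C.shape, matvec=lambda x: x / d)
        s, info = spla.cg(C, rhs, rtol=tol, maxiter=max_iter, M=M)
        if info != 0:
            raise SolverError(f"conjugate gradients did not converge (info={info})")
        iters = max_iter if info > 0 else -1
    else:
        raise ModelError(f"unknown solver method {method!r}")
    scale = max(float(np.linalg.norm(rhs)), 1e-300)
    rel = float(np.linalg.norm(C @ s - rhs)) / scale
    if rel > 1e-6:
        raise SolverError(f"solution residual too large: {rel:.2e}")
    return FitResult(system, s, {"method": method, "rel_residual": rel, "iterations": iters})


# ------------------------------------------------------------ kernel helpers
def build_kernel_inverse(
    kernel: str,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix | None = None,
    blend_weight: float = 0.9,
    groups: dict | None = None,
) -> RelationshipMatrix:
    """A⁻¹ for ``kernel='pedigree'`` or H⁻¹ for ``kernel='ssgblup'``."""
    ainv = a_inverse(pedigree, groups=groups)
    if kernel in ("pedigree", "blup"):
        return ainv
    if kernel in ("ssgblup", "single-step", "ss"):
        if genotypes is None:
            raise ModelError("single-step kernel requires genotypes")
        gstar = vanraden_G(genotypes)
        a22 = a22_from_pedigree(pedigree, genotypes.ids)
        G = blend_G(gstar, a22, w=blend_weight)
        return h_inverse(ainv, G, a22, genotypes.ids)
    raise ModelError(f"unknown kernel {kernel!r}")


def fit_metric(
    metric_name: str,
    data: pd.DataFrame,
    vc: VarianceComponents,
    kernel: str = "pedigree",
    pedigree: Pedigree | None = None,
    genotypes: GenotypeMatrix | None = None,
    kernel_inverse: RelationshipMatrix | None = None,
    blend_weight: float = 0.9,
    **solve_kwargs,
) -> FitResult:
    """End-to-end convenience: build spec → assemble → solve for one metric."""
    spec = build_spec(metric_name)
    sub = data.dropna(subset=[c for c in spec.traits if c in data.columns])
    if spec.edmi_column is not None:
        sub = sub.dropna(subset=[spec.edmi_column])
    if kernel_inverse is None:
        if pedigree is None:
            raise ModelError("supply a pedigree or a precomputed kernel inverse")
        kernel_inverse = build_kernel_inverse(kernel, pedigree, genotypes, blend_weight)
    system = assemble_mme(spec, sub, vc, kernel_inverse=kernel_inverse)
    return solve_mme(system, **solve_kwargs)


# -------------------------------------------------- statsmodels-style facade
class FeedEfficiencyModel:
    """A feed-efficiency genetic-evaluation model bound to data.

    Parameters
    ----------
    data : weekly phenotype table with effect-code columns (cow, herd, hpy,
        htm, week, period) and the trait columns the metric requires
    metric : one of {"refi_rdc", "refi_nrc2021", "multitrait", "rfi", "ece"}
    pedigree : :class:`Pedigree` covering every cow with records
    genotypes : optional :class:`GenotypeMatrix` (enables the single-step kernel)
    kernel : "pedigree" (BLUP) or "ssgblup"

    ``fit(vc)`` solves the mixed-model equations at fixed variance components;
    ``fit_reml()`` estimates the variance components first (EM-REML) and then
    solves.  Both return results objects carrying solutions, breeding values
    and a ``summary()``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        metric: str,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix | None = None,
        kernel: str = "pedigree",
        blend_weight: float = 0.9,
    ):
        self.data = data
        self.metric = metric
        self.spec = build_spec(metric)
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.kernel = kernel
        self._kernel_inverse = build_kernel_inverse(
            kernel, pedigree, genotypes, blend_weight
        )

    @classmethod
    def from_dataframe(cls, data, metric, pedigree, **kwargs):
        return cls(data, metric, pedigree, **kwargs)

    @property
    def kernel_inverse(self) -> RelationshipMatrix:
        return self._kernel_inverse

    def fit(self, vc: VarianceComponents, **solve_kwargs) -> FitResult:
        return fit_metric(
            self.metric,
            self.data,
            vc,
            kernel_inverse=self._kernel_inverse,
            **solve_kwargs,
        )

    def fit_reml(self, init: VarianceComponents | None = None, **reml_kwargs):
        from .reml import em_reml  # local import to avoid a cycle

        pedigree_ainv = (
            self._kernel_inverse
            if self.kernel in ("pedigree", "blup")
            else a_inverse(self.pedigree)
        )
        return em_reml(self.spec, self.data, init=init, kernel_inverse=pedigree_ainv, **reml_kwargs)

    def mean_edmi(self) -> float | None:
        if self.spec.edmi_column is None:
            return None
        return float(self.data[self.spec.edmi_column].dropna().mean())
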