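"""EM-REML variance-component estimation on the mixed-model equations.

The expectation-maximisation REML updates for a model
y = Xb + Σ_j Z_j u_j + e with u_j ~ N(0, K_j ⊗ V_j) and period-blocked
residuals R_p are, with C the MME coefficient matrix and s its solution,

    V_j ← ( Û_j' K_j⁻¹ Û_j + Tr_j ) / q_j,
    R_p ← ( Σ_{i∈p} ê_i ê_i' + Σ_{i∈p} W_i C⁻¹ W_i' ) / n_p,

where Tr_j[t,u] = tr(K_j⁻¹ C⁻¹ over the (j,t)×(j,u) equations) and W_i is the
design row-block of record i.  The traces are computed exactly from a dense
inverse of C (problem sizes here are a few thousand equations), in contrast to
Monte-Carlo trace approximations used for national-scale evaluations; the
estimating equations are identical.  Each sweep cannot decrease the restricted
log-likelihood, which is monitored and returned.

Variances are floored at 1e-10 × the phenotypic variance rather than allowed
to cross zero; a boundary flag records when the floor binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import cho_solve
from scipy.linalg.lapack import dpotrf, dpotri

from .components import DerivedRatios, VarianceComponents, delta_method_se, heritability, index_variances  # noqa: F401 re-export
from .model import MMESystem, ModelError, ModelSpec, assemble_mme
from .pedigree import RelationshipMatrix


class REMLError(RuntimeError):
    pass


@dataclass
class REMLResults:
    """Converged variance components with the likelihood trace."""

    varcomp: VarianceComponents
    loglik_trace: list
    converged: bool
    n_iter: int
    boundary_terms: list = field(default_factory=list)
    spec_name: str = ""
    mean_edmi: float | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def heritability(self, mean_edmi: float | None = None) -> DerivedRatios:
        scale = mean_edmi if mean_edmi is not None else self.mean_edmi
        return heritability(self.varcomp, mean_edmi=scale)

    def summary(self) -> str:
        lines = [
            f"EM-REML: {self.spec_name}",
            f"  iterations: {self.n_iter}  converged: {self.converged}",
            f"  restricted log-likelihood: {self.loglik:.4f}",
        ]
        for name, v in self.varcomp.random.items():
            v = np.asarray(v)
            if v.ndim == 0:
                lines.append(f"  Var({name}) = {float(v):.6g}")
            else:
                lines.append(f"  Var({name}) =\n{np.array_str(v, precision=4)}")
        res = self.varcomp.residual
        if res.ndim == 1:
            lines.append("  Var(residual, per period) = " + ", ".join(f"{x:.6g}" for x in res))
            lines.append(f"  Var(residual, weighted) = {self.varcomp.weighted_residual():.6g}")
        if self.boundary_terms:
            lines.append(f"  boundary: {', '.join(self.boundary_terms)}")
        try:
            h = self.heritability()
            lines.append(f"  h² = {h.h2:.3f}  repeatability = {h.repeatability:.3f}")
        except Exception:
            pass
        return "\n".join(lines)


def _default_init(spec: ModelSpec, data: pd.DataFrame) -> VarianceComponents:
    """Even split of the phenotypic variance over model components.

    For random-regression (slope) terms the share is divided by the mean
    squared covariate so that initial values live on the slope scale.
    """
    T = spec.n_traits
    k = len(spec.random) + 1
    if T == 1:
        vy = float(np.var(data[spec.traits[0]].to_numpy(dtype=float)))
        random = {}
        for term in spec.random:
            share = vy / k
            if term.slope_column is not None:
                share /= float(np.mean(data[term.slope_column].to_numpy(dtype=float) ** 2))
            random[term.name] = share
        n_periods = 5 if "period" in data.columns or "week" in data.columns else 1
        return VarianceComponents(random=random, residual=np.full(n_periods, vy / k))
    Y = data[list(spec.traits)].to_numpy(dtype=float)
    Vy = np.cov(Y, rowvar=False)
    Vy = Vy + 1e-8 * np.eye(T) * max(np.trace(Vy) / T, 1.0)
    random = {term.name: Vy / k for term in spec.random}
    return VarianceComponents(
        random=random, residual=np.repeat((Vy / k)[None], 5, axis=0), traits=spec.traits
    )


def _logdet_kernel(Kinv: sp.spmatrix) -> float:
    """log det K = −log det K⁻¹ for a sparse PD inverse kernel."""
    lu = spla.splu(Kinv.tocsc())
    diagU = lu.U.diagonal()
    return -float(np.sum(np.log(np.abs(diagU))))


def em_reml(
    spec: ModelSpec,
    data: pd.DataFrame,
    init: VarianceComponents | None = None,
    kernel_inverse: RelationshipMatrix | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    max_dense_equations: int = 8000,
    verbose: bool = False,
) -> REMLResults:
    """Exact-trace EM-REML for one model specification.

    Variance components are estimated under the pedigree kernel (pass A⁻¹ as
    ``kernel_inverse``), matching how single-step evaluations are usually
    parameterised.  ``tol`` is the maximum relative parameter change between
    sweeps; each sweep costs one dense factorisation + inversion of the MME,
    so keep the pedigree at analysis scale below ``max_dense_equations``.
    """
    T = spec.n_traits
    cols = [c for c in spec.traits]
    if spec.edmi_column is not None:
        cols.append(spec.edmi_column)
    sub = data.dropna(subset=[c for c in cols if c in data.columns])
    vc = init if init is not None else _default_init(spec, sub)

    system = assemble_mme(spec, sub, vc, kernel_inverse=kernel_inverse)
    m = system.n_eq
    if m > max_dense_equations:
        raise REMLError(
            f"{m} equations exceed the exact-trace EM limit "
            f"({max_dense_equations}); reduce the analysis scale"
        )
    W, y, period = system.W, system.y, system.period
    n = period.shape[0]
    periods = np.arange(1, vc.n_periods + 1)
    counts = np.array([(period == p).sum() for p in periods], dtype=float)

    # --- fixed structure reused across sweeps -------------------------------
    # per-period, per trait-pair Gram matrices M[p][t,u] = W_{p,t}' W_{p,u}
    W_pt = {}
    for pi, p in enumerate(periods):
        rec = np.where(period == p)[0]
        for t in range(T):
            W_pt[(pi, t)] = W[rec * T + t]
    y_pt = {
        (pi, t): y[(np.where(period == p)[0]) * T + t]
        for pi, p in enumerate(periods)
        for t in range(T)
    }
    gram = {}
    for pi in range(len(periods)):
        for t in range(T):
            for u in range(t, T):
                gram[(pi, t, u)] = (W_pt[(pi, t)].T @ W_pt[(pi, u)]).tocoo()

    terms = []  # (name, offset, q, Kinv coo or None, logdetK)
    for term in spec.random:
        off, levels = system.layout[term.name]
        q = len(levels)
        if term.kernel == "genetic":
            Kinv = sp.csr_matrix(kernel_inverse.values)
            ldK = _logdet_kernel(Kinv)
        else:
            Kinv = sp.identity(q, format="csr")
            ldK = 0.0
        terms.append((term.name, off, q, Kinv.tocoo(), ldK))

    constrained = system.constrained
    floor = 1e-10 * float(np.var(y))
    boundary: set[str] = set()
    loglik_trace: list[float] = []
    converged = False

    def flatten(vc_: VarianceComponents) -> np.ndarray:
        parts = [np.asarray(vc_.random[t[0]], dtype=float).reshape(-1) for t in terms]
        parts.append(vc_.residual.reshape(-1))
        return np.concatenate(parts)

    it = 0
    for it in range(1, max_iter + 1):
        system = assemble_mme(spec, sub, vc, kernel_inverse=kernel_inverse)
        Cd = system.C.toarray()
        rhs = system.rhs
        Lf, info = dpotrf(Cd, lower=1, overwrite_a=0)
        if info != 0:
            raise REMLError(f"MME not positive definite at sweep {it} (info={info})")
        logdetC = 2.0 * float(np.sum(np.log(np.diag(Lf))))
        s = cho_solve((Lf, True), rhs)
        Cinv, info = dpotri(Lf, lower=1)
        if info != 0:
            raise REMLError("dense inversion of the MME failed")
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        if constrained.size:
            Cinv[constrained, :] = 0.0
            Cinv[:, constrained] = 0.0

        # restricted log-likelihood at current components
        Om = _omega(period, vc, T)
        yPy = float(y @ (Om @ y)) - float(s @ rhs)
        ll = -0.5 * (logdetC + yPy + _logdet_G(vc, terms, T) + _logdet_R(vc, counts, T))
        loglik_trace.append(ll)
        if verbose:  # pragma: no cover
            print(f"sweep {it}: logL = {ll:.6f}")

        theta_old = flatten(vc)
        new_random = {}
        for name, off, q, Kcoo, _ in terms:
            U = s[off : off + q * T].reshape(q, T)
            quad = U.T @ (Kcoo.tocsr() @ U)
            sub_inv = Cinv[off : off + q * T, off : off + q * T]
            tr = np.empty((T, T))
            ra, ca, va = Kcoo.row, Kcoo.col, Kcoo.data
            for t in range(T):
                for u in range(T):
                    tr[t, u] = float(va @ sub_inv[ra * T + t, ca * T + u])
            V = (quad + tr) / q
            if T == 1:
                val = float(V[0, 0])
                if val < floor:
                    val = floor
                    boundary.add(name)
                new_random[name] = val
            else:
                V = (V + V.T) / 2.0
                evals = np.linalg.eigvalsh(V)
                if evals.min() < floor:
                    V = V + (floor - evals.min()) * np.eye(T)
                    boundary.add(name)
                new_random[name] = V

        ehat = y - W @ s
        new_res = np.empty_like(vc.residual)
        for pi in range(len(periods)):
            npd = counts[pi]
            if npd == 0:
                new_res[pi] = vc.residual[pi]
                continue
            E = np.empty((T, T))
            trp = np.empty((T, T))
            rec = np.where(period == periods[pi])[0]
            for t in range(T):
                for u in range(t, T):
                    E[t, u] = E[u, t] = float(ehat[rec * T + t] @ ehat[rec * T + u])
                    g = gram[(pi, t, u)]
                    # Σ_{i∈p} w_{i,t} C⁻¹ w_{i,u}' = tr(C⁻¹ · W_{p,u}'W_{p,t})
                    trp[t, u] = trp[u, t] = float(g.data @ Cinv[g.row, g.col])
            Rp = (E + trp) / npd
            if T == 1:
                new_res[pi] = max(float(Rp[0, 0]), floor)
            else:
                Rp = (Rp + Rp.T) / 2.0
                evals = np.linalg.eigvalsh(Rp)
                if evals.min() < floor:
                    Rp = Rp + (floor - evals.min()) * np.eye(T)
                new_res[pi] = Rp

        vc = VarianceComponents(
            random=new_random, residual=new_res, counts=counts, traits=vc.traits
        )
        theta_new = flatten(vc)
        # global relative change: a component collapsing to its boundary no
        # longer dominates once it is negligible against the rest
        rel = float(
            np.linalg.norm(theta_new - theta_old) / max(np.linalg.norm(theta_new), floor)
        )
        if rel < tol:
            converged = True
            break

    if not converged and it >= max_iter:
        raise REMLError(
            f"EM-REML did not converge within {max_iter} sweeps "
            f"(last relative change above tolerance); likelihood trace attached"
        ) from None
    mean_edmi = (
        float(sub[spec.edmi_column].mean()) if spec.edmi_column is not None else None
    )
    return REMLResults(
        varcomp=vc,
        loglik_trace=loglik_trace,
        converged=converged,
        n_iter=it,
        boundary_terms=sorted(boundary),
        spec_name=spec.name,
        mean_edmi=mean_edmi,
    )


def _omega(period, vc, T):
    from .model import _residual_inverse

    return _residual_inverse(period, vc, T)


def _logdet_G(vc: VarianceComponents, terms, T: int) -> float:
    total = 0.0
    for name, _off, q, _K, ldK in terms:
        v = np.asarray(vc.random[name], dtype=float)
        ldV = float(np.log(v)) if v.ndim == 0 else float(np.linalg.slogdet(v)[1])
        total += q * ldV + T * ldK
    return total


def _logdet_R(vc: VarianceComponents, counts, T: int) -> float:
    total = 0.0
    r = vc.residual
    for pi, npd in enumerate(counts):
        if npd == 0:
            continue
        ld = float(np.log(r[pi])) if r.ndim == 1 else float(np.linalg.slogdet(r[pi])[1])
        total += npd * ld
    return total
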