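"""Variance components, heritability/repeatability ratios and index variances.

A repeatability animal model partitions phenotypic variance into contemporary
group (HTM), permanent environment (pe), additive genetic (animal) and
period-specific residual parts.  Heritability and repeatability are reported
against the pe + genetic + weighted-residual total (the contemporary-group
variance is, as usual for these models, excluded from the phenotypic total).

For the ReFI random-regression metrics the pe and genetic components are
variances of a regression coefficient per unit expected DMI; multiplying them
by the squared data-mean eDMI puts them on the DMI scale on which the residual
variance already lives, and ratios are formed on that common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ComponentError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """Variance components of one model.

    ``random`` maps term name → variance: a positive scalar for univariate
    models or a T×T PSD matrix for the multi-trait model.  ``residual`` holds
    one entry per lactation-period class: shape (P,) of scalars or (P, T, T).
    ``counts`` (records per period) weights the combined residual variance.
    """

    random: dict
    residual: np.ndarray
    counts: np.ndarray | None = None
    traits: tuple | None = None

    def __post_init__(self):
        self.residual = np.asarray(self.residual, dtype=float)
        if self.residual.ndim == 0:
            self.residual = self.residual.reshape(1)
        for name, v in self.random.items():
            v = np.asarray(v, dtype=float)
            if v.ndim == 0:
                if v < 0:
                    raise ComponentError(f"variance of {name!r} must be non-negative")
            else:
                if not np.allclose(v, v.T):
                    raise ComponentError(f"covariance of {name!r} not symmetric")
                if np.linalg.eigvalsh(v).min() < -1e-10:
                    raise ComponentError(f"covariance of {name!r} not PSD")
            self.random[name] = v

    # ------------------------------------------------------------- structure
    @classmethod
    def univariate(cls, g, pe=None, htm=None, residual=1.0, counts=None):
        """Scalar components; ``residual`` may be one value or one per period."""
        random = {"animal": float(g)}
        if pe is not None:
            random["pe"] = float(pe)
        if htm is not None:
            random["htm"] = float(htm)
        res = np.atleast_1d(np.asarray(residual, dtype=float))
        return cls(random=random, residual=res, counts=counts)

    @property
    def n_periods(self) -> int:
        return self.residual.shape[0]

    def check_periods(self, max_period: int) -> None:
        if max_period > self.n_periods:
            raise ComponentError(
                f"data has period class {max_period} but only "
                f"{self.n_periods} residual variances supplied"
            )

    def residual_array(self, T: int) -> np.ndarray:
        r = self.residual
        if T == 1:
            if r.ndim == 1:
                return r
            if r.ndim == 3 and r.shape[1] == 1:
                return r[:, 0, 0]
            raise ComponentError("univariate model but matrix residuals supplied")
        if r.ndim != 3 or r.shape[1] != T:
            raise ComponentError(f"expected residual shape (P,{T},{T}), got {r.shape}")
        return r

    def inverse_of(self, name: str, T: int) -> np.ndarray:
        if name not in self.random:
            raise ComponentError(f"no variance supplied for random term {name!r}")
        v = np.asarray(self.random[name], dtype=float)
        if T == 1:
            val = float(v) if v.ndim == 0 else float(v.reshape(()))
            if val <= 0:
                raise ComponentError(f"variance of {name!r} must be positive to fit")
            return np.array([[1.0 / val]])
        if v.shape != (T, T):
            raise ComponentError(f"term {name!r}: expected {T}×{T} covariance")
        return np.linalg.inv(v)

    # --------------------------------------------------------------- summary
    def scalar(self, name: str) -> float:
        v = np.asarray(self.random[name], dtype=float)
        if v.ndim != 0:
            raise ComponentError(f"term {name!r} is not scalar")
        return float(v)

    def weighted_residual(self) -> float:
        """Record-count weighted average of the per-period residual variances."""
        r = self.residual
        if r.ndim == 3:
            raise ComponentError("weighted_residual is for univariate components")
        if self.counts is None:
            return float(r.mean())
        w = np.asarray(self.counts, dtype=float)
        if w.shape != r.shape:
            raise ComponentError("counts shape does not match residual periods")
        return float(np.average(r, weights=w))

    def as_dict(self) -> dict:
        return {
            "random": {k: np.asarray(v).tolist() for k, v in self.random.items()},
            "residual": self.residual.tolist(),
            "counts": None if self.counts is None else np.asarray(self.counts).tolist(),
            "traits": None if self.traits is None else list(self.traits),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceComponents":
        random = {k: np.asarray(v, dtype=float) for k, v in d["random"].items()}
        random = {k: (float(v) if v.ndim == 0 else v) for k, v in random.items()}
        counts = d.get("counts")
        return cls(
            random=random,
            residual=np.asarray(d["residual"], dtype=float),
            counts=None if counts is None else np.asarray(counts, dtype=float),
            traits=None if d.get("traits") is None else tuple(d["traits"]),
        )


@dataclass
class DerivedRatios:
    """Heritability and repeatability with optional delta-method SEs."""

    h2: float
    repeatability: float
    h2_se: float | None = None
    repeatability_se: float | None = None
    scale_note: str = "raw"

    def __iter__(self):
        yield self.h2
        yield self.repeatability


def heritability(
    vc: VarianceComponents,
    mean_edmi: float | None = None,
    cov: np.ndarray | None = None,
) -> DerivedRatios:
    """Heritability and repeatability from univariate variance components.

    h² = VarG / (VarPE + VarG + VarR̄) and r = (VarPE + VarG) / total, with
    VarR̄ the (count-weighted) average of the period residual variances.  For
    ReFI slope-scale components supply ``mean_edmi``: VarG and VarPE are
    multiplied by mean_edmi² before the ratio is formed.  ``cov`` (3×3 over
    pe, g, residual on the final common scale) adds delta-method SEs.
    """
    var_g = vc.scalar("animal")
    var_pe = vc.scalar("pe") if "pe" in vc.random else 0.0
    var_r = vc.weighted_residual()
    scale_note = "raw"
    if mean_edmi is not None:
        var_g *= mean_edmi**2
        var_pe *= mean_edmi**2
        scale_note = f"pe/G scaled by mean eDMI² ({mean_edmi}²)"
    total = var_pe + var_g + var_r
    if total <= 0:
        raise ComponentError("total variance must be positive")
    h2 = var_g / total
    rep = (var_pe + var_g) / total
    h2_se = rep_se = None
    if cov is not None:
        ses = delta_method_se(np.array([var_pe, var_g, var_r]), np.asarray(cov, dtype=float))
        h2_se, rep_se = ses["h2_se"], ses["repeatability_se"]
    return DerivedRatios(h2, rep, h2_se, rep_se, scale_note)


def ratio_gradients(components: np.ndarray) -> dict:
    """Analytic gradients of h² and r in (VarPE, VarG, VarR)."""
    pe, g, r = components
    T = pe + g + r
    grad_h2 = np.array([-g, T - g, -g]) / T**2
    grad_rep = np.array([T - (pe + g), T - (pe + g), -(pe + g)]) / T**2
    return {"h2": grad_h2, "repeatability": grad_rep}


def delta_method_se(components: np.ndarray, cov: np.ndarray) -> dict:
    """First-order delta-method SEs of h² and repeatability.

    ``components`` = (VarPE, VarG, VarR) point estimates; ``cov`` their 3×3
    sampling covariance.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3):
        raise ComponentError("covariance must be 3×3 over (pe, g, residual)")
    if np.linalg.eigvalsh((cov + cov.T) / 2).min() < -1e-8:
        raise ComponentError("covariance of estimates is not PSD")
    grads = ratio_gradients(np.asarray(components, dtype=float))
    out = {}
    for key, gvec in grads.items():
        out[f"{key}_se"] = float(np.sqrt(max(gvec @ cov @ gvec, 0.0)))
    return out


def index_variances(weights, vc: VarianceComponents) -> VarianceComponents:
    """Scalarise multi-trait components through a linear index w'BV.

    VarG = w'V_a w, VarPE = w'P w, per-period VarR_p = w'R_p w, preserving the
    period record counts so the weighted-average residual carries over.
    """
    w = np.asarray(weights, dtype=float)
    T = w.shape[0]
    random = {}
    for name, v in vc.random.items():
        v = np.asarray(v, dtype=float)
        if v.shape != (T, T):
            raise ComponentError(f"term {name!r}: expected {T}×{T} covariance")
        random[name] = float(w @ v @ w)
    R = vc.residual_array(T)
    res = np.array([float(w @ R[p] @ w) for p in range(R.shape[0])])
    return VarianceComponents(random=random, residual=res, counts=vc.counts)
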