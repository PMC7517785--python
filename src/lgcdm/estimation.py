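"""Marginal maximum-likelihood and posterior-mode fitting of the model menu.

Four model families share one estimation machinery:

``rdina``      cross-sectional RDINA latent class model; when handed
               longitudinal data the occasions are stacked with one mastery
               profile per person held constant over time (the deliberately
               misspecified "ignore the growth" baseline).
``rdina_cov``  RDINA with an attribute-level covariate effect h_k.
``lg_uncond``  unconditional latent growth CDM: person-level random intercept
               and slope factors (standard normal, free loadings) plus a
               time-specific disturbance on every attribute logit.
``lg_cond``    conditional latent growth CDM: adds the covariate main effect
               h_k and covariate shifts h0/h1 of the two loadings.

Estimation is EM with aggregated sufficient statistics (weighted two-group
logistic updates for the items, a quasi-Newton update for the attribute
block), followed by an L-BFGS polish of the marginal (penalized) likelihood
using the exact score obtained from the E-step via Fisher's identity.
Posterior-mode (PM) estimation adds an independent normal prior on every free
parameter to keep estimates off the boundary.  Standard errors come from the
outer product of per-person scores (BHHH).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

from .model_core import (
    AttributeGrowthParameters,
    ItemParameters,
    QMatrix,
    QuadratureRule,
    TimeCoding,
    attribute_patterns,
    ideal_response_table,
)

__all__ = [
    "ModelSpec",
    "LongitudinalResponses",
    "FitResult",
    "EstimationError",
    "FAMILIES",
    "person_loglik",
    "fit",
    "information_criteria",
    "check_local_identification",
    "posterior_mode_penalty",
]

FAMILIES = ("rdina", "rdina_cov", "lg_uncond", "lg_cond")

logger = logging.getLogger("lgcdm")

_PROB_FLOOR = 1e-12
_LOGIT_CAP = 15.0


class EstimationError(RuntimeError):
    """Raised when estimation cannot produce a usable result."""

    def __init__(self, message: str, partial: "FitResult | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, on which design.

    ``quadrature`` is the number of Gauss-Hermite nodes per random dimension
    (intercept factor, slope factor, and the time-specific disturbance).
    ``constraints`` maps parameter-block names (``"h"``, ``"h0"``, ``"h1"``,
    ``"b"``, ``"lam0"``, ``"lam1"``, ``"f"``, ``"d"``) to fixed values;
    constrained blocks are removed from the free parameter vector.
    """

    family: str
    qmatrix: QMatrix
    time_coding: TimeCoding
    covariate_names: tuple[str, ...] = ()
    estimation: str = "pm"
    quadrature: int = 9
    constraints: dict = field(default_factory=dict)
    eps_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.estimation not in ("ml", "pm"):
            raise ValueError("estimation must be 'ml' or 'pm'")
        if self.family.startswith("lg_") and self.time_coding.n_occasions < 2:
            raise ValueError(
                f"{self.family} requires at least 2 measurement occasions"
            )
        if self.quadrature < 2:
            raise ValueError("need at least 2 quadrature nodes per dimension")
        unknown = set(self.constraints) - set(_family_blocks(self.family))
        if unknown:
            raise ValueError(f"constraints name unknown parameters: {sorted(unknown)}")

    @property
    def has_covariate(self) -> bool:
        return self.family in ("rdina_cov", "lg_cond")

    @property
    def n_free_params(self) -> int:
        return ParamLayout(self).n_free


@dataclass(frozen=True)
class LongitudinalResponses:
    """Binary person x occasion x item responses with optional covariate.

    ``y`` is a float array with entries in {0, 1} or NaN for missing.
    """

    y: np.ndarray
    occasion_codes: np.ndarray
    z: np.ndarray | None = None
    person_ids: tuple = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 3:
            raise ValueError("y must be (persons x occasions x items)")
        finite = y[np.isfinite(y)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("responses must be 0, 1, or missing (NaN)")
        object.__setattr__(self, "y", y)
        codes = np.atleast_1d(np.asarray(self.occasion_codes, dtype=float))
        if codes.shape[0] != y.shape[1]:
            raise ValueError("occasion_codes length must match y's occasion axis")
        object.__setattr__(self, "occasion_codes", codes)
        if self.z is not None:
            z = np.asarray(self.z, dtype=float)
            if z.shape != (y.shape[0],):
                raise ValueError("z must be one value per person")
            object.__setattr__(self, "z", z)
        if not self.person_ids:
            object.__setattr__(
                self, "person_ids", tuple(f"p{i + 1}" for i in range(y.shape[0]))
            )

    @property
    def n_persons(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def n_items(self) -> int:
        return self.y.shape[2]


@dataclass
class FitResult:
    """Estimates, uncertainty, and fit indices from one model fit."""

    spec: ModelSpec
    item_params: ItemParameters
    attr_params: AttributeGrowthParameters
    std_errors: dict
    loglik: float
    n_params: int
    n_persons: int
    aic: float
    bic: float
    converged: bool
    n_starts_used: int
    best_start_seed: int
    em_history: list
    grad_norm: float
    jacobian_rank: tuple | None = None
    posterior_cache: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    @property
    def estimates(self) -> dict:
        return {"item": self.item_params, "attribute": self.attr_params}

    def free_vector(self) -> np.ndarray:
        return ParamLayout(self.spec).pack(self.item_params, self.attr_params)


# ---------------------------------------------------------------------------
# parameter layout


def _family_blocks(family: str) -> tuple[str, ...]:
    if family == "rdina":
        return ("f", "d", "b")
    if family == "rdina_cov":
        return ("f", "d", "b", "h")
    if family == "lg_uncond":
        return ("f", "d", "b", "lam0", "lam1")
    return ("f", "d", "b", "h", "lam0", "lam1", "h0", "h1")


_START = {"f": math.log(0.2 / 0.8), "d": 2 * math.log(0.8 / 0.2), "b": 0.0,
          "h": 0.0, "lam0": 0.5, "lam1": 0.2, "h0": 0.0, "h1": 0.0}
_LOWER = {"lam0": 0.0, "lam1": 0.0}


class ParamLayout:
    """Maps between the free parameter vector and the typed parameter objects.

    Block order is fixed per family: item false-alarm logits ``f`` (J), item
    discriminations ``d`` (J), attribute difficulties ``b`` (K), covariate
    main effects ``h`` (K), loadings ``lam0``/``lam1`` and their covariate
    shifts ``h0``/``h1`` (scalars).  Blocks named in ``spec.constraints`` are
    held fixed and dropped from the free vector.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        J = spec.qmatrix.n_items
        K = spec.qmatrix.n_attributes
        sizes = {"f": J, "d": J, "b": K, "h": K,
                 "lam0": 1, "lam1": 1, "h0": 1, "h1": 1}
        self.blocks = _family_blocks(spec.family)
        self.sizes = {name: sizes[name] for name in self.blocks}
        self.fixed = {}
        for name, value in spec.constraints.items():
            self.fixed[name] = np.broadcast_to(
                np.asarray(value, dtype=float), (self.sizes[name],)
            ).copy()
        self.free_blocks = tuple(b for b in self.blocks if b not in self.fixed)
        self.slices = {}
        pos = 0
        for name in self.free_blocks:
            self.slices[name] = slice(pos, pos + self.sizes[name])
            pos += self.sizes[name]
        self.n_free = pos

    def free_names(self) -> list[str]:
        names = []
        for b in self.free_blocks:
            n = self.sizes[b]
            names.extend([b] if n == 1 else [f"{b}[{i}]" for i in range(n)])
        return names

    def start_vector(self) -> np.ndarray:
        out = np.empty(self.n_free)
        for b in self.free_blocks:
            out[self.slices[b]] = _START[b]
        return out

    def bounds(self) -> list[tuple]:
        bnds = []
        for b in self.free_blocks:
            lo = _LOWER.get(b, -np.inf)
            bnds.extend([(lo, np.inf)] * self.sizes[b])
        return bnds

    def perturb(self, vec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = vec + rng.normal(0.0, 0.5, size=vec.shape)
        for b in ("lam0", "lam1"):
            if b in self.slices:
                out[self.slices[b]] = np.maximum(out[self.slices[b]], 0.05)
        return out

    def _block_value(self, name: str, free: np.ndarray) -> np.ndarray:
        if name in self.fixed:
            return self.fixed[name]
        return free[self.slices[name]]

    def unpack(self, free: np.ndarray) -> tuple[ItemParameters, AttributeGrowthParameters]:
        free = np.asarray(free, dtype=float)
        get = lambda n: self._block_value(n, free)  # noqa: E731
        item = ItemParameters(f=get("f"), d=get("d"))
        K = self.sizes["b"]
        kw = dict(b=get("b"), h=np.zeros(K), sigma0=0.0, sigma1=0.0,
                  h0=0.0, h1=0.0, eps_sd=0.0)
        if "h" in self.blocks:
            kw["h"] = get("h")
        if self.spec.family.startswith("lg_"):
            kw["sigma0"] = float(get("lam0")[0])
            kw["sigma1"] = float(get("lam1")[0])
            kw["eps_sd"] = self.spec.eps_sd
            if self.spec.family == "lg_cond":
                kw["h0"] = float(get("h0")[0])
                kw["h1"] = float(get("h1")[0])
        return item, AttributeGrowthParameters(**kw)

    def pack(self, item: ItemParameters, attr: AttributeGrowthParameters) -> np.ndarray:
        values = {"f": item.f, "d": item.d, "b": attr.b, "h": attr.h,
                  "lam0": [attr.sigma0], "lam1": [attr.sigma1],
                  "h0": [attr.h0], "h1": [attr.h1]}
        out = np.empty(self.n_free)
        for b in self.free_blocks:
            out[self.slices[b]] = np.asarray(values[b], dtype=float)
        return out


# ---------------------------------------------------------------------------
# likelihood engines


def _item_logtables(item: ItemParameters) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """log P(y=1), log P(y=0) for eta = 0 and 1, each length J."""
    lin0, lin1 = item.f, item.f + item.d
    return log_expit(lin0), log_expit(-lin0), log_expit(lin1), log_expit(-lin1)


def _clip_probs(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)


class _EngineBase:
    """Shared data preparation for both likelihood engines."""

    def __init__(self, spec: ModelSpec, data: LongitudinalResponses):
        self.spec = spec
        self.data = data
        q = spec.qmatrix
        if data.n_items != q.n_items:
            raise ValueError(
                f"data has {data.n_items} items but Q-matrix has {q.n_items}"
            )
        self.A = attribute_patterns(q.n_attributes)          # (C, K)
        self.E = ideal_response_table(q)                     # (C, J)
        self.mask = np.isfinite(data.y)
        self.Yobs = np.where(self.mask, data.y, 0.0)
        self.Ymis0 = np.where(self.mask, 1.0 - data.y, 0.0)
        self.tcodes = data.occasion_codes
        if spec.has_covariate:
            if data.z is None:
                raise ValueError(f"{spec.family} requires a person covariate")
            self.zvals = np.unique(data.z)
            self.zidx = np.searchsorted(self.zvals, data.z)
        else:
            self.zvals = np.zeros(1)
            self.zidx = np.zeros(data.n_persons, dtype=int)
        self.groups = [np.flatnonzero(self.zidx == g) for g in range(len(self.zvals))]

    def _occasion_pattern_loglik(self, item: ItemParameters) -> np.ndarray:
        """(n, T, C) log-likelihood of each occasion's responses per pattern."""
        lp0, lq0, lp1, lq1 = _item_logtables(item)
        Wy = lp0[None, :] + self.E * (lp1 - lp0)[None, :]    # (C, J)
        Wn = lq0[None, :] + self.E * (lq1 - lq0)[None, :]
        return np.einsum("itj,cj->itc", self.Yobs, Wy) + np.einsum(
            "itj,cj->itc", self.Ymis0, Wn
        )


class LGEngine(_EngineBase):
    """Vectorized marginal likelihood for the latent growth families.

    The person-level random intercept u and slope v are integrated on a
    tensor-product Gauss-Hermite grid; the time-specific disturbance is
    integrated by a one-dimensional rule inside the attribute probabilities.
    Attribute indicators are independent across attributes and occasions
    given (u, v, eps, z, t).
    """

    def __init__(self, spec: ModelSpec, data: LongitudinalResponses):
        super().__init__(spec, data)
        g1 = QuadratureRule.gauss_hermite(spec.quadrature)
        uu, vv = np.meshgrid(g1.nodes, g1.nodes, indexing="ij")
        ww = np.outer(g1.weights, g1.weights)
        self.uq = uu.ravel()
        self.vq = vv.ravel()
        self.logwq = np.log(ww.ravel())
        self.eps_quad = QuadratureRule.gauss_hermite(spec.quadrature)

    def attr_probs(self, attr: AttributeGrowthParameters) -> tuple[np.ndarray, np.ndarray]:
        """P[z, q, t, k] mastery probabilities (eps integrated) and dP/da."""
        z = self.zvals[:, None, None, None]
        u = self.uq[None, :, None, None]
        v = self.vq[None, :, None, None]
        t = self.tcodes[None, None, :, None]
        b = attr.b[None, None, None, :]
        h = attr.h[None, None, None, :]
        load0 = attr.sigma0 + attr.h0 * z
        load1 = attr.sigma1 + attr.h1 * z
        a = b + h * z + attr.mu0 + load0 * u + (attr.mu1 + load1 * v) * t
        if attr.eps_sd > 0:
            xe = attr.eps_sd * self.eps_quad.nodes
            we = self.eps_quad.weights
            pe = expit(a[..., None] + xe)
            P = np.einsum("e,zqtke->zqtk", we, pe)
            D = np.einsum("e,zqtke->zqtk", we, pe * (1.0 - pe))
        else:
            P = expit(a)
            D = P * (1.0 - P)
        return _clip_probs(P), D

    def estep(
        self,
        item: ItemParameters,
        attr: AttributeGrowthParameters,
        want_scores: bool = False,
    ) -> dict:
        n, T, J = self.data.y.shape
        C = self.A.shape[0]
        Q = self.uq.shape[0]
        P, D = self.attr_probs(attr)                          # (Z, Q, T, K)
        logP, log1mP = np.log(P), np.log1p(-P)
        # prior probability of each pattern at each node/occasion/covariate
        logPR = np.einsum("ck,zqtk->zqtc", self.A, logP) + np.einsum(
            "ck,zqtk->zqtc", 1 - self.A, log1mP
        )
        PR = np.exp(logPR)                                    # (Z, Q, T, C)
        LB = self._occasion_pattern_loglik(item)              # (n, T, C)
        LBmax = LB.max(axis=2)
        LBs = np.exp(LB - LBmax[:, :, None])

        loglik_i = np.empty(n)
        PQ = np.empty((n, Q))
        G = np.empty((n, Q, T))
        for g, idx in enumerate(self.groups):
            if idx.size == 0:
                continue
            # G[i, q, t] = sum_c PR[z, q, t, c] * LBs[i, t, c]
            Gg = np.einsum("itc,qtc->iqt", LBs[idx], PR[g], optimize=True)
            G[idx] = Gg
            S = self.logwq[None, :] + np.log(np.clip(Gg, 1e-300, None)).sum(axis=2)
            S += LBmax[idx].sum(axis=1)[:, None]
            li = logsumexp(S, axis=1)
            loglik_i[idx] = li
            PQ[idx] = np.exp(S - li[:, None])

        out = {"loglik": float(loglik_i.sum()), "loglik_i": loglik_i, "PQ": PQ}

        # pattern posterior marginalized over nodes: (n, T, C)
        PQoverG = PQ[:, :, None] / np.clip(G, 1e-300, None)
        PCm = np.empty((n, T, C))
        PA = np.empty((n, Q, T, self.A.shape[1]))
        PRA = np.einsum("zqtc,ck->zqtkc", PR, self.A)
        for g, idx in enumerate(self.groups):
            if idx.size == 0:
                continue
            PCm[idx] = LBs[idx] * np.einsum(
                "iqt,qtc->itc", PQoverG[idx], PR[g], optimize=True
            )
            H = np.einsum("itc,qtkc->iqtk", LBs[idx], PRA[g], optimize=True)
            PA[idx] = H / np.clip(G[idx][:, :, :, None], 1e-300, None)
        out["post_attr"] = np.einsum("iq,iqtk->itk", PQ, PA)
        out["post_eta"] = PCm @ self.E                        # (n, T, J)

        # aggregated sufficient statistics
        pe1 = out["post_eta"]
        Y1 = np.einsum("itj,itj->j", self.Yobs, pe1)
        W1 = np.einsum("itj,itj->j", self.mask.astype(float), pe1)
        Ytot = self.Yobs.sum(axis=(0, 1))
        Wtot = self.mask.sum(axis=(0, 1)).astype(float)
        out["item_stats"] = (Ytot - Y1, Wtot - W1, Y1, W1)    # Y0, W0, Y1, W1
        Z = len(self.zvals)
        R = np.zeros((Z,) + P.shape[1:])
        N = np.zeros((Z, Q))
        for g, idx in enumerate(self.groups):
            if idx.size == 0:
                continue
            R[g] = np.einsum("iq,iqtk->qtk", PQ[idx], PA[idx])
            N[g] = PQ[idx].sum(axis=0)
        out["attr_stats"] = (R, N)
        out["P"], out["D"] = P, D

        if want_scores:
            out["scores"] = self._person_scores(item, attr, out, PA)
        return out

    def _person_scores(self, item, attr, est, PA) -> np.ndarray:
        """Per-person score of the marginal loglik (Fisher identity)."""
        layout = ParamLayout(self.spec)
        n = self.data.n_persons
        S = np.zeros((n, layout.n_free))
        pe1 = est["post_eta"]
        obs = self.mask.astype(float)
        sf0, sf1 = expit(item.f), expit(item.f + item.d)
        # observed-cell residuals under each eta branch
        r0 = self.Yobs - obs * sf0[None, None, :]
        r1 = self.Yobs - obs * sf1[None, None, :]
        s_f = ((1.0 - pe1) * r0 + pe1 * r1).sum(axis=1)
        s_d = (pe1 * r1).sum(axis=1)
        if "f" in layout.slices:
            S[:, layout.slices["f"]] = s_f
        if "d" in layout.slices:
            S[:, layout.slices["d"]] = s_d

        P, D = est["P"], est["D"]
        PQ = est["PQ"]
        # per-person gradient wrt the logit mean a_{z,q,t,k}
        for g, idx in enumerate(self.groups):
            if idx.size == 0:
                continue
            w = (PA[idx] * (D[g] / P[g])[None] -
                 (1.0 - PA[idx]) * (D[g] / (1.0 - P[g]))[None])
            w *= PQ[idx][:, :, None, None]                    # (i, q, t, k)
            zval = self.zvals[g]
            if "b" in layout.slices:
                S[np.ix_(idx, np.arange(*layout.slices["b"].indices(layout.n_free)))] += \
                    w.sum(axis=(1, 2))
            if "h" in layout.slices:
                S[np.ix_(idx, np.arange(*layout.slices["h"].indices(layout.n_free)))] += \
                    zval * w.sum(axis=(1, 2))
            wu = np.einsum("iqtk,q->i", w, self.uq)
            wvt = np.einsum("iqtk,q,t->i", w, self.vq, self.tcodes)
            if "lam0" in layout.slices:
                S[idx, layout.slices["lam0"].start] += wu
            if "lam1" in layout.slices:
                S[idx, layout.slices["lam1"].start] += wvt
            if "h0" in layout.slices:
                S[idx, layout.slices["h0"].start] += zval * wu
            if "h1" in layout.slices:
                S[idx, layout.slices["h1"].start] += zval * wvt
        return S

    # gradient of the expected complete-data loglik (and of the marginal
    # loglik, by Fisher's identity) with respect to the attribute block
    def attr_grad(self, attr: AttributeGrowthParameters, R, N) -> dict:
        P, D = self.attr_probs(attr)
        ga = (R / P - (np.maximum(N[:, :, None, None] - R, 0.0)) / (1.0 - P)) * D
        out = {
            "b": ga.sum(axis=(0, 1, 2)),
            "h": np.einsum("zqtk,z->k", ga, self.zvals),
            "lam0": np.array([np.einsum("zqtk,q->", ga, self.uq)]),
            "lam1": np.array([np.einsum("zqtk,q,t->", ga, self.vq, self.tcodes)]),
            "h0": np.array([np.einsum("zqtk,z,q->", ga, self.zvals, self.uq)]),
            "h1": np.array(
                [np.einsum("zqtk,z,q,t->", ga, self.zvals, self.vq, self.tcodes)]
            ),
        }
        return out

    def attr_expected_loglik(self, attr: AttributeGrowthParameters, R, N) -> float:
        P, _ = self.attr_probs(attr)
        fail = np.maximum(N[:, :, None, None] - R, 0.0)
        return float((R * np.log(P) + fail * np.log1p(-P)).sum())


class RDINAEngine(_EngineBase):
    """Stacked cross-sectional RDINA: one mastery profile per person."""

    def attr_probs(self, attr: AttributeGrowthParameters) -> np.ndarray:
        """P[z, k] mastery probabilities."""
        z = self.zvals[:, None]
        return _clip_probs(expit(attr.b[None, :] + attr.h[None, :] * z + attr.mu0))

    def estep(
        self,
        item: ItemParameters,
        attr: AttributeGrowthParameters,
        want_scores: bool = False,
    ) -> dict:
        n, T, J = self.data.y.shape
        P = self.attr_probs(attr)                             # (Z, K)
        logpi = self.A @ np.log(P).T + (1 - self.A) @ np.log1p(-P).T  # (C, Z)
        LB = self._occasion_pattern_loglik(item).sum(axis=1)  # (n, C)
        S = logpi.T[self.zidx] + LB                           # (n, C)
        li = logsumexp(S, axis=1)
        PC = np.exp(S - li[:, None])
        pe1 = PC @ self.E                                     # (n, J); constant in t
        post_attr = PC @ self.A                               # (n, K)
        out = {
            "loglik": float(li.sum()),
            "loglik_i": li,
            "post_attr": np.repeat(post_attr[:, None, :], T, axis=1),
            "post_eta": np.repeat(pe1[:, None, :], T, axis=1),
            "P": P,
        }
        Y1 = np.einsum("itj,ij->j", self.Yobs, pe1)
        W1 = np.einsum("itj,ij->j", self.mask.astype(float), pe1)
        Ytot = self.Yobs.sum(axis=(0, 1))
        Wtot = self.mask.sum(axis=(0, 1)).astype(float)
        out["item_stats"] = (Ytot - Y1, Wtot - W1, Y1, W1)
        Z = len(self.zvals)
        R = np.zeros((Z, self.A.shape[1]))
        N = np.zeros(Z)
        for g, idx in enumerate(self.groups):
            R[g] = post_attr[idx].sum(axis=0)
            N[g] = idx.size
        out["attr_stats"] = (R, N)
        if want_scores:
            layout = ParamLayout(self.spec)
            Smat = np.zeros((n, layout.n_free))
            obs = self.mask.astype(float)
            sf0, sf1 = expit(item.f), expit(item.f + item.d)
            r0 = self.Yobs - obs * sf0[None, None, :]
            r1 = self.Yobs - obs * sf1[None, None, :]
            pe = pe1[:, None, :]
            if "f" in layout.slices:
                Smat[:, layout.slices["f"]] = ((1 - pe) * r0 + pe * r1).sum(axis=1)
            if "d" in layout.slices:
                Smat[:, layout.slices["d"]] = (pe * r1).sum(axis=1)
            resid = post_attr - P[self.zidx]
            if "b" in layout.slices:
                Smat[:, layout.slices["b"]] = resid
            if "h" in layout.slices:
                Smat[:, layout.slices["h"]] = resid * self.zvals[self.zidx][:, None]
            out["scores"] = Smat
        return out


def _make_engine(spec: ModelSpec, data: LongitudinalResponses) -> _EngineBase:
    if spec.family.startswith("lg_"):
        return LGEngine(spec, data)
    return RDINAEngine(spec, data)


# ---------------------------------------------------------------------------
# public likelihood


def _check_finite(item: ItemParameters, attr: AttributeGrowthParameters) -> None:
    for name, arr in (("f", item.f), ("d", item.d), ("b", attr.b), ("h", attr.h),
                      ("lam0", [attr.sigma0]), ("lam1", [attr.sigma1]),
                      ("h0", [attr.h0]), ("h1", [attr.h1])):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite value in parameter block {name!r}")


def person_loglik(
    spec: ModelSpec,
    item_params: ItemParameters,
    attr_params: AttributeGrowthParameters,
    y_i: np.ndarray,
    z_i: float | None = None,
    quadrature: int | None = None,
) -> float:
    """Marginal log-likelihood of one person's response array.

    ``y_i`` is (occasions x items) with NaN for missing responses.  The
    likelihood mixes over the person random effects on a Gauss-Hermite grid
    and, within each node, over all ``2**K`` mastery profiles independently
    per occasion; missing responses contribute a factor of one.
    """
    _check_finite(item_params, attr_params)
    y_i = np.atleast_2d(np.asarray(y_i, dtype=float))
    if quadrature is not None:
        spec = replace(spec, quadrature=quadrature)
    z = None
    if spec.has_covariate:
        z = np.array([0.0 if z_i is None else float(z_i)])
        if z_i is None:
            raise ValueError(f"{spec.family} requires a covariate value z_i")
    data = LongitudinalResponses(
        y=y_i[None], occasion_codes=spec.time_coding.codes[: y_i.shape[0]], z=z
    )
    engine = _make_engine(spec, data)
    return float(engine.estep(item_params, attr_params)["loglik"])


def information_criteria(loglik: float, n_params: int, n_persons: int) -> tuple[float, float]:
    """AIC and BIC from the maximized log-likelihood."""
    if n_persons < 1:
        raise ValueError("n_persons must be at least 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * math.log(n_persons)
    return aic, bic


def posterior_mode_penalty(params_vector: np.ndarray, prior_sd: float) -> float:
    """Log normal prior density summed over free logit-scale parameters."""
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    return float(norm.logpdf(np.asarray(params_vector), 0.0, prior_sd).sum())


# ---------------------------------------------------------------------------
# M-steps


def _newton_two_group(Y0, W0, Y1, W1, x0, x1, prior_var, n_iter=30, tol=1e-10):
    """Maximize a two-cell weighted Bernoulli loglik in (x0, delta).

    Cell 0 has success/total (Y0, W0) at logit ``x0``; cell 1 has (Y1, W1) at
    logit ``x0 + delta``.  A normal(0, prior_var) penalty applies to both
    parameters.  Used for item updates (f, d) and the covariate attribute
    update (b, h).  Vectorized over the last axis.
    """
    f = np.clip(np.asarray(x0, dtype=float).copy(), -_LOGIT_CAP, _LOGIT_CAP)
    d = np.clip(np.asarray(x1, dtype=float) - f, -2 * _LOGIT_CAP, 2 * _LOGIT_CAP)
    ipv = 0.0 if np.isinf(prior_var) else 1.0 / prior_var
    for _ in range(n_iter):
        p0, p1 = expit(f), expit(f + d)
        gf = (Y0 - W0 * p0) + (Y1 - W1 * p1) - ipv * f
        gd = (Y1 - W1 * p1) - ipv * d
        v0 = W0 * p0 * (1 - p0) + 1e-12
        v1 = W1 * p1 * (1 - p1) + 1e-12
        hff = v0 + v1 + ipv
        hfd = v1
        hdd = v1 + ipv + 1e-12
        det = hff * hdd - hfd * hfd
        step_f = (hdd * gf - hfd * gd) / det
        step_d = (hff * gd - hfd * gf) / det
        norm_step = np.maximum(np.abs(step_f), np.abs(step_d))
        scale = np.minimum(1.0, 2.0 / np.maximum(norm_step, 1e-300))
        f = np.clip(f + scale * step_f, -_LOGIT_CAP, _LOGIT_CAP)
        d = np.clip(d + scale * step_d, -2 * _LOGIT_CAP, 2 * _LOGIT_CAP)
        if np.max(norm_step) < tol:
            break
    return f, f + d


def _newton_one_group(Y, W, x, prior_var, n_iter=30, tol=1e-10):
    b = np.clip(np.asarray(x, dtype=float).copy(), -_LOGIT_CAP, _LOGIT_CAP)
    ipv = 0.0 if np.isinf(prior_var) else 1.0 / prior_var
    for _ in range(n_iter):
        p = expit(b)
        g = Y - W * p - ipv * b
        h = W * p * (1 - p) + ipv + 1e-12
        step = np.clip(g / h, -2.0, 2.0)
        b = np.clip(b + step, -_LOGIT_CAP, _LOGIT_CAP)
        if np.max(np.abs(step)) < tol:
            break
    return b


# ---------------------------------------------------------------------------
# fitting


def _free_grad(layout: ParamLayout, engine, item, attr, est, prior_var) -> np.ndarray:
    """Exact score of the penalized marginal loglik at the current point."""
    Y0, W0, Y1, W1 = est["item_stats"]
    p0, p1 = expit(item.f), expit(item.f + item.d)
    grads = {
        "f": (Y0 - W0 * p0) + (Y1 - W1 * p1),
        "d": Y1 - W1 * p1,
    }
    R, N = est["attr_stats"]
    if isinstance(engine, LGEngine):
        grads.update(engine.attr_grad(attr, R, N))
    else:
        P = engine.attr_probs(attr)
        resid = R - N[:, None] * P
        grads["b"] = resid.sum(axis=0)
        grads["h"] = np.einsum("zk,z->k", resid, engine.zvals)
    vec = layout.pack(item, attr)
    g = np.zeros(layout.n_free)
    for name in layout.free_blocks:
        g[layout.slices[name]] = grads[name]
    if not np.isinf(prior_var):
        g -= vec / prior_var
    return g


def _attr_mstep_lg(layout, engine, attr, R, N, prior_var, maxiter=25):
    """Quasi-Newton maximization of the attribute block's Q-function."""
    attr_blocks = [b for b in layout.free_blocks if b not in ("f", "d")]
    if not attr_blocks:
        return attr
    slices, pos = {}, 0
    for b in attr_blocks:
        slices[b] = slice(pos, pos + layout.sizes[b])
        pos += layout.sizes[b]

    def to_attr(sub):
        kw = dict(b=attr.b, h=attr.h, sigma0=attr.sigma0, sigma1=attr.sigma1,
                  h0=attr.h0, h1=attr.h1, mu0=attr.mu0, mu1=attr.mu1,
                  eps_sd=attr.eps_sd)
        for name in attr_blocks:
            val = sub[slices[name]]
            if name == "b":
                kw["b"] = val
            elif name == "h":
                kw["h"] = val
            elif name == "lam0":
                kw["sigma0"] = float(max(val[0], 0.0))
            elif name == "lam1":
                kw["sigma1"] = float(max(val[0], 0.0))
            elif name == "h0":
                kw["h0"] = float(val[0])
            elif name == "h1":
                kw["h1"] = float(val[0])
        return AttributeGrowthParameters(**kw)

    start = np.empty(pos)
    vals = {"b": attr.b, "h": attr.h, "lam0": [attr.sigma0],
            "lam1": [attr.sigma1], "h0": [attr.h0], "h1": [attr.h1]}
    for name in attr_blocks:
        start[slices[name]] = np.asarray(vals[name], dtype=float)
    ipv = 0.0 if np.isinf(prior_var) else 1.0 / prior_var

    def nll_and_grad(sub):
        a = to_attr(sub)
        val = engine.attr_expected_loglik(a, R, N) - 0.5 * ipv * float(sub @ sub)
        gd = engine.attr_grad(a, R, N)
        g = np.empty(pos)
        for name in attr_blocks:
            g[slices[name]] = gd[name]
        g -= ipv * sub
        return -val, -g

    bounds = [(0.0, None) if b in ("lam0", "lam1") else (None, None)
              for b in attr_blocks for _ in range(layout.sizes[b])]
    res = minimize(nll_and_grad, start, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": maxiter})
    # generalized EM: accept the update only if it improves the Q-function
    if -res.fun >= -nll_and_grad(start)[0] - 1e-10:
        return to_attr(res.x)
    return attr


def _run_em(layout, engine, free0, options) -> dict:
    spec = layout.spec
    prior_var = (options["prior_sd"] ** 2) if spec.estimation == "pm" else np.inf
    item, attr = layout.unpack(free0)
    history = []
    pll_prev = -np.inf
    converged = False
    est = engine.estep(item, attr)
    for it in range(options["max_em_iter"]):
        pll = est["loglik"]
        if not np.isinf(prior_var):
            pll += posterior_mode_penalty(layout.pack(item, attr), options["prior_sd"])
        history.append(pll)
        if it > 0 and abs(pll - pll_prev) / (abs(pll) + 1.0) < options["em_tol"]:
            converged = True
            break
        pll_prev = pll
        # M-step: items (closed-ish form), then attribute block
        Y0, W0, Y1, W1 = est["item_stats"]
        if "f" in layout.free_blocks or "d" in layout.free_blocks:
            fnew, fd = _newton_two_group(Y0, W0, Y1, W1, item.f, item.f + item.d,
                                         prior_var)
            fvec = fnew if "f" in layout.free_blocks else item.f
            dvec = (fd - fnew) if "d" in layout.free_blocks else item.d
            item = ItemParameters(f=fvec, d=dvec)
        R, N = est["attr_stats"]
        if isinstance(engine, LGEngine):
            attr = _attr_mstep_lg(layout, engine, attr, R, N, prior_var)
        else:
            if "h" in layout.free_blocks and len(engine.zvals) > 1:
                bnew, bh = _newton_two_group(R[0], np.full_like(R[0], N[0]),
                                             R[1], np.full_like(R[1], N[1]),
                                             attr.b, attr.b + attr.h, prior_var)
                attr = replace(attr, b=bnew, h=bh - bnew)
            elif "b" in layout.free_blocks:
                Yk = R.sum(axis=0)
                Wk = np.full_like(Yk, N.sum())
                attr = replace(attr, b=_newton_one_group(Yk, Wk, attr.b, prior_var))
        est = engine.estep(item, attr)
    final_pll = est["loglik"]
    if not np.isinf(prior_var):
        final_pll += posterior_mode_penalty(layout.pack(item, attr), options["prior_sd"])
    history.append(final_pll)
    return {"item": item, "attr": attr, "pll": final_pll, "est": est,
            "history": history, "em_converged": converged}


def fit(spec: ModelSpec, data: LongitudinalResponses, **options) -> FitResult:
    """Fit a model by EM with multi-start and an L-BFGS polish.

    Options (all keyword): ``max_em_iter`` (default 500), ``em_tol`` (relative
    penalized-loglik change, 1e-9), ``nr_tol`` (score infinity-norm declaring
    the polished optimum converged, 1e-3), ``n_starts`` (20), ``seed`` (0),
    ``prior_sd`` (3.0, PM mode only), ``polish`` (True), ``compute_se``
    (True), ``start_em_iter`` (EM iterations per non-best start, 40).

    Returns the highest penalized-loglik solution across starts.  Start 1 is
    deterministic (guessing 0.2, slip 0.2, difficulties 0, loadings 0.5/0.2);
    later starts add seeded N(0, 0.5) perturbations.
    """
    opts = {"max_em_iter": 500, "em_tol": 1e-9, "nr_tol": 1e-3, "n_starts": 20,
            "seed": 0, "prior_sd": 3.0, "polish": True, "compute_se": True,
            "start_em_iter": 40, "polish_maxiter": 200,
            "check_identification": False}
    unknown = set(options) - set(opts)
    if unknown:
        raise TypeError(f"unknown fit options: {sorted(unknown)}")
    opts.update(options)

    layout = ParamLayout(spec)
    engine = _make_engine(spec, data)
    if data.n_persons < 2 * layout.n_free:
        warnings.warn(
            f"only {data.n_persons} persons for {layout.n_free} free parameters; "
            "estimates may be unstable",
            stacklevel=2,
        )
    prior_var = (opts["prior_sd"] ** 2) if spec.estimation == "pm" else np.inf

    # multi-start: short EM runs, keep the best, then run it to convergence
    rng = np.random.default_rng(opts["seed"])
    starts = [layout.start_vector()]
    for _ in range(opts["n_starts"] - 1):
        starts.append(layout.perturb(layout.start_vector(), rng))
    best, best_idx = None, 0
    burn = {**opts, "max_em_iter": min(opts["start_em_iter"], opts["max_em_iter"])}
    for s_idx, s_vec in enumerate(starts):
        try:
            run = _run_em(layout, engine, s_vec, burn if len(starts) > 1 else opts)
        except FloatingPointError:
            logger.info("start %d (seed %d): failed", s_idx, opts["seed"])
            continue
        logger.info(
            "start %d (seed %d): %d EM iterations, penalized loglik %.4f",
            s_idx, opts["seed"], len(run["history"]) - 1, run["pll"],
        )
        if best is None or run["pll"] > best["pll"] + 1e-12:
            best, best_idx = run, s_idx
    if best is None:
        raise EstimationError("all starting values failed")
    if len(starts) > 1:
        best = _run_em(layout, engine, layout.pack(best["item"], best["attr"]), opts)

    item, attr = best["item"], best["attr"]
    grad = _free_grad(layout, engine, item, attr, best["est"], prior_var)
    grad_norm = float(np.max(np.abs(grad)))

    if opts["polish"]:
        def nll_and_grad(vec):
            itm, att = layout.unpack(vec)
            est = engine.estep(itm, att)
            val = est["loglik"]
            if not np.isinf(prior_var):
                val += posterior_mode_penalty(vec, opts["prior_sd"])
            g = _free_grad(layout, engine, itm, att, est, prior_var)
            return -val, -g

        res = minimize(nll_and_grad, layout.pack(item, attr), jac=True,
                       method="L-BFGS-B", bounds=layout.bounds(),
                       options={"maxiter": opts["polish_maxiter"]})
        if -res.fun >= best["pll"] - 1e-9:
            item, attr = layout.unpack(res.x)
            best["pll"] = -res.fun
            grad_norm = float(np.max(np.abs(res.jac)))

    est = engine.estep(item, attr, want_scores=opts["compute_se"])
    loglik = est["loglik"]
    n_params = layout.n_free
    aic, bic = information_criteria(loglik, n_params, data.n_persons)
    converged = bool(best["em_converged"] or grad_norm < opts["nr_tol"])

    std_errors = {"free": None, "names": layout.free_names()}
    if opts["compute_se"]:
        S = est["scores"]
        if spec.estimation == "pm":
            S = S - layout.pack(item, attr)[None, :] / (prior_var * data.n_persons)
        info = S.T @ S
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
            if (diag <= 0).any():
                raise np.linalg.LinAlgError
            std_errors["free"] = np.sqrt(diag)
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix; standard errors unavailable",
                          stacklevel=2)
            std_errors["free"] = np.full(n_params, np.nan)

    if np.any(item.d < 0):
        bad = [spec.qmatrix.item_ids[j] for j in np.flatnonzero(item.d < 0)]
        warnings.warn(f"negative discrimination (non-monotone) for items: {bad}",
                      stacklevel=2)

    jac_rank = None
    if opts["check_identification"]:
        rank, n_free, full = check_local_identification(spec, item, attr)
        jac_rank = (rank, n_free)
        if not full:
            logger.warning("Jacobian rank %d < %d free parameters: model not "
                           "locally identified at the estimate", rank, n_free)

    logger.info(
        "final: loglik %.4f, %d params, AIC %.2f, BIC %.2f, converged=%s",
        loglik, n_params, aic, bic, converged,
    )
    return FitResult(
        spec=spec,
        item_params=item,
        attr_params=attr,
        std_errors=std_errors,
        loglik=loglik,
        n_params=n_params,
        n_persons=data.n_persons,
        aic=aic,
        bic=bic,
        converged=converged,
        n_starts_used=len(starts),
        best_start_seed=best_idx,
        em_history=best["history"],
        grad_norm=grad_norm,
        jacobian_rank=jac_rank,
        posterior_cache={
            "attribute_posteriors": est["post_attr"],
            "loglik_i": est["loglik_i"],
        },
        options=opts,
    )


# ---------------------------------------------------------------------------
# local identification


def check_local_identification(
    spec: ModelSpec,
    item_params: ItemParameters,
    attr_params: AttributeGrowthParameters,
    tol: float = 1e-7,
    seed: int = 0,
    step: float = 1e-5,
) -> tuple[int, int, bool]:
    """Numerical rank of the Jacobian of response-pattern probabilities.

    Differentiates the map from free parameters to the probabilities of
    complete response arrays (all ``2**(J*T)`` arrays when that is at most
    65536, i.e. J*T <= 16, else a seeded random subsample of at least four
    arrays per free parameter).  Full column rank at the estimate is the
    standard local-identification condition for latent class regression
    models.  Returns ``(rank, n_free, full_rank)``.
    """
    layout = ParamLayout(spec)
    J = spec.qmatrix.n_items
    T = spec.time_coding.n_occasions
    n_free = layout.n_free
    rng = np.random.default_rng(seed)
    if J * T <= 16:
        arrays = (
            (np.arange(2 ** (J * T))[:, None] >> np.arange(J * T)[None, :]) & 1
        ).astype(float)
    else:
        m = max(4 * n_free, 64)
        arrays = (rng.random((m, J * T)) < 0.5).astype(float)
    arrays = arrays.reshape(arrays.shape[0], T, J)
    zvals = np.array([0.0, 1.0]) if spec.has_covariate else np.array([0.0])
    n_arr = arrays.shape[0]
    zcol = np.tile(zvals, int(np.ceil(n_arr / zvals.size)))[:n_arr]
    data = LongitudinalResponses(
        y=arrays, occasion_codes=spec.time_coding.codes,
        z=zcol if spec.has_covariate else None,
    )
    engine = _make_engine(spec, data)
    theta0 = layout.pack(item_params, attr_params)

    def probs(theta):
        itm, att = layout.unpack(theta)
        return np.exp(engine.estep(itm, att)["loglik_i"])

    jac = np.empty((n_arr, n_free))
    for p in range(n_free):
        up, dn = theta0.copy(), theta0.copy()
        up[p] += step
        dn[p] -= step
        jac[:, p] = (probs(up) - probs(dn)) / (2 * step)
    sv = np.linalg.svd(jac, compute_uv=False)
    rank = int(np.sum(sv > tol * sv[0])) if sv.size else 0
    return rank, n_free, rank == n_free
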