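"""Deterministic model mathematics for latent growth cognitive diagnostic models.

The measurement layer is the reparameterized DINA (RDINA): an item ``j`` is
answerable (``eta = 1``) only if the respondent masters every attribute the
Q-matrix requires for it, and the response probability is

    logit P(Y_ij = 1 | eta_ij) = f_j + d_j * eta_ij

with ``f_j`` the false-alarm logit and ``d_j`` the discrimination logit.  The
classical DINA guessing and slip parameters are the inverse-logit transforms
``g_j = logistic(f_j)`` and ``s_j = 1 - logistic(f_j + d_j)``.

The structural layer places a latent growth curve on each attribute-mastery
logit: a fixed difficulty per attribute, person-level random intercept and
slope factors (standard normal, entering through free loading parameters),
an optional treatment covariate shifting the difficulty and the loadings, and
a time-specific standard-normal disturbance:

    logit P(alpha_itk = 1) = b_k + h_k z_i
                             + (sigma0 + h0 z_i) * u_i
                             + (mu1 + (sigma1 + h1 z_i) * v_i) * t
                             + eps_sd * eps_itk

with ``u_i, v_i ~ N(0, 1)``.  The loadings ``sigma0``/``sigma1`` are the
random-intercept and random-slope scales; ``h0``/``h1`` are the covariate
shifts of those scales; ``h_k`` is the attribute-level covariate main effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit as _logit

__all__ = [
    "QMatrix",
    "AttributePattern",
    "ItemParameters",
    "AttributeGrowthParameters",
    "ItemGrowthParameters",
    "PersonRandomEffects",
    "TimeCoding",
    "QuadratureRule",
    "attribute_patterns",
    "ideal_response",
    "ideal_response_table",
    "rdina_response_prob",
    "guess_slip",
    "item_params_from_guess_slip",
    "attribute_logit",
    "marginal_attribute_prob",
    "pattern_prob",
    "pattern_prob_table",
    "item_growth_logit",
]


@dataclass(frozen=True)
class QMatrix:
    """Binary item-by-attribute loading structure.

    ``entries[j, k] = 1`` when item ``j`` requires attribute ``k``.
    """

    entries: np.ndarray
    item_ids: tuple[str, ...] = ()
    attribute_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=int)
        if entries.ndim != 2:
            raise ValueError("Q-matrix must be two-dimensional (items x attributes)")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0 or 1")
        if (entries.sum(axis=1) == 0).any():
            bad = int(np.flatnonzero(entries.sum(axis=1) == 0)[0])
            raise ValueError(f"item row {bad} of the Q-matrix requires no attribute")
        object.__setattr__(self, "entries", entries)
        J, K = entries.shape
        if J < K:
            warnings.warn(
                f"Q-matrix has fewer items ({J}) than attributes ({K}); "
                "the model is unlikely to be identified",
                stacklevel=2,
            )
        if not self.item_ids:
            object.__setattr__(self, "item_ids", tuple(f"Y{j + 1}" for j in range(J)))
        if not self.attribute_ids:
            object.__setattr__(
                self, "attribute_ids", tuple(f"a{k + 1}" for k in range(K))
            )
        if len(self.item_ids) != J or len(self.attribute_ids) != K:
            raise ValueError("label lengths do not match Q-matrix shape")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class AttributePattern:
    """A single binary mastery profile alpha = (alpha_1, ..., alpha_K)."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=int)
        if alpha.ndim != 1 or not np.isin(alpha, (0, 1)).all():
            raise ValueError("attribute pattern must be a binary vector")
        object.__setattr__(self, "alpha", alpha)


def attribute_patterns(n_attributes: int) -> np.ndarray:
    """All ``2**K`` mastery profiles as a ``(2**K, K)`` binary array.

    Pattern ``c`` holds the binary expansion of ``c`` with attribute 0 as the
    most significant bit, so pattern 0 is the null profile and the last
    pattern is full mastery.
    """
    if n_attributes < 1:
        raise ValueError("need at least one attribute")
    c = np.arange(2**n_attributes)
    shifts = n_attributes - 1 - np.arange(n_attributes)
    return ((c[:, None] >> shifts[None, :]) & 1).astype(int)


@dataclass(frozen=True)
class ItemParameters:
    """Per-item RDINA parameters on the logit scale.

    ``f`` is the false-alarm logit, ``d`` the discrimination logit, and ``l``
    an optional per-item covariate effect (logit units per covariate unit).
    Negative ``d`` values are legal (RDINA places no monotonicity constraint)
    but flag a non-monotone item.
    """

    f: np.ndarray
    d: np.ndarray
    l: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.f, dtype=float))
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if f.shape != d.shape:
            raise ValueError("f and d must have the same length")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "d", d)
        if self.l is not None:
            l = np.atleast_1d(np.asarray(self.l, dtype=float))
            if l.shape != f.shape:
                raise ValueError("l must have the same length as f")
            object.__setattr__(self, "l", l)

    @property
    def n_items(self) -> int:
        return self.f.shape[0]

    def monotone(self) -> np.ndarray:
        """Boolean mask of items with nonnegative discrimination."""
        return self.d >= 0


@dataclass(frozen=True)
class AttributeGrowthParameters:
    """Attribute-level growth-curve parameters.

    ``b``        attribute difficulty intercepts (logit units, length K)
    ``sigma0``   random-intercept loading (SD of the intercept effect)
    ``sigma1``   random-slope loading (SD of the growth-rate effect)
    ``h``        attribute-level covariate main effects (length K)
    ``h0``       covariate shift of the random-intercept loading
    ``h1``       covariate shift of the random-slope loading
    ``mu0/mu1``  fixed means of the latent intercept/slope factors; the
                 factors are standard normal for identification, so these
                 default to zero (``mu1`` can carry a fixed mean growth rate
                 in extensions)
    ``eps_sd``   SD of the time-specific disturbance (1 by default, 0 for the
                 documented fast mode without the extra mixing layer)
    """

    b: np.ndarray
    sigma0: float = 1.0
    sigma1: float = 1.0
    h: np.ndarray | None = None
    h0: float = 0.0
    h1: float = 0.0
    mu0: float = 0.0
    mu1: float = 0.0
    eps_sd: float = 1.0

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        object.__setattr__(self, "b", b)
        if self.h is None:
            object.__setattr__(self, "h", np.zeros_like(b))
        else:
            h = np.atleast_1d(np.asarray(self.h, dtype=float))
            if h.shape != b.shape:
                raise ValueError("h must have the same length as b")
            object.__setattr__(self, "h", h)
        # loadings may be negative (sign-equivalent under the symmetric
        # factors); only the disturbance SD must be a true scale
        if self.eps_sd < 0:
            raise ValueError("eps_sd must be nonnegative")

    @property
    def n_attributes(self) -> int:
        return self.b.shape[0]

    @property
    def is_unconditional(self) -> bool:
        return (
            bool(np.all(self.h == 0.0)) and self.h0 == 0.0 and self.h1 == 0.0
        )


@dataclass(frozen=True)
class ItemGrowthParameters:
    """Item-level growth parameters (simulation/extension only; no estimator)."""

    rho: np.ndarray
    xi_mean: float = 0.0
    xi_sd: float = 1.0
    phi_sd: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rho", np.atleast_1d(np.asarray(self.rho, dtype=float))
        )


@dataclass(frozen=True)
class PersonRandomEffects:
    """Standard-normal person deviates; covariate shifts live in the logit ops."""

    zeta: float
    gamma: float


@dataclass(frozen=True)
class TimeCoding:
    """Numeric codes per measurement occasion; baseline (pretest) coded 0."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.atleast_1d(np.asarray(self.codes, dtype=float))
        if codes[0] != 0.0:
            raise ValueError("first occasion must be coded 0 (pretest baseline)")
        if codes.size > 1 and not np.all(np.diff(codes) > 0):
            raise ValueError("occasion codes must be strictly increasing")
        object.__setattr__(self, "codes", codes)

    @property
    def n_occasions(self) -> int:
        return self.codes.shape[0]


@dataclass(frozen=True)
class QuadratureRule:
    """Normalized quadrature rule for N(0, 1) expectations."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.size == 0:
            raise ValueError("quadrature rule must have at least one node")
        if nodes.shape != weights.shape:
            raise ValueError("nodes and weights must have the same shape")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / weights.sum())

    @classmethod
    def gauss_hermite(cls, n_nodes: int) -> "QuadratureRule":
        """Gauss-Hermite rule rescaled so that weights sum to one and nodes
        are on the standard-normal scale (probabilists' convention)."""
        x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
        return cls(nodes=x, weights=w / w.sum())

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


def ideal_response(pattern: AttributePattern | np.ndarray, q_row: np.ndarray) -> int:
    """Conjunctive ideal response: 1 iff every required attribute is mastered."""
    alpha = pattern.alpha if isinstance(pattern, AttributePattern) else np.asarray(pattern)
    q_row = np.asarray(q_row)
    if alpha.shape != q_row.shape:
        raise ValueError(
            f"pattern length {alpha.shape} does not match Q-matrix row {q_row.shape}"
        )
    return int(np.all(alpha >= q_row))


def ideal_response_table(qmatrix: QMatrix) -> np.ndarray:
    """``(2**K, J)`` table of ideal responses for every pattern and item."""
    patterns = attribute_patterns(qmatrix.n_attributes)
    # eta[c, j] = 1 iff pattern c covers all attributes required by item j
    return (patterns @ qmatrix.entries.T == qmatrix.entries.sum(axis=1)).astype(int)


def rdina_response_prob(
    item: ItemParameters,
    j: int,
    eta: int | np.ndarray,
    z: float | None = None,
) -> float | np.ndarray:
    """RDINA response probability ``logistic(f_j + d_j eta [+ l_j z])``."""
    if not 0 <= j < item.n_items:
        raise IndexError(f"item index {j} out of range")
    lin = item.f[j] + item.d[j] * np.asarray(eta, dtype=float)
    if z is not None:
        if item.l is None:
            raise ValueError(
                "covariate value supplied but the item has no covariate effect l"
            )
        lin = lin + item.l[j] * z
    out = expit(lin)
    return float(out) if np.ndim(out) == 0 else out


def guess_slip(item: ItemParameters) -> tuple[np.ndarray, np.ndarray]:
    """Classical DINA guessing and slip from the RDINA logits."""
    g = expit(item.f)
    s = 1.0 - expit(item.f + item.d)
    return g, s


def item_params_from_guess_slip(g: np.ndarray, s: np.ndarray) -> ItemParameters:
    """Inverse transform: ``f = logit(g)``, ``d = logit(1 - s) - logit(g)``."""
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    f = _logit(g)
    d = _logit(1.0 - s) - f
    return ItemParameters(f=f, d=d)


def attribute_logit(
    params: AttributeGrowthParameters,
    k: int,
    t: float,
    z: float = 0.0,
    zeta: float = 0.0,
    gamma: float = 0.0,
    eps: float = 0.0,
) -> float:
    """Attribute-mastery logit at time ``t`` for given person deviates.

    ``zeta``/``gamma``/``eps`` are on the standard-normal scale; the covariate
    shifts the difficulty (through ``h_k``) and the random-effect loadings
    (through ``h0``/``h1``).  With ``z = 0`` and all covariate effects zero
    this reduces exactly to the unconditional growth logit.
    """
    load0 = params.sigma0 + params.h0 * z
    load1 = params.sigma1 + params.h1 * z
    return float(
        params.b[k]
        + params.h[k] * z
        + params.mu0
        + load0 * zeta
        + (params.mu1 + load1 * gamma) * t
        + params.eps_sd * eps
    )


def _total_sd(params: AttributeGrowthParameters, t: float, z: float) -> float:
    load0 = params.sigma0 + params.h0 * z
    load1 = (params.sigma1 + params.h1 * z) * t
    return float(np.sqrt(load0**2 + load1**2 + params.eps_sd**2))


def marginal_attribute_prob(
    params: AttributeGrowthParameters,
    k: int,
    t: float,
    z: float = 0.0,
    quad: QuadratureRule | None = None,
) -> float:
    """Population mastery probability after integrating out all deviates.

    The random intercept, scaled slope and time disturbance are independent
    normals, so their sum is a single normal with the combined SD and the
    three-dimensional expectation collapses to a one-dimensional quadrature.
    """
    if quad is None:
        quad = QuadratureRule.gauss_hermite(41)
    if quad.n_nodes < 3:
        raise ValueError("marginal_attribute_prob needs at least 3 quadrature nodes")
    mean = attribute_logit(params, k, t, z)  # deviates at zero
    sd = _total_sd(params, t, z)
    if sd == 0.0:
        return float(expit(mean))
    return float(quad.weights @ expit(mean + sd * quad.nodes))


def pattern_prob(
    attr_probs: np.ndarray, pattern: AttributePattern | np.ndarray
) -> float:
    """Probability of one mastery profile under attribute independence."""
    alpha = pattern.alpha if isinstance(pattern, AttributePattern) else np.asarray(pattern)
    p = np.asarray(attr_probs, dtype=float)
    return float(np.prod(np.where(alpha == 1, p, 1.0 - p)))


def pattern_prob_table(attr_probs: np.ndarray) -> np.ndarray:
    """Probabilities of all ``2**K`` profiles, in ``attribute_patterns`` order."""
    p = np.asarray(attr_probs, dtype=float)
    patterns = attribute_patterns(p.shape[0])
    with np.errstate(divide="ignore"):
        logp = patterns @ np.log(np.clip(p, 1e-300, None)) + (1 - patterns) @ np.log(
            np.clip(1.0 - p, 1e-300, None)
        )
    return np.exp(logp)


def item_growth_logit(
    params: ItemGrowthParameters,
    item: ItemParameters,
    j: int,
    eta: int,
    t: float,
    xi: float = 0.0,
    phi: float = 0.0,
) -> float:
    """Item-level growth linear predictor (simulation/extension only).

    Adds an item time slope and person-by-item random intercept to the RDINA
    logit; no estimator is attached to this variant.
    """
    if not 0 <= j < item.n_items:
        raise IndexError(f"item index {j} out of range")
    return float(
        item.f[j]
        + item.d[j] * eta
        + params.rho[j % params.rho.shape[0]] * t
        + params.xi_mean
        + params.xi_sd * xi
        + params.phi_sd * phi
    )
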