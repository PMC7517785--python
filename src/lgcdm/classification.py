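"""Posterior attribute classification and classification-quality statistics.

Two statistics summarize how well the fitted model separates masters from
non-masters of each attribute:

* ``P_c`` — the expected proportion of cases correctly classified by the
  maximum-posterior rule, i.e. the frequency-weighted mean over unique
  response patterns of ``max(p, 1 - p)`` where ``p`` is the posterior mastery
  probability of the attribute given the pattern.
* ``lambda`` — the chance-corrected version, ``(P_c - m) / (1 - m)`` with
  ``m`` the larger of the two marginal class shares; it is the relative
  reduction in classification error over assigning every case to the modal
  class.

A "case" is one person at one measurement occasion; statistics average over
occasions weighted by case counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult, LongitudinalResponses, _make_engine
from .model_core import QuadratureRule, marginal_attribute_prob

__all__ = [
    "ClassificationReport",
    "posterior_attribute_probs",
    "proportion_correct",
    "lambda_stat",
    "attribute_prevalence",
    "classification_report",
]


@dataclass
class ClassificationReport:
    """Per-attribute classification quality plus per-case MAP profiles."""

    pc: np.ndarray
    lam: np.ndarray
    prevalence: np.ndarray
    map_patterns: np.ndarray
    pattern_table: pd.DataFrame
    n_posterior_ties: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pc": self.pc, "lambda": self.lam, "prevalence": self.prevalence},
            index=[f"a{k + 1}" for k in range(self.pc.shape[0])],
        )


def posterior_attribute_probs(
    fit: FitResult, data: LongitudinalResponses
) -> np.ndarray:
    """Posterior mastery probabilities, persons x occasions x attributes.

    Conditions on the person's complete response array (all occasions), so
    information flows across occasions through the shared random effects.
    """
    engine = _make_engine(fit.spec, data)
    est = engine.estep(fit.item_params, fit.attr_params)
    return est["post_attr"]


def proportion_correct(pattern_table: pd.DataFrame) -> np.ndarray:
    """Frequency-weighted P_c per attribute from a pattern table.

    The table must have an ``n`` column of pattern frequencies and one
    ``max_post_a{k}`` column per attribute holding max(p, 1-p) for that
    pattern.
    """
    if len(pattern_table) == 0 or pattern_table["n"].sum() == 0:
        raise ValueError("empty pattern table")
    cols = [c for c in pattern_table.columns if c.startswith("max_post_")]
    n = pattern_table["n"].to_numpy(dtype=float)
    return np.array(
        [float(n @ pattern_table[c].to_numpy() / n.sum()) for c in cols]
    )


def lambda_stat(pc: float, prevalence_k: float) -> float:
    """Chance-corrected classification quality for one attribute."""
    m = max(prevalence_k, 1.0 - prevalence_k)
    if m >= 1.0:
        warnings.warn("degenerate prevalence; lambda undefined", stacklevel=2)
        return float("nan")
    return (pc - m) / (1.0 - m)


def attribute_prevalence(fit: FitResult, data: LongitudinalResponses | None = None) -> np.ndarray:
    """Model-implied marginal mastery probability per attribute.

    Integrates the random effects and disturbance by quadrature and averages
    over measurement occasions and the empirical covariate distribution.
    """
    spec = fit.spec
    attr = fit.attr_params
    if spec.has_covariate:
        if data is None or data.z is None:
            zvals, zw = np.array([0.0, 1.0]), np.array([0.5, 0.5])
        else:
            zvals, counts = np.unique(data.z, return_counts=True)
            zw = counts / counts.sum()
    else:
        zvals, zw = np.array([0.0]), np.array([1.0])
    quad = QuadratureRule.gauss_hermite(41)
    K = attr.n_attributes
    tcodes = spec.time_coding.codes
    prev = np.zeros(K)
    for k in range(K):
        vals = [
            zw[i] * marginal_attribute_prob(attr, k, t, z, quad)
            for t in tcodes
            for i, z in enumerate(zvals)
        ]
        prev[k] = np.sum(vals) / tcodes.shape[0]
    return prev


def classification_report(
    fit: FitResult, data: LongitudinalResponses
) -> ClassificationReport:
    """Full classification summary for a fitted model on its data."""
    post = posterior_attribute_probs(fit, data)            # (n, T, K)
    n, T, K = post.shape
    maxpost = np.maximum(post, 1.0 - post)
    ties = int(np.sum(post == 0.5))
    if ties:
        warnings.warn(
            f"{ties} posterior(s) exactly 0.5 classified as non-mastery",
            stacklevel=2,
        )
    map_patterns = (post > 0.5).astype(int)

    # unique (covariate, response-array) patterns; cases are person-occasions
    keys = []
    for i in range(n):
        z_i = float(data.z[i]) if data.z is not None else 0.0
        keys.append((z_i, data.y[i].tobytes()))
    frame = pd.DataFrame({"key": keys})
    frame["n"] = T  # each person contributes one case per occasion
    for k in range(K):
        # occasion-averaged max-posterior for this person's pattern
        frame[f"max_post_a{k}"] = maxpost[:, :, k].mean(axis=1)
    pattern_table = (
        frame.groupby("key", sort=False)
        .agg(n=("n", "sum"), **{
            f"max_post_a{k}": (f"max_post_a{k}", "mean") for k in range(K)
        })
        .reset_index(drop=True)
    )

    pc = proportion_correct(pattern_table)
    prev = attribute_prevalence(fit, data)
    lam = np.array([lambda_stat(pc[k], prev[k]) for k in range(K)])
    return ClassificationReport(
        pc=pc,
        lam=lam,
        prevalence=prev,
        map_patterns=map_patterns,
        pattern_table=pattern_table,
        n_posterior_ties=ties,
    )
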