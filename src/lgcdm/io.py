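"""Readers and writers for responses, Q-matrices, parameters and fit results.

File conventions: CSV, UTF-8, comma-separated, "." decimal, missing marker
"NA".  Person and item orderings are canonicalized lexicographically by id so
that pattern-table collapsing and downstream statistics are deterministic.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimation import (
    FitResult,
    LongitudinalResponses,
    ModelSpec,
    ParamLayout,
)
from .model_core import (
    AttributeGrowthParameters,
    ItemParameters,
    QMatrix,
    TimeCoding,
)

__all__ = [
    "read_responses",
    "write_responses",
    "read_qmatrix",
    "write_qmatrix",
    "read_covariates",
    "read_params",
    "write_params",
    "write_fit",
    "read_fit",
]

_NA = "NA"


def _validate_binary(series: pd.Series, path) -> None:
    bad = series.dropna()
    bad = bad[~bad.isin([0.0, 1.0])]
    if len(bad):
        row = int(bad.index[0])
        raise ValueError(
            f"{path}: non-binary response value {bad.iloc[0]!r} at row {row + 2}"
        )


def read_responses(path, layout: str = "long") -> LongitudinalResponses:
    """Read longitudinal binary responses from CSV.

    ``long`` layout: columns (person_id, time, item_id, response).
    ``wide`` layout: columns (person_id, time, <item columns...>), one row
    per person-occasion.  Persons and items are ordered lexicographically by
    id; missing responses are the string "NA" or empty cells.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=[_NA], keep_default_na=True)
    if layout == "long":
        required = {"person_id", "time", "item_id", "response"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: long layout needs columns {sorted(missing)}")
        dup = df.duplicated(subset=["person_id", "time", "item_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValueError(
                f"{path}: duplicate (person, time, item) entry at row {row + 2}"
            )
        _validate_binary(df["response"], path)
        persons = sorted(df["person_id"].astype(str).unique())
        items = sorted(df["item_id"].astype(str).unique())
        times = np.sort(df["time"].unique())
        pidx = {p: i for i, p in enumerate(persons)}
        iidx = {s: j for j, s in enumerate(items)}
        tidx = {t: k for k, t in enumerate(times)}
        y = np.full((len(persons), len(times), len(items)), np.nan)
        y[
            df["person_id"].astype(str).map(pidx),
            df["time"].map(tidx),
            df["item_id"].astype(str).map(iidx),
        ] = df["response"].to_numpy(dtype=float)
    elif layout == "wide":
        if "person_id" not in df.columns or "time" not in df.columns:
            raise ValueError(f"{path}: wide layout needs person_id and time columns")
        item_cols = [c for c in df.columns if c not in ("person_id", "time")]
        items = sorted(item_cols)
        for c in items:
            _validate_binary(df[c], path)
        dup = df.duplicated(subset=["person_id", "time"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValueError(f"{path}: duplicate (person, time) row at {row + 2}")
        persons = sorted(df["person_id"].astype(str).unique())
        times = np.sort(df["time"].unique())
        pidx = {p: i for i, p in enumerate(persons)}
        tidx = {t: k for k, t in enumerate(times)}
        y = np.full((len(persons), len(times), len(items)), np.nan)
        rows = df["person_id"].astype(str).map(pidx).to_numpy()
        occ = df["time"].map(tidx).to_numpy()
        y[rows, occ] = df[items].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'long' or 'wide'")
    codes = np.asarray(times, dtype=float)
    codes = codes - codes[0]  # baseline coded 0
    return LongitudinalResponses(
        y=y, occasion_codes=codes, person_ids=tuple(persons)
    )


def write_responses(data: LongitudinalResponses, path, layout: str = "long") -> None:
    path = Path(path)
    n, T, J = data.y.shape
    items = [f"Y{j + 1}" for j in range(J)]
    if layout == "long":
        rows = []
        for i, pid in enumerate(data.person_ids):
            for t in range(T):
                for j in range(J):
                    v = data.y[i, t, j]
                    rows.append(
                        (pid, data.occasion_codes[t], items[j],
                         _NA if not np.isfinite(v) else int(v))
                    )
        pd.DataFrame(rows, columns=["person_id", "time", "item_id", "response"]).to_csv(
            path, index=False
        )
    elif layout == "wide":
        recs = []
        for i, pid in enumerate(data.person_ids):
            for t in range(T):
                rec = {"person_id": pid, "time": data.occasion_codes[t]}
                for j in range(J):
                    v = data.y[i, t, j]
                    rec[items[j]] = _NA if not np.isfinite(v) else int(v)
                recs.append(rec)
        pd.DataFrame(recs).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_qmatrix(path) -> QMatrix:
    """Q-matrix CSV: first column item id, remaining columns 0/1 per attribute."""
    df = pd.read_csv(path)
    item_col = df.columns[0]
    attrs = list(df.columns[1:])
    entries = df[attrs].to_numpy(dtype=int)
    return QMatrix(
        entries=entries,
        item_ids=tuple(df[item_col].astype(str)),
        attribute_ids=tuple(attrs),
    )


def write_qmatrix(q: QMatrix, path) -> None:
    df = pd.DataFrame(q.entries, columns=list(q.attribute_ids))
    df.insert(0, "item_id", list(q.item_ids))
    df.to_csv(path, index=False)


def read_covariates(path, person_ids: tuple) -> np.ndarray:
    """Person-level covariate CSV with columns (person_id, <covariate>)."""
    df = pd.read_csv(path)
    if "person_id" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: need person_id plus one covariate column")
    cov = df.columns[1]
    lookup = dict(zip(df["person_id"].astype(str), df[cov].astype(float)))
    missing = [p for p in person_ids if str(p) not in lookup]
    if missing:
        raise ValueError(f"{path}: no covariate value for persons {missing[:5]}")
    return np.array([lookup[str(p)] for p in person_ids])


def write_params(item: ItemParameters, attr: AttributeGrowthParameters, path) -> None:
    """Parameter JSON with named blocks."""
    blob = {
        "item": {"f": item.f.tolist(), "d": item.d.tolist()},
        "attribute": {
            "b": attr.b.tolist(), "h": attr.h.tolist(),
            "sigma0": attr.sigma0, "sigma1": attr.sigma1,
            "h0": attr.h0, "h1": attr.h1,
            "mu0": attr.mu0, "mu1": attr.mu1, "eps_sd": attr.eps_sd,
        },
    }
    if item.l is not None:
        blob["item"]["l"] = item.l.tolist()
    Path(path).write_text(json.dumps(blob, indent=1))


def read_params(path) -> tuple[ItemParameters, AttributeGrowthParameters]:
    blob = json.loads(Path(path).read_text())
    it = blob["item"]
    at = blob["attribute"]
    item = ItemParameters(
        f=np.array(it["f"]), d=np.array(it["d"]),
        l=np.array(it["l"]) if "l" in it else None,
    )
    attr = AttributeGrowthParameters(
        b=np.array(at["b"]), h=np.array(at.get("h", np.zeros(len(at["b"])))),
        sigma0=at.get("sigma0", 0.0), sigma1=at.get("sigma1", 0.0),
        h0=at.get("h0", 0.0), h1=at.get("h1", 0.0),
        mu0=at.get("mu0", 0.0), mu1=at.get("mu1", 0.0),
        eps_sd=at.get("eps_sd", 0.0),
    )
    return item, attr


def _spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "family": spec.family,
        "qmatrix": {
            "entries": spec.qmatrix.entries.tolist(),
            "item_ids": list(spec.qmatrix.item_ids),
            "attribute_ids": list(spec.qmatrix.attribute_ids),
        },
        "time_codes": spec.time_coding.codes.tolist(),
        "covariate_names": list(spec.covariate_names),
        "estimation": spec.estimation,
        "quadrature": spec.quadrature,
        "constraints": {k: np.asarray(v).tolist() for k, v in spec.constraints.items()},
        "eps_sd": spec.eps_sd,
    }


def _spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        family=d["family"],
        qmatrix=QMatrix(
            entries=np.array(d["qmatrix"]["entries"]),
            item_ids=tuple(d["qmatrix"]["item_ids"]),
            attribute_ids=tuple(d["qmatrix"]["attribute_ids"]),
        ),
        time_coding=TimeCoding(np.array(d["time_codes"])),
        covariate_names=tuple(d["covariate_names"]),
        estimation=d["estimation"],
        quadrature=d["quadrature"],
        constraints={k: np.array(v) for k, v in d.get("constraints", {}).items()},
        eps_sd=d.get("eps_sd", 1.0),
    )


def write_fit(result: FitResult, path) -> None:
    """Serialize a FitResult to JSON at full numeric precision."""
    se = result.std_errors.get("free")
    blob = {
        "version": __version__,
        "spec": _spec_to_dict(result.spec),
        "estimates": {
            "item": {"f": result.item_params.f.tolist(),
                     "d": result.item_params.d.tolist()},
            "attribute": {
                "b": result.attr_params.b.tolist(),
                "h": result.attr_params.h.tolist(),
                "sigma0": result.attr_params.sigma0,
                "sigma1": result.attr_params.sigma1,
                "h0": result.attr_params.h0,
                "h1": result.attr_params.h1,
                "mu0": result.attr_params.mu0,
                "mu1": result.attr_params.mu1,
                "eps_sd": result.attr_params.eps_sd,
            },
        },
        "std_errors": None if se is None else list(se),
        "param_names": result.std_errors.get("names"),
        "loglik": result.loglik,
        "n_params": result.n_params,
        "n_persons": result.n_persons,
        "aic": result.aic,
        "bic": result.bic,
        "converged": result.converged,
        "n_starts_used": result.n_starts_used,
        "best_start_seed": result.best_start_seed,
        "grad_norm": result.grad_norm,
        "jacobian_rank": result.jacobian_rank,
        "options": {k: v for k, v in result.options.items()
                    if isinstance(v, (int, float, bool, str))},
    }
    Path(path).write_text(json.dumps(blob, indent=1))


def read_fit(path) -> FitResult:
    try:
        blob = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid fit file ({exc})") from None
    if blob.get("version") != __version__:
        warnings.warn(
            f"fit file written by version {blob.get('version')}, "
            f"reading with {__version__}",
            stacklevel=2,
        )
    spec = _spec_from_dict(blob["spec"])
    est = blob["estimates"]
    item = ItemParameters(f=np.array(est["item"]["f"]), d=np.array(est["item"]["d"]))
    at = est["attribute"]
    attr = AttributeGrowthParameters(
        b=np.array(at["b"]), h=np.array(at["h"]), sigma0=at["sigma0"],
        sigma1=at["sigma1"], h0=at["h0"], h1=at["h1"], mu0=at["mu0"],
        mu1=at["mu1"], eps_sd=at["eps_sd"],
    )
    se = blob.get("std_errors")
    return FitResult(
        spec=spec, item_params=item, attr_params=attr,
        std_errors={"free": None if se is None else np.array(se),
                    "names": blob.get("param_names")},
        loglik=blob["loglik"], n_params=blob["n_params"],
        n_persons=blob["n_persons"], aic=blob["aic"], bic=blob["bic"],
        converged=blob["converged"], n_starts_used=blob["n_starts_used"],
        best_start_seed=blob["best_start_seed"], em_history=[],
        grad_norm=blob.get("grad_norm", float("nan")),
        jacobian_rank=tuple(blob["jacobian_rank"]) if blob.get("jacobian_rank") else None,
        options=blob.get("options", {}),
    )
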