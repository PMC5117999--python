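"""Readers and writers for distributions, matrices and time series.

Formats are deliberately plain: JSON for distributions
({"shape": [...], "p": flattened row-major list}), whitespace/comma
delimited text for matrices and series (delimiter auto-detected), JSON
for results.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .discrete import Bipartition, JointDistribution, TwoTimeDistribution, validate_joint
from .gaussian import GaussianSystem, fit_ar
from .measures import PhiResult

__all__ = [
    "read_distribution",
    "write_distribution",
    "read_matrix",
    "write_matrix",
    "read_series",
    "read_system",
    "result_to_dict",
]


def read_distribution(path: str | Path):
    """Load a TwoTimeDistribution or JointDistribution (by rank) from JSON
    or shape-headed delimited text."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        obj = json.loads(text)
        shape = tuple(int(s) for s in obj["shape"])
        p = np.asarray(obj["p"], dtype=float).reshape(shape)
        if "n_bits" in obj and obj["n_bits"] is not None and len(shape) == 2:
            return TwoTimeDistribution(p, n_bits=int(obj["n_bits"]))
        return validate_joint(p)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    shape = tuple(int(s) for s in lines[0].replace(",", " ").split())
    values = np.fromstring(" ".join(lines[1:]).replace(",", " "), sep=" ")
    return validate_joint(values.reshape(shape))


def write_distribution(dist, path: str | Path) -> None:
    path = Path(path)
    p = dist.p
    obj = {"shape": list(p.shape), "p": p.ravel().tolist()}
    if isinstance(dist, TwoTimeDistribution) and dist.n_bits is not None:
        obj["n_bits"] = dist.n_bits
    path.write_text(json.dumps(obj))


def _detect_delimiter(text: str) -> str | None:
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    return "," if "," in first else None


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    text = path.read_text()
    return np.loadtxt(path, delimiter=_detect_delimiter(text))


def write_matrix(M: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(M, dtype=float), delimiter="\t")


def read_series(path: str | Path) -> np.ndarray:
    """Delimited time series: rows = time points, columns = channels."""
    X = read_matrix(path)
    if X.ndim == 1:
        X = X[:, None]
    return X


def read_system(path: str | Path, kind: str):
    """Load a domain object: kind 'joint' (JSON/text distribution),
    'series' (fit an AR system), or 'covariance' (two matrices C, B given
    as 'cpath:bpath' or a directory containing C.tsv and B.tsv)."""
    if kind == "joint":
        return read_distribution(path)
    if kind == "series":
        return fit_ar(read_series(path))
    if kind == "covariance":
        p = Path(path)
        if ":" in str(path) and not p.exists():
            cpath, bpath = str(path).split(":", 1)
        elif p.is_dir():
            cpath, bpath = p / "C.tsv", p / "B.tsv"
        else:
            raise ValueError("covariance input needs 'C:B' paths or a directory")
        return GaussianSystem(C=read_matrix(cpath), B=read_matrix(bpath))
    raise ValueError(f"unknown system kind {kind!r}")


def result_to_dict(res: PhiResult | object, seed: int | None = None) -> dict:
    """JSON-ready dict for a PhiResult or CutSearchResult."""
    def clean(v):
        if isinstance(v, Bipartition):
            return {"part_A": list(v.part_A), "part_B": list(v.part_B)}
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    out = {k: clean(v) for k, v in vars(res).items()}
    if seed is not None:
        out["seed"] = seed
    from . import __version__

    out["version"] = __version__
    return out
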