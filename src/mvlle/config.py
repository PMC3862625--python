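"""Run configuration: validated parameters for the full pipeline.

Defaults follow the parameter study on large radiograph collections:
embedding dimension d=200, patch size K=140, weight exponent r=2.5,
Euclidean neighbor metric, diagnostic k=15.  All bounds owned by the
individual modules are enforced here at load time so a bad configuration
fails before any computation starts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

__all__ = ["ViewDef", "EmbeddingParams", "EvalParams", "RunConfig", "load_config"]

DEFAULT_TOP_N = (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass(frozen=True)
class ViewDef:
    """One feature view: extractor kind plus its parameters."""

    kind: str  # "lbp" | "sift" | "intensity"
    grids: Sequence[int] = (1,)
    words: int = 500  # BoW dictionary size (ignored for lbp)
    iters: int = 100  # K-means iterations (ignored for lbp)

    def __post_init__(self) -> None:
        if self.kind not in ("lbp", "sift", "intensity"):
            raise ValueError(f"view kind must be lbp|sift|intensity, got {self.kind!r}")
        if any(g < 1 for g in self.grids):
            raise ValueError("grids entries must be >= 1")
        if self.kind != "lbp" and self.words < 2:
            raise ValueError("words must be >= 2")


@dataclass(frozen=True)
class EmbeddingParams:
    d: int = 200
    K: int = 140
    r: float = 2.5
    metric: str = "l2"
    reg: float = 0.2
    max_iter: int = 50
    tol: float = 1e-6
    drop_trivial: bool = True

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"d={self.d}: must be >= 1")
        if self.K < 1:
            raise ValueError(f"K={self.K}: must be >= 1")
        if self.r <= 1:
            raise ValueError(
                f"r={self.r}: must be > 1; at r <= 1 the view-weight optimum "
                "collapses onto a single view and the method degenerates to "
                "single-view LLE"
            )
        if self.metric not in ("l2", "l1", "geodesic"):
            raise ValueError(f"metric={self.metric!r}: must be l2|l1|geodesic")
        if self.reg < 0:
            raise ValueError(f"reg={self.reg}: must be >= 0")


@dataclass(frozen=True)
class EvalParams:
    top_n: Sequence[int] = DEFAULT_TOP_N
    k: int = 15
    query_policy: str = "first"

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.top_n):
            raise ValueError("top_n entries must be >= 1")
        if self.k < 1:
            raise ValueError(f"k={self.k}: must be >= 1")
        if self.query_policy not in ("first", "random"):
            raise ValueError("query_policy must be 'first' or 'random'")


def _default_views() -> tuple[ViewDef, ...]:
    return (
        ViewDef(kind="lbp", grids=(3, 4, 5, 6)),
        ViewDef(kind="sift", grids=(1, 2, 3, 4)),
        ViewDef(kind="intensity", grids=(1, 2, 3, 4)),
    )


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    views: tuple[ViewDef, ...] = field(default_factory=_default_views)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    evaluation: EvalParams = field(default_factory=EvalParams)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["views"] = [dict(v, grids=list(v["grids"])) for v in d["views"]]
        d["evaluation"]["top_n"] = list(d["evaluation"]["top_n"])
        return d

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text, encoding="utf-8")
        return path


def _check_keys(data: dict, allowed: set[str], where: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def from_dict(data: dict[str, Any]) -> RunConfig:
    _check_keys(data, {"seed", "views", "embedding", "evaluation"}, "config")
    views: list[ViewDef] = []
    for i, v in enumerate(data.get("views", [])):
        _check_keys(v, {"kind", "grids", "words", "iters"}, f"views[{i}]")
        views.append(ViewDef(**{**v, "grids": tuple(v.get("grids", (1,)))}))
    emb = data.get("embedding", {})
    _check_keys(
        emb,
        {"d", "K", "r", "metric", "reg", "max_iter", "tol", "drop_trivial"},
        "embedding",
    )
    ev = data.get("evaluation", {})
    _check_keys(ev, {"top_n", "k", "query_policy"}, "evaluation")
    if "top_n" in ev:
        ev = {**ev, "top_n": tuple(ev["top_n"])}
    return RunConfig(
        seed=int(data.get("seed", 0)),
        views=tuple(views) if views else _default_views(),
        embedding=EmbeddingParams(**emb),
        evaluation=EvalParams(**ev),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Omitted fields take the documented defaults; unknown keys and
    out-of-range values raise with the offending key named.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    # YAML 1.1 misreads JSON floats like 1e-06 as strings, so dispatch on suffix
    data = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return from_dict(data)
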