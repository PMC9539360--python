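"""Mixed categorical/integer/real search space for IVT reaction conditions.

The in vitro transcription (IVT) reaction is parameterized by 12 quantities:
the magnesium cofactor salt and its concentration, DTT, RNase inhibitor,
NTPs, DNA template, inorganic pyrophosphatase, spermidine, T7 RNA polymerase
activity, temperature, reaction time and initial pH.  The default bounds span
the ranges explored during reaction optimization (e.g. pH 6.5-8, T7 RNAP
1000-50000 U/mL).

Numeric parameters are min-max scaled to [0, 1] before any kernel evaluation
because the raw domains span four orders of magnitude; categorical parameters
are one-hot encoded, one coordinate per level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParamSpec",
    "ParamSpace",
    "ReactionConditions",
    "Violation",
    "build_default_space",
    "load_space",
    "encode",
    "decode",
    "validate",
]


@dataclass(frozen=True)
class ParamSpec:
    """One reaction parameter: a categorical label set or a closed numeric interval."""

    name: str
    kind: str  # "categorical" | "integer" | "real"
    domain: tuple  # labels for categorical, (lo, hi) otherwise
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "integer", "real"):
            raise ValueError(f"unknown parameter kind {self.kind!r} for {self.name!r}")
        object.__setattr__(self, "domain", tuple(self.domain))
        if self.kind == "categorical":
            if len(self.domain) == 0:
                raise ValueError(f"{self.name!r}: empty label set")
            if len(set(self.domain)) != len(self.domain):
                raise ValueError(f"{self.name!r}: duplicate labels")
        else:
            lo, hi = self.domain
            if not lo < hi:
                raise ValueError(f"{self.name!r}: need lo < hi, got [{lo}, {hi}]")

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("integer", "real")

    @property
    def lo(self) -> float:
        return float(self.domain[0])

    @property
    def hi(self) -> float:
        return float(self.domain[1])

    @property
    def width(self) -> int:
        """Number of encoded coordinates this parameter occupies."""
        return len(self.domain) if self.kind == "categorical" else 1

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.domain
        try:
            v = float(value)
        except (TypeError, ValueError):
            return False
        if self.kind == "integer" and float(v) != int(v):
            return False
        return self.lo <= v <= self.hi


@dataclass(frozen=True)
class ParamSpace:
    """Ordered collection of ParamSpecs defining the reaction search domain."""

    specs: tuple[ParamSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in space")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def encoded_dim(self) -> int:
        return sum(s.width for s in self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, name: str) -> ParamSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    def blocks(self) -> list[tuple[ParamSpec, slice]]:
        """Encoded coordinate slice for each parameter, in declaration order."""
        out, i = [], 0
        for s in self.specs:
            out.append((s, slice(i, i + s.width)))
            i += s.width
        return out

    def to_json(self) -> str:
        items = [
            {
                "name": s.name,
                "kind": s.kind,
                "domain": list(s.domain),
                "units": s.units,
            }
            for s in self.specs
        ]
        return json.dumps(items, indent=1)


@dataclass(frozen=True)
class ReactionConditions:
    """A complete assignment of all reaction parameters for one IVT run."""

    values: Mapping[str, object]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str):
        return self.values[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, ReactionConditions) and self.values == other.values

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.values.items())))


@dataclass(frozen=True)
class Violation:
    """One domain violation; violations are data, not exceptions."""

    parameter: str
    value: object
    message: str

    def __str__(self) -> str:
        return f"{self.parameter}={self.value!r}: {self.message}"


# Default 12-parameter IVT space.  DNA template is dosed in nM, enzymes in
# volumetric activity U/mL.  The mRNA yield (g/L) is the evaluation metric,
# not a 13th parameter.
_DEFAULT_SPECS: tuple[tuple[str, str, tuple, str], ...] = (
    ("cofactor", "categorical", ("MgAcetate", "MgCl2"), ""),
    ("cofactor_mM", "real", (0.0, 100.0), "mM"),
    ("DTT_mM", "real", (0.0, 10.0), "mM"),
    ("RNaseInh_UmL", "integer", (0, 2000), "U/mL"),
    ("NTPs_mM", "real", (1.0, 10.0), "mM"),
    ("DNA_nM", "integer", (10, 100), "nM"),
    ("PPase_UmL", "integer", (0, 10), "U/mL"),
    ("spermidine_mM", "real", (0.0, 10.0), "mM"),
    ("T7_UmL", "integer", (1000, 50000), "U/mL"),
    ("temperature_C", "integer", (20, 50), "degC"),
    ("time_min", "integer", (10, 300), "min"),
    ("pH", "real", (6.5, 8.0), ""),
)


def build_default_space() -> ParamSpace:
    """The default 12-parameter IVT reaction space."""
    return ParamSpace(tuple(ParamSpec(n, k, d, u) for n, k, d, u in _DEFAULT_SPECS))


def load_space(path_or_items) -> ParamSpace:
    """Load a ParamSpace from a JSON file path or a parsed list of spec objects."""
    if isinstance(path_or_items, (str, bytes)) or hasattr(path_or_items, "read_text"):
        items = json.loads(
            path_or_items.read_text()
            if hasattr(path_or_items, "read_text")
            else open(path_or_items).read()
        )
    else:
        items = list(path_or_items)
    specs = []
    for it in items:
        dom = tuple(it["domain"])
        specs.append(ParamSpec(it["name"], it["kind"], dom, it.get("units", "")))
    return ParamSpace(tuple(specs))


def default_space_json() -> str:
    """The bundled JSON definition of the default space."""
    return resources.files("ivtbo.data").joinpath("default_space.json").read_text()


def validate(c: ReactionConditions, s: ParamSpace) -> list[Violation]:
    """All domain violations of ``c`` against ``s``; empty list means valid."""
    out: list[Violation] = []
    for spec in s.specs:
        if spec.name not in c.values:
            out.append(Violation(spec.name, None, "missing parameter"))
            continue
        v = c.values[spec.name]
        if spec.kind == "categorical":
            if v not in spec.domain:
                out.append(
                    Violation(spec.name, v, f"not one of {list(spec.domain)}")
                )
        else:
            if not spec.contains(v):
                out.append(
                    Violation(
                        spec.name,
                        v,
                        f"outside {spec.kind} domain [{spec.domain[0]}, {spec.domain[1]}] {spec.units}".rstrip(),
                    )
                )
    for name in c.values:
        if name not in s:
            out.append(Violation(name, c.values[name], "unknown parameter"))
    return out


def _check_valid(c: ReactionConditions, s: ParamSpace) -> None:
    bad = validate(c, s)
    if bad:
        raise ValueError(
            "invalid reaction conditions: " + "; ".join(str(v) for v in bad)
        )


def encode(c: ReactionConditions, s: ParamSpace) -> np.ndarray:
    """Encode valid conditions to a unit-cube vector of length ``s.encoded_dim``.

    Numeric parameters are min-max scaled; each categorical parameter becomes a
    one-hot block in declared label order.
    """
    _check_valid(c, s)
    x = np.zeros(s.encoded_dim)
    for spec, sl in s.blocks():
        v = c.values[spec.name]
        if spec.kind == "categorical":
            x[sl.start + spec.domain.index(v)] = 1.0
        else:
            x[sl.start] = (float(v) - spec.lo) / (spec.hi - spec.lo)
    return x


def encode_many(conds: Iterable[ReactionConditions], s: ParamSpace) -> np.ndarray:
    return np.array([encode(c, s) for c in conds]).reshape(-1, s.encoded_dim)


def snap_encoded(P: np.ndarray, s: ParamSpace) -> np.ndarray:
    """Vectorized decode-then-encode round trip on rows of encoded points.

    Clips coordinates to [0, 1], rounds integer parameters onto their grid and
    collapses categorical blocks to exact one-hot (argmax), so every returned
    row equals ``encode(decode(row))`` without building condition objects.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[1] != s.encoded_dim:
        raise ValueError(f"expected {s.encoded_dim} columns, got {P.shape[1]}")
    out = np.clip(P, 0.0, 1.0)
    for spec, sl in s.blocks():
        if spec.kind == "categorical":
            block = np.zeros((len(P), spec.width))
            block[np.arange(len(P)), np.argmax(P[:, sl], axis=1)] = 1.0
            out[:, sl] = block
        elif spec.kind == "integer":
            span = spec.hi - spec.lo
            vals = np.clip(np.round(out[:, sl.start] * span), 0, span)
            out[:, sl.start] = vals / span
    return out


def decode(p: Sequence[float], s: ParamSpace) -> ReactionConditions:
    """Decode an encoded point back to reaction conditions.

    Accepts relaxed points (coordinates outside [0,1], non-one-hot categorical
    blocks, as produced by acquisition search): numeric coordinates are clipped
    to bounds, integers rounded to nearest, categoricals decoded by block argmax.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (s.encoded_dim,):
        raise ValueError(
            f"encoded point has shape {p.shape}, expected ({s.encoded_dim},)"
        )
    vals: dict[str, object] = {}
    for spec, sl in s.blocks():
        if spec.kind == "categorical":
            vals[spec.name] = spec.domain[int(np.argmax(p[sl]))]
        else:
            raw = spec.lo + float(np.clip(p[sl.start], 0.0, 1.0)) * (spec.hi - spec.lo)
            if spec.kind == "integer":
                vals[spec.name] = int(np.clip(round(raw), spec.lo, spec.hi))
            else:
                vals[spec.name] = raw
    return ReactionConditions(vals)
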