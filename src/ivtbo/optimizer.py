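"""Closed-loop Bayesian optimization of IVT yield.

The loop: seed the design with LHS conditions, measure them, then repeatedly
refit the GP surrogate on the full experiment log, propose an EI batch of 3-5
conditions, measure, and append — until the evaluation budget is exhausted or
the best yield plateaus.  The append-only experiment log (CSV on disk) is the
single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import gp
from .acquisition import BatchProposal, propose_batch
from .design import lhs_sample
from .space import (
    ParamSpace,
    ReactionConditions,
    build_default_space,
    encode_many,
    validate,
)

__all__ = [
    "Observation",
    "ExperimentLog",
    "StoppingRule",
    "initialize",
    "step",
    "record",
    "stopped",
    "best_so_far_trace",
    "run_closed_loop",
    "random_search_baseline",
]

CSV_COLUMNS = [
    "batch_id",
    "source",
    "cofactor",
    "cofactor_mM",
    "DTT_mM",
    "RNaseInh_UmL",
    "NTPs_mM",
    "DNA_nM",
    "PPase_UmL",
    "spermidine_mM",
    "T7_UmL",
    "temperature_C",
    "time_min",
    "pH",
    "yield_gL",
    "replicate_sd_gL",
]


@dataclass(frozen=True)
class Observation:
    """One evaluated reaction: conditions, measured yield, provenance."""

    conditions: ReactionConditions
    yield_gL: float
    batch_id: int
    source: str  # "lhs" | "bo" | "manual"
    replicate_sd: float | None = None

    def __post_init__(self) -> None:
        if self.yield_gL < 0:
            raise ValueError("yield must be non-negative")
        if self.batch_id < 0:
            raise ValueError("batch_id must be non-negative")
        if self.source not in ("lhs", "bo", "manual"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class ExperimentLog:
    """Append-only ordered sequence of observations over one space."""

    space: ParamSpace
    observations: tuple[Observation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        for ob in self.observations:
            bad = validate(ob.conditions, self.space)
            if bad:
                raise ValueError(
                    f"observation invalid for space: {'; '.join(map(str, bad))}"
                )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def yields(self) -> np.ndarray:
        return np.array([ob.yield_gL for ob in self.observations])

    @property
    def f_max(self) -> float:
        if not self.observations:
            raise ValueError("empty log has no best yield")
        return float(np.max(self.yields))

    @property
    def best(self) -> Observation:
        return self.observations[int(np.argmax(self.yields))]

    def encoded(self) -> np.ndarray:
        return encode_many((ob.conditions for ob in self.observations), self.space)

    def next_batch_id(self) -> int:
        if not self.observations:
            return 0
        return max(ob.batch_id for ob in self.observations) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ob in self.observations:
            row = {"batch_id": ob.batch_id, "source": ob.source}
            row.update(ob.conditions.values)
            row["yield_gL"] = ob.yield_gL
            row["replicate_sd_gL"] = (
                "" if ob.replicate_sd is None else ob.replicate_sd
            )
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, space: ParamSpace | None = None) -> "ExperimentLog":
        space = space or build_default_space()
        df = pd.read_csv(path, float_precision="round_trip")
        obs = []
        for _, row in df.iterrows():
            vals: dict[str, object] = {}
            for spec in space.specs:
                v = row[spec.name]
                if spec.kind == "categorical":
                    vals[spec.name] = str(v)
                elif spec.kind == "integer":
                    vals[spec.name] = int(v)
                else:
                    vals[spec.name] = float(v)
            rsd = row.get("replicate_sd_gL")
            rsd = None if pd.isna(rsd) or rsd == "" else float(rsd)
            obs.append(
                Observation(
                    conditions=ReactionConditions(vals),
                    yield_gL=float(row["yield_gL"]),
                    batch_id=int(row["batch_id"]),
                    source=str(row["source"]),
                    replicate_sd=rsd,
                )
            )
        return cls(space=space, observations=tuple(obs))


@dataclass(frozen=True)
class StoppingRule:
    """Stop at a total evaluation cap or when best-so-far plateaus.

    The plateau clause fires when the best yield improved by less than
    ``min_improvement`` (g/L) over the last ``patience`` evaluations —
    the default 0.5 g/L is on the order of replicate SD.
    """

    max_budget: int = 150
    patience: int = 30
    min_improvement: float = 0.5

    def __post_init__(self) -> None:
        if self.max_budget <= 0 or self.patience <= 0 or self.min_improvement <= 0:
            raise ValueError("stopping-rule fields must be positive")


def initialize(
    s: ParamSpace, n_init: int = 16, seed: int = 0
) -> BatchProposal:
    """Initial LHS design of ``n_init`` reaction conditions (source 'lhs')."""
    conds = lhs_sample(s, n_init, seed)
    return BatchProposal(
        conditions=tuple(conds),
        ei=tuple(float("nan") for _ in conds),
        provenance=tuple("lhs" for _ in conds),
    )


# default GP noise floor: replicate SD of the yield assay, g/L.  Measured
# replicate SDs run 0.2-1.0 g/L; fitting single-replicate logs without a
# floor lets the GP interpolate noise and kills exploration.
REPLICATE_NOISE_SD = 0.5


def _noise_floor(log: ExperimentLog, noise_floor_sd: float | None) -> float:
    if noise_floor_sd is not None:
        return float(noise_floor_sd) ** 2
    sds = [ob.replicate_sd for ob in log.observations if ob.replicate_sd]
    sd = float(np.median(sds)) if sds else REPLICATE_NOISE_SD
    return sd**2


def fit_surrogate(
    log: ExperimentLog,
    seed: int = 0,
    restarts: int = 8,
    noise_floor_sd: float | None = None,
) -> gp.GPModel:
    """Refit the GP surrogate on the full log.

    The observation-noise variance is floored at ``noise_floor_sd`` squared
    (default: the log's median recorded replicate SD, else 0.5 g/L).
    """
    if len(log) < 2:
        raise ValueError("need at least 2 observations; run initialize first")
    return gp.fit(
        log.encoded(),
        log.yields,
        restarts=restarts,
        seed=seed,
        noise_floor_var=_noise_floor(log, noise_floor_sd),
    )


def step(
    log: ExperimentLog,
    batch_size: int = 4,
    seed: int = 0,
    restarts: int = 8,
    pool_size: int = 20000,
    noise_floor_sd: float | None = None,
) -> BatchProposal:
    """One optimization cycle: refit on the log, propose the next EI batch.

    Pure with respect to the log (no mutation); deterministic under
    (log, seed).
    """
    model = fit_surrogate(
        log, seed=seed, restarts=restarts, noise_floor_sd=noise_floor_sd
    )
    return propose_batch(
        model, log.space, log.f_max, batch_size=batch_size, seed=seed,
        pool_size=pool_size,
    )


def record(
    log: ExperimentLog,
    proposals: BatchProposal | Sequence[ReactionConditions],
    yields: Sequence[float],
    replicate_sd: Sequence[float] | None = None,
    source: str | None = None,
) -> ExperimentLog:
    """Append measured yields for (a prefix of) a proposal batch; returns a new log.

    Partial batches are allowed (fewer yields than proposals) — wet-lab runs
    can fail — but the two sequences must align element-wise.
    """
    conds = (
        list(proposals.conditions)
        if isinstance(proposals, BatchProposal)
        else list(proposals)
    )
    if len(yields) > len(conds):
        raise ValueError(
            f"{len(yields)} yields for {len(conds)} proposals — misaligned"
        )
    if replicate_sd is not None and len(replicate_sd) != len(yields):
        raise ValueError("replicate_sd must align with yields")
    if isinstance(proposals, BatchProposal) and source is None:
        source = "lhs" if proposals.provenance[0] == "lhs" else "bo"
    source = source or "manual"
    bid = log.next_batch_id()
    new = [
        Observation(
            conditions=c,
            yield_gL=float(y),
            batch_id=bid,
            source=source,
            replicate_sd=None if replicate_sd is None else float(replicate_sd[i]),
        )
        for i, (c, y) in enumerate(zip(conds, yields))
    ]
    return ExperimentLog(space=log.space, observations=log.observations + tuple(new))


def best_so_far_trace(log: ExperimentLog) -> list[tuple[int, float]]:
    """Running maximum of yield vs evaluation index (1-based); non-decreasing."""
    if len(log) == 0:
        raise ValueError("empty log has no trace")
    best = -np.inf
    out = []
    for i, ob in enumerate(log.observations, start=1):
        best = max(best, ob.yield_gL)
        out.append((i, float(best)))
    return out


def stopped(log: ExperimentLog, rule: StoppingRule = StoppingRule()) -> tuple[bool, str]:
    """Stopping decision and reason ('budget', 'plateau', or 'continue')."""
    n = len(log)
    if n >= rule.max_budget:
        return True, "budget"
    if n > rule.patience:
        trace = [b for _, b in best_so_far_trace(log)]
        if trace[-1] - trace[-1 - rule.patience] < rule.min_improvement:
            return True, "plateau"
    return False, "continue"


def run_closed_loop(
    measure: Callable[[ReactionConditions, int], float],
    space: ParamSpace | None = None,
    budget: int = 60,
    batch_size: int = 4,
    n_init: int = 16,
    seed: int = 0,
    rule: StoppingRule | None = None,
    restarts: int = 8,
    pool_size: int = 20000,
) -> ExperimentLog:
    """Run the full in-silico loop: LHS seed, then EI batches until budget.

    ``measure(conditions, call_index)`` returns one measured yield (g/L) —
    e.g. the bundled simulator's noisy measurement.  Bit-reproducible under
    (seed, config).
    """
    space = space or build_default_space()
    log = ExperimentLog(space=space)
    call = 0

    init = initialize(space, n_init=min(n_init, budget), seed=seed)
    ys = []
    for c in init.conditions:
        ys.append(measure(c, call))
        call += 1
    log = record(log, init, ys, source="lhs")

    cycle = 0
    while len(log) < budget:
        if rule is not None and stopped(log, rule)[0]:
            break
        k = min(batch_size, budget - len(log))
        k_prop = max(k, 3)  # proposal contract needs 3-5; extras are dropped
        try:
            batch = step(
                log, batch_size=k_prop, seed=seed + 1000 * (cycle + 1),
                restarts=restarts, pool_size=pool_size,
            )
        except Exception as e:
            raise RuntimeError(f"closed-loop cycle {cycle} failed") from e
        conds = batch.conditions[:k]
        ys = []
        for c in conds:
            ys.append(measure(c, call))
            call += 1
        log = record(log, list(conds), ys, source="bo")
        cycle += 1
    return log


def random_search_baseline(
    measure: Callable[[ReactionConditions, int], float],
    space: ParamSpace | None = None,
    budget: int = 60,
    seed: int = 0,
) -> ExperimentLog:
    """Uniform random search at the same budget — the paired BO baseline."""
    from .design import uniform_sample

    space = space or build_default_space()
    conds = uniform_sample(space, budget, seed)
    obs = []
    for i, c in enumerate(conds):
        obs.append(
            Observation(
                conditions=c,
                yield_gL=float(measure(c, i)),
                batch_id=0,
                source="manual",
            )
        )
    return ExperimentLog(space=space, observations=tuple(obs))


def parallel_coordinates_table(log: ExperimentLog) -> pd.DataFrame:
    """Per-run parameter configuration plus yield, for parallel-coordinate plots."""
    df = log.to_frame()
    return df.drop(columns=["replicate_sd_gL"])
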