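"""Model-agnostic Shapley-value attributions for surrogate predictions.

The additive explanation model g(z') = phi_0 + sum_j phi_j z'_j assigns each
of the M reaction parameters an effect phi_j (g/L) such that the effects sum
(with the base value phi_0) to the surrogate's prediction at the explained
conditions.  Exact Shapley values require all 2^M coalitions; here they are
approximated by the Shapley sampling-values method: random feature
permutations with absent features imputed from a background sample, the
marginal contribution of each feature averaged over permutations.  Antithetic
(forward + reversed) permutations are used for variance reduction.

Features are the raw reaction parameters (12 of them), not one-hot columns:
the categorical cofactor is imputed at label level before encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .space import ParamSpace, ReactionConditions

__all__ = ["Attribution", "shap_values", "importance_summary", "dependence_table"]

PredictFn = Callable[[Sequence[ReactionConditions]], np.ndarray]
"""Batched predictor: list of conditions -> array of predicted yields (g/L)."""


@dataclass(frozen=True)
class Attribution:
    """Per-parameter Shapley effects phi_j plus base value phi_0 for one prediction."""

    base: float  # phi_0: mean prediction over the background, g/L
    effects: dict  # parameter name -> phi_j, g/L
    mc_sd: dict  # parameter name -> Monte-Carlo standard error of phi_j
    prediction: float  # f(x) at the explained conditions

    @property
    def total(self) -> float:
        return self.base + sum(self.effects.values())


def shap_values(
    predict_fn: PredictFn,
    background: Sequence[ReactionConditions],
    x: ReactionConditions,
    space: ParamSpace,
    n_permutations: int = 256,
    seed: int = 0,
) -> Attribution:
    """Shapley sampling-values attribution of ``predict_fn`` at ``x``.

    For each sampled permutation a background row is drawn; features enter in
    permutation order (absent features keep the background row's values) and
    phi_j is the mean marginal contribution of parameter j.  Permutations are
    antithetic pairs (each sampled order is also used reversed, with the same
    background row).  Deterministic under ``seed``.
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    names = space.names
    M = len(names)
    rng = np.random.default_rng(seed)

    n_pairs = (n_permutations + 1) // 2
    orders = []
    bg_rows = []
    for _ in range(n_pairs):
        perm = rng.permutation(M)
        b = background[int(rng.integers(0, len(background)))]
        orders.append(perm)
        bg_rows.append(b)
        orders.append(perm[::-1])
        bg_rows.append(b)
    orders = orders[:n_permutations]
    bg_rows = bg_rows[:n_permutations]

    # build every intermediate coalition point, batch-predict once
    batch: list[ReactionConditions] = []
    for perm, b in zip(orders, bg_rows):
        vals = dict(b.values)
        batch.append(ReactionConditions(vals))
        for j in perm:
            vals[names[j]] = x.values[names[j]]
            batch.append(ReactionConditions(dict(vals)))
    preds = np.asarray(predict_fn(batch), dtype=float)
    if preds.shape != (len(batch),):
        raise ValueError("predict_fn must return one value per condition set")

    contrib = np.zeros((len(orders), M))
    pos = 0
    for i, perm in enumerate(orders):
        chain = preds[pos : pos + M + 1]
        pos += M + 1
        deltas = np.diff(chain)
        contrib[i, perm] = deltas
    phi = contrib.mean(axis=0)
    mc_sd = contrib.std(axis=0, ddof=1) / np.sqrt(len(orders)) if len(orders) > 1 else np.zeros(M)

    base = float(np.mean(predict_fn(list(background))))
    pred_x = float(np.asarray(predict_fn([x]))[0])
    return Attribution(
        base=base,
        effects={n: float(v) for n, v in zip(names, phi)},
        mc_sd={n: float(v) for n, v in zip(names, mc_sd)},
        prediction=pred_x,
    )


def importance_summary(attributions: Sequence[Attribution]) -> pd.DataFrame:
    """Mean |phi_j| per parameter over a set of attributions, sorted descending.

    Ties break by parameter order of the first attribution.
    """
    if len(attributions) == 0:
        raise ValueError("need at least one attribution")
    names = list(attributions[0].effects)
    mat = np.array([[a.effects[n] for n in names] for a in attributions])
    mean_abs = np.abs(mat).mean(axis=0)
    df = pd.DataFrame({"parameter": names, "mean_abs_phi": mean_abs})
    df["_order"] = np.arange(len(names))
    df = df.sort_values(["mean_abs_phi", "_order"], ascending=[False, True])
    return df.drop(columns="_order").reset_index(drop=True)


def dependence_table(
    attributions: Sequence[Attribution],
    conditions: Sequence[ReactionConditions],
    parameter: str,
) -> pd.DataFrame:
    """(raw value, phi) pairs for one parameter, in log order — dependence-plot data."""
    if len(attributions) != len(conditions):
        raise ValueError("attributions and conditions must align")
    if not attributions or parameter not in attributions[0].effects:
        raise KeyError(f"unknown parameter {parameter!r}")
    return pd.DataFrame(
        {
            "value": [c.values[parameter] for c in conditions],
            "phi": [a.effects[parameter] for a in attributions],
        }
    )
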