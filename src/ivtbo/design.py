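"""Latin hypercube sampling of initial IVT reaction conditions.

LHS is stratified Monte Carlo: for n samples, each numeric dimension is split
into n equal-probability strata and every stratum is hit exactly once, with a
uniform draw inside the stratum and an independent permutation of strata per
dimension.  Categorical parameters get the analogous balanced treatment: the
levels are cycled until n assignments exist, then shuffled.

Note the stratification guarantee lives on the latent continuous design;
integer parameters are rounded afterwards, which can merge strata when the
integer range is narrower than n.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import qmc

from .space import ParamSpace, ReactionConditions, decode

__all__ = ["lhs_sample", "lhs_unit", "uniform_sample"]


def lhs_unit(d: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Latin hypercube design of n points in the d-dimensional unit cube.

    Each column hits each of the n strata [i/n, (i+1)/n) exactly once.
    """
    sampler = qmc.LatinHypercube(d=d, seed=rng)
    return sampler.random(n)


def _conditions_from_unit(
    u: np.ndarray, s: ParamSpace, cat_draws: dict[str, list], n: int
) -> list[ReactionConditions]:
    numeric = [spec for spec in s.specs if spec.is_numeric]
    conds = []
    for i in range(n):
        x = np.zeros(s.encoded_dim)
        j = 0
        for spec, sl in s.blocks():
            if spec.kind == "categorical":
                x[sl.start + spec.domain.index(cat_draws[spec.name][i])] = 1.0
            else:
                x[sl.start] = u[i, j]
                j += 1
        assert j == len(numeric)
        conds.append(decode(x, s))
    return conds


def lhs_sample(s: ParamSpace, n: int, seed: int) -> list[ReactionConditions]:
    """Sample ``n`` reaction conditions by Latin hypercube design.

    Deterministic under ``seed``.  Raises for n < 1.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    d = sum(1 for spec in s.specs if spec.is_numeric)
    u = lhs_unit(d, n, rng) if d else np.zeros((n, 0))
    cat_draws: dict[str, list] = {}
    for spec in s.specs:
        if spec.kind == "categorical":
            levels = list(spec.domain)
            assigned = [levels[i % len(levels)] for i in range(n)]
            rng.shuffle(assigned)
            cat_draws[spec.name] = assigned
    return _conditions_from_unit(u, s, cat_draws, n)


def uniform_sample(s: ParamSpace, n: int, seed: int) -> list[ReactionConditions]:
    """Plain uniform random design over the space (baseline alternative to LHS)."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    d = sum(1 for spec in s.specs if spec.is_numeric)
    u = rng.random((n, d))
    cat_draws = {
        spec.name: [spec.domain[k] for k in rng.integers(0, len(spec.domain), n)]
        for spec in s.specs
        if spec.kind == "categorical"
    }
    return _conditions_from_unit(u, s, cat_draws, n)
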