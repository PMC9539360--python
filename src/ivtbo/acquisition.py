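"""Expected improvement and batch proposal of next reaction conditions.

EI scores a candidate by the expected amount its (Gaussian) predicted yield
exceeds the best yield observed so far:

    EI = (mu - f_max) Phi(z) + s phi(z),   z = (mu - f_max) / s,

with Phi/phi the standard normal cdf/pdf.  A batch balances exploitation and
exploration: its first member maximizes EI over a large candidate pool, the
remaining members are random draws from the pool's high-EI region subject to
a minimum pairwise distance in encoded space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import gp
from .design import lhs_unit
from .space import ParamSpace, ReactionConditions, decode, snap_encoded

__all__ = ["expected_improvement", "propose_batch", "BatchProposal"]

# Batch-diversity knobs: members 2..k are drawn from pool points with
# EI >= EI_FRACTION * max EI, at encoded distance >= MIN_DIST from members
# already chosen (falling back to next-best EI when exhausted).
EI_FRACTION = 0.5
MIN_DIST = 0.05
POOL_SIZE = 20000
N_LOCAL = 2000  # local refinements around the incumbent
LOCAL_SD = 0.05
ZOOM_RADII = (0.1, 0.04, 0.015)  # shrinking zoom rounds on top-EI candidates
ZOOM_TOP = 40
ZOOM_PER_POINT = 25


def expected_improvement(y_hat, s, f_max):
    """EI (g/L) of a prediction (y_hat, s) over incumbent f_max; s >= 0.

    Vectorized over y_hat/s.  At s = 0 the deterministic improvement
    max(0, y_hat - f_max) is returned.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("predictive sd must be non-negative")
    scalar = y_hat.ndim == 0 and s.ndim == 0
    y_hat, s = np.atleast_1d(y_hat), np.atleast_1d(s)
    y_hat, s = np.broadcast_arrays(y_hat, s)
    ei = np.maximum(y_hat - f_max, 0.0)
    pos = s > 0
    if np.any(pos):
        z = (y_hat[pos] - f_max) / s[pos]
        ei = ei.astype(float)
        ei[pos] = (y_hat[pos] - f_max) * norm.cdf(z) + s[pos] * norm.pdf(z)
    ei = np.maximum(ei, 0.0)
    return float(ei[0]) if scalar else ei


@dataclass(frozen=True)
class BatchProposal:
    """3-5 distinct proposed reaction conditions with their EI values."""

    conditions: tuple[ReactionConditions, ...]
    ei: tuple[float, ...]
    provenance: tuple[str, ...]  # "maximizer" | "diverse" | "fallback" | "lhs"

    def __len__(self) -> int:
        return len(self.conditions)


def _candidate_pool(
    s: ParamSpace,
    incumbent: np.ndarray | None,
    seed: int,
    pool_size: int,
) -> np.ndarray:
    """Encoded, grid-snapped candidate pool: LHS cover plus local refinements."""
    rng = np.random.default_rng(seed)
    numeric = [spec for spec in s.specs if spec.is_numeric]
    u = lhs_unit(len(numeric), pool_size, rng)
    pool = np.zeros((pool_size, s.encoded_dim))
    j = 0
    for spec, sl in s.blocks():
        if spec.kind == "categorical":
            levels = np.array(
                [i % spec.width for i in range(pool_size)], dtype=int
            )
            rng.shuffle(levels)
            pool[np.arange(pool_size), sl.start + levels] = 1.0
        else:
            pool[:, sl.start] = u[:, j]
            j += 1
    if incumbent is not None:
        local = incumbent[None, :] + rng.normal(
            0.0, LOCAL_SD, (N_LOCAL, s.encoded_dim)
        )
        pool = np.vstack([pool, local])
    return snap_encoded(pool, s)


def propose_batch(
    model: gp.GPModel,
    s: ParamSpace,
    f_max: float,
    batch_size: int = 4,
    seed: int = 0,
    pool_size: int = POOL_SIZE,
) -> BatchProposal:
    """Propose ``batch_size`` (3-5) next reaction conditions.

    Member 1 is the EI maximizer over an LHS candidate pool augmented with
    local refinements around the incumbent (best training point); members
    2..k are seeded random draws from the high-EI region with a minimum
    pairwise encoded distance, falling back to next-best-EI points when the
    diverse set is exhausted.  Deterministic under ``seed``.
    """
    if model.n < 1:
        raise ValueError("model must be fitted on at least one observation")
    if not 3 <= batch_size <= 5:
        raise ValueError("batch size must be between 3 and 5")

    incumbent = model.X[int(np.argmax(model.y))]
    pool = _candidate_pool(s, incumbent, seed, pool_size)
    mu, sd = gp.predict(model, pool)
    ei = expected_improvement(mu, sd, f_max)

    n_base = len(pool)

    # iterative zoom: resample around the current top-EI candidates at
    # shrinking radii so the maximizer is located finer than pool spacing;
    # only member 1 comes from the zoomed set — diversity draws stay global
    rng_zoom = np.random.default_rng(seed + 3)
    for radius in ZOOM_RADII:
        top = np.argsort(-ei)[:ZOOM_TOP]
        perturbed = np.repeat(pool[top], ZOOM_PER_POINT, axis=0)
        perturbed = perturbed + rng_zoom.normal(0.0, radius, perturbed.shape)
        perturbed = snap_encoded(perturbed, s)
        mu_z, sd_z = gp.predict(model, perturbed)
        ei_z = expected_improvement(mu_z, sd_z, f_max)
        pool = np.vstack([pool, perturbed])
        ei = np.concatenate([ei, ei_z])

    order = np.argsort(-ei)
    chosen: list[int] = [int(order[0])]
    provenance = ["maximizer"]

    rng = np.random.default_rng(seed + 2)
    good = np.flatnonzero(ei[:n_base] >= EI_FRACTION * ei[chosen[0]])
    good = good[~np.isin(good, chosen)]
    rng.shuffle(good)

    def far_enough(idx: int) -> bool:
        return all(
            np.linalg.norm(pool[idx] - pool[j]) >= MIN_DIST for j in chosen
        )

    for idx in good:
        if len(chosen) >= batch_size:
            break
        if far_enough(int(idx)):
            chosen.append(int(idx))
            provenance.append("diverse")
    # fallback: walk down the EI ranking, requiring distinctness only
    for idx in order:
        if len(chosen) >= batch_size:
            break
        idx = int(idx)
        if idx in chosen:
            continue
        if all(np.linalg.norm(pool[idx] - pool[j]) > 1e-12 for j in chosen):
            chosen.append(idx)
            provenance.append("fallback")

    conds = tuple(decode(pool[i], s) for i in chosen)
    return BatchProposal(
        conditions=conds,
        ei=tuple(float(ei[i]) for i in chosen),
        provenance=tuple(provenance),
    )
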