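"""Synthetic IVT wet-lab stand-in: calibrated yield surface, kinetics, noise.

The simulator is a calibrated emulator, not a mechanistic transcription
model.  The noise-free yield surface is multiplicative over per-parameter
unimodal response factors,

    yield(c) = Y_max * prod_j f_j(x_j) * g(t),     g(t) = 1 - exp(-k t),

with each f_j in (0, 1]: saturating Hill responses for components that help
monotonically (DTT, NTPs, DNA template, PPase), asymmetric (generalized)
Gaussian bells for windowed optima (cofactor concentration, spermidine, T7
RNAP activity on a log scale, temperature, pH), and a nearly flat response
for the RNase inhibitor.  The cofactor salt couples to its concentration:
MgCl2 shifts the usable concentration window downward relative to MgAcetate
(acetate tolerates higher Mg2+), with a small amplitude penalty.

The shared first-order rate k = ln(5)/120 per minute makes the reaction reach
exactly 80% of its plateau at the 2-hour mark.  Calibration fits the factor
shapes to the seven reference reactions under window constraints on each
factor's optimum, and the result ships as a frozen JSON fixture.

Kinetics for a reaction's conditions follow m(t) = Y_kin(c) (1 - e^{-kt}) for
the base 1195 bp template; templates beyond a size threshold have their
amplitude attenuated and decline linearly after the 120-min peak (aberrant
product formation / precipitation for long transcripts).  The dsRNA
by-product mass fraction ramps up after ~115 min toward 0.05 mg/mg at
reaction completion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import least_squares

from .anchors import KINETIC_ANCHORS, REFERENCE_REACTIONS, AnchorReaction
from .optimizer import Observation
from .space import ReactionConditions, build_default_space, validate

__all__ = [
    "SimParams",
    "KineticProfile",
    "yield_mean",
    "plateau",
    "measure",
    "kinetic_profile",
    "calibrate",
    "load_default_params",
    "Simulator",
]

K_TIME = np.log(5.0) / 120.0  # min^-1; 1 - e^{-k*120} = 0.8 exactly
BASE_TEMPLATE_BP = 1195
PEAK_MIN = 120.0  # large templates peak here, then decline


# ---------------------------------------------------------------------------
# response-factor primitives


def _bell(x: float, c: float, wl: float, wr: float, floor: float, p: float = 2.0) -> float:
    """Asymmetric generalized-Gaussian bell with a floor; peak value 1 at x=c."""
    w = wl if x < c else wr
    return floor + (1.0 - floor) * float(np.exp(-0.5 * np.abs((x - c) / w) ** p))


def _hill(x: float, K: float, h: float, floor: float) -> float:
    """Saturating increasing response; floor at x=0, approaching 1 for x >> K."""
    xs = max(float(x), 0.0)
    return floor + (1.0 - floor) * xs**h / (xs**h + K**h)


# fixed floors (fraction of full activity retained at the worst value of each
# factor); chosen a priori so no single mid-impact parameter can zero the
# reaction, mirroring the reported parameter-importance ordering
_FLOORS = {
    "cofactor_mM": 0.20,
    "DTT_mM": 0.60,
    "NTPs_mM": 0.50,
    "DNA_nM": 0.55,
    "PPase_UmL": 0.60,
    "spermidine_mM": 0.30,
    "T7_UmL": 0.40,
    "temperature_C": 0.40,
    "pH": 0.45,
}

_TEMP_SHAPE_P = 6.0  # plateau-like temperature optimum
_MGCL2_SCALE = 0.97  # cofactor type itself is low-impact


@dataclass(frozen=True)
class SimParams:
    """Frozen parameters of the calibrated IVT response surface and kinetics."""

    y_max: float  # plateau ceiling, g/L
    factors: dict  # per-parameter response-shape parameters
    kin_scale: float  # kinetic plateau = kin_scale * surface plateau
    dsrna_onset_min: float
    dsrna_tau_min: float
    dsrna_rho_inf: float  # mg/mg
    template_bp_threshold: float
    template_amp_rate: float  # amplitude loss per bp above threshold
    template_slope_rate: float  # post-peak relative decline per min per bp
    noise_sd: float = 0.5  # replicate noise, g/L

    def __post_init__(self) -> None:
        if not 0 < self.y_max <= 20:
            raise ValueError("y_max must lie in (0, 20] g/L")
        if not 0 <= self.dsrna_rho_inf <= 1:
            raise ValueError("dsRNA asymptote must lie in [0, 1]")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class KineticProfile:
    """mRNA and dsRNA-fraction time courses for one reaction's conditions."""

    times: np.ndarray  # min
    mrna: np.ndarray  # g/L
    dsrna_ratio: np.ndarray  # mg/mg, non-decreasing, <= rho_inf

    def at(self, t: float) -> float:
        """mRNA concentration at time t (exact grid point or interpolated)."""
        return float(np.interp(t, self.times, self.mrna))


def _factor(name: str, value, cofactor: str, fp: dict) -> float:
    if name == "RNaseInh_UmL":
        return 0.92 + 0.08 * value / (value + 200.0)
    p = fp[name]
    if name == "cofactor_mM":
        center = p["center"] if cofactor == "MgAcetate" else p["center"] - p["mgcl2_shift"]
        scale = 1.0 if cofactor == "MgAcetate" else _MGCL2_SCALE
        return scale * _bell(value, center, p["wl"], p["wr"], p["floor"])
    if name in ("DTT_mM", "NTPs_mM", "DNA_nM", "PPase_UmL"):
        return _hill(value, p["K"], p["h"], p["floor"])
    if name == "spermidine_mM":
        return _bell(value, p["center"], p["wl"], p["wr"], p["floor"])
    if name == "T7_UmL":
        return _bell(np.log10(value), p["center"], p["wl"], p["wr"], p["floor"])
    if name == "temperature_C":
        return _bell(value, p["center"], p["w"], p["w"], p["floor"], p=_TEMP_SHAPE_P)
    if name == "pH":
        return _bell(value, p["center"], p["wl"], p["wr"], p["floor"])
    raise KeyError(name)


def plateau(c: ReactionConditions, p: SimParams) -> float:
    """Noise-free surface plateau Y_max * prod_j f_j (time factor excluded), g/L."""
    space = build_default_space()
    bad = validate(c, space)
    if bad:
        raise ValueError("invalid conditions: " + "; ".join(map(str, bad)))
    cof = c["cofactor"]
    prod = 1.0
    for name in space.names:
        if name in ("cofactor", "time_min"):
            continue
        prod *= _factor(name, c[name], cof, p.factors)
    return p.y_max * prod


def _template_curve(t: np.ndarray, bp: float, p: SimParams) -> np.ndarray:
    """Relative (fraction-of-plateau) time course for a template of given size."""
    t = np.asarray(t, dtype=float)
    excess = max(0.0, float(bp) - p.template_bp_threshold)
    amp = max(0.0, 1.0 - p.template_amp_rate * excess)
    rise = amp * (1.0 - np.exp(-K_TIME * t))
    if excess == 0.0:
        return rise
    slope = p.template_slope_rate * excess
    peak = amp * (1.0 - np.exp(-K_TIME * PEAK_MIN))
    decline = peak - slope * (t - PEAK_MIN)
    return np.where(t <= PEAK_MIN, rise, np.maximum(decline, 0.0))


def yield_mean(
    c: ReactionConditions, p: SimParams, template_bp: float = BASE_TEMPLATE_BP
) -> float:
    """Noise-free mRNA yield (g/L) at the conditions' own reaction time."""
    t = float(c["time_min"])
    rel = float(_template_curve(np.array([t]), template_bp, p)[0])
    return plateau(c, p) * rel


def measure(
    c: ReactionConditions,
    p: SimParams,
    seed,
    template_bp: float = BASE_TEMPLATE_BP,
) -> Observation:
    """One noisy measurement: yield_mean + N(0, noise_sd), truncated at 0."""
    rng = np.random.default_rng(seed)
    y = yield_mean(c, p, template_bp) + rng.normal(0.0, p.noise_sd)
    return Observation(
        conditions=c,
        yield_gL=max(0.0, float(y)),
        batch_id=0,
        source="manual",
        replicate_sd=p.noise_sd,
    )


def kinetic_profile(
    c: ReactionConditions,
    p: SimParams,
    times=None,
    template_bp: float = BASE_TEMPLATE_BP,
) -> KineticProfile:
    """Noise-free mRNA and dsRNA-ratio time courses at fixed conditions.

    The kinetic plateau is ``kin_scale * plateau(c)`` (the kinetics experiment
    is anchored separately from the endpoint surface); mRNA rises first-order
    with rate k, and templates above the size threshold decline linearly after
    the 120-min peak.  The dsRNA mass fraction ramps from the onset time
    toward its asymptote.
    """
    if times is None:
        times = np.arange(0.0, 301.0, 1.0)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(t > 300):
        raise ValueError("times must lie within [0, 300] min")
    y_kin = p.kin_scale * plateau(c, p)
    mrna = y_kin * _template_curve(t, template_bp, p)
    ramp = 1.0 - np.exp(-np.maximum(t - p.dsrna_onset_min, 0.0) / p.dsrna_tau_min)
    ds = p.dsrna_rho_inf * ramp
    return KineticProfile(times=t, mrna=mrna, dsrna_ratio=ds)


# ---------------------------------------------------------------------------
# calibration

# free parameters: (factor, key, initial, lo, hi).  Bounds keep each factor's
# optimum inside its reported optimal window (cofactor 40-60 mM, spermidine
# 1-3 mM, T7 6000-8000 U/mL, temperature 37-44 C, pH 6.5-7.2; NTPs/DNA/PPase/
# DTT are structurally increasing).
_FREE = [
    # ceiling just above the best observed endpoint plateau (~15.2 g/L at the
    # best run's conditions): the campaign converged, so the reachable optimum
    # is not far beyond what it found
    ("__global__", "y_max", 15.5, 14.0, 17.0),
    ("cofactor_mM", "center", 52.0, 40.0, 60.0),
    ("cofactor_mM", "wl", 18.0, 5.0, 40.0),
    ("cofactor_mM", "wr", 25.0, 5.0, 50.0),
    ("cofactor_mM", "mgcl2_shift", 15.0, 5.0, 30.0),
    ("DTT_mM", "K", 4.0, 1.0, 8.0),
    ("DTT_mM", "h", 1.5, 0.8, 5.0),
    ("NTPs_mM", "K", 5.0, 3.0, 7.0),
    ("NTPs_mM", "h", 2.0, 1.0, 5.0),
    ("DNA_nM", "K", 35.0, 20.0, 60.0),
    ("DNA_nM", "h", 2.0, 1.0, 5.0),
    ("PPase_UmL", "K", 3.0, 0.5, 6.0),
    ("PPase_UmL", "h", 1.5, 0.8, 5.0),
    ("spermidine_mM", "center", 2.0, 1.0, 3.0),
    ("spermidine_mM", "wl", 1.2, 0.4, 3.0),
    ("spermidine_mM", "wr", 3.0, 0.8, 8.0),
    ("T7_UmL", "center", np.log10(7000.0), np.log10(6000.0), np.log10(8000.0)),
    ("T7_UmL", "wl", 0.35, 0.08, 1.2),
    ("T7_UmL", "wr", 0.5, 0.08, 1.5),
    ("temperature_C", "center", 40.5, 37.0, 44.0),
    ("temperature_C", "w", 7.0, 3.0, 15.0),
    # pH falls off sharply above ~7.5 (high-impact parameter); the width
    # bound keeps the emulator's pH response as influential as reported
    ("pH", "center", 6.9, 6.5, 7.2),
    ("pH", "wl", 0.4, 0.15, 0.8),
    ("pH", "wr", 0.5, 0.25, 0.8),
]

_PRIOR_WEIGHT = 0.05  # weak pull toward the initial guess, per scaled unit


def _params_from_vector(x: np.ndarray, noise_sd: float) -> SimParams:
    factors: dict[str, dict[str, float]] = {}
    y_max = 16.5
    for (fac, key, *_), v in zip(_FREE, x):
        if fac == "__global__":
            y_max = float(v)
        else:
            factors.setdefault(fac, {})[key] = float(v)
    for name, floor in _FLOORS.items():
        factors.setdefault(name, {})["floor"] = floor

    # kinetic-side constants follow in closed form from the kinetic anchors
    ka = KINETIC_ANCHORS
    frac = ka["plateau_fraction_at_120min"]
    y_kin_plateau = ka["mrna_at_120min_gL"] / frac  # run-5 kinetic plateau
    tau = 40.0
    rho_inf = ka["dsrna_ratio_at_completion"] / (
        1.0 - np.exp(-(300.0 - ka["dsrna_onset_min"]) / tau)
    )
    # large-template anchors fix the linear post-peak decline and attenuation
    bp = ka["large_template_bp"]
    thresh = 2000.0
    r145 = ka["large_template_mrna_145min_gL"] / y_kin_plateau
    r300 = ka["large_template_mrna_300min_gL"] / y_kin_plateau
    slope = (r145 - r300) / (300.0 - 145.0)
    amp = (r145 + slope * (145.0 - PEAK_MIN)) / frac
    p = SimParams(
        y_max=y_max,
        factors=factors,
        kin_scale=1.0,  # placeholder; set after the surface is known
        dsrna_onset_min=ka["dsrna_onset_min"],
        dsrna_tau_min=tau,
        dsrna_rho_inf=float(rho_inf),
        template_bp_threshold=thresh,
        template_amp_rate=float((1.0 - amp) / (bp - thresh)),
        template_slope_rate=float(slope / (bp - thresh)),
        noise_sd=noise_sd,
    )
    return p


def calibrate(
    anchors: tuple[AnchorReaction, ...] = REFERENCE_REACTIONS,
    seed: int = 0,
    noise_sd: float = 0.5,
) -> SimParams:
    """Fit the response surface to the reference reactions; freeze kinetics.

    Minimizes the SD-weighted squared error of the noise-free yields at the
    seven anchor conditions, with bound constraints keeping every factor's
    optimum inside its reported window and a weak prior pulling shape
    parameters toward their initial guesses.  Raises if the achieved RMSE
    exceeds the mean printed replicate SD.
    """
    if len(anchors) < 7:
        raise ValueError("calibration needs all seven reference reactions")
    x0 = np.array([f[2] for f in _FREE])
    lo = np.array([f[3] for f in _FREE])
    hi = np.array([f[4] for f in _FREE])
    scale = hi - lo
    sds = np.array([a.sd_gL for a in anchors])

    def residuals(x):
        p = _params_from_vector(x, noise_sd)
        res = [
            (yield_mean(a.conditions, p) - a.yield_gL) / a.sd_gL for a in anchors
        ]
        prior = _PRIOR_WEIGHT * (x - x0) / scale
        return np.concatenate([res, prior])

    sol = least_squares(residuals, x0, bounds=(lo, hi), x_scale=scale, jac="3-point")
    p = _params_from_vector(sol.x, noise_sd)

    resid = np.array([yield_mean(a.conditions, p) - a.yield_gL for a in anchors])
    rmse = float(np.sqrt(np.mean(resid**2)))
    if rmse > float(np.mean(sds)):
        raise RuntimeError(
            f"calibration RMSE {rmse:.3f} g/L exceeds the mean replicate SD "
            f"{np.mean(sds):.3f}; residuals: "
            + ", ".join(f"{a.name}={r:+.3f}" for a, r in zip(anchors, resid))
        )

    # anchor the kinetic plateau: run-5 base-template profile passes through
    # 10.65 g/L at 120 min (80% of its 5-h plateau)
    run5 = anchors[4]
    y_kin_plateau = (
        KINETIC_ANCHORS["mrna_at_120min_gL"]
        / KINETIC_ANCHORS["plateau_fraction_at_120min"]
    )
    kin_scale = y_kin_plateau / plateau(run5.conditions, p)
    d = json.loads(p.to_json())
    d["kin_scale"] = float(kin_scale)
    return SimParams(**d)


def load_default_params() -> SimParams:
    """The frozen, versioned calibration fixture shipped with the package."""
    text = resources.files("ivtbo.data").joinpath("sim_params.json").read_text()
    return SimParams.from_json(text)


class Simulator:
    """Convenience wrapper binding SimParams with a seeded measurement stream."""

    def __init__(self, params: SimParams | None = None, seed: int = 0):
        self.params = params or load_default_params()
        self.seed = int(seed)

    def yield_mean(self, c: ReactionConditions, template_bp: float = BASE_TEMPLATE_BP) -> float:
        return yield_mean(c, self.params, template_bp)

    def measure_fn(self):
        """A ``measure(conditions, call_index) -> yield`` closure for the loop.

        Deterministic per (simulator seed, call index).
        """

        def fn(c: ReactionConditions, call_index: int) -> float:
            return measure(c, self.params, seed=(self.seed, int(call_index))).yield_gL

        return fn

    def kinetic_profile(self, c, times=None, template_bp: float = BASE_TEMPLATE_BP):
        return kinetic_profile(c, self.params, times, template_bp)
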