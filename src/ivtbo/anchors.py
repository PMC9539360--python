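"""Published calibration anchors for the synthetic IVT response surface.

The seven reference reactions are the six best conditions found by the wet-lab
optimization campaign plus the patent-derived benchmark reaction (reaction 7),
each with its measured mRNA yield and replicate SD.  They are the inputs the
simulator is calibrated against, together with the kinetic anchors of the best
run (run 5): 80% of the 5-h plateau reached at 2 h (10.65 g/L), a final
dsRNA/total-RNA mass ratio of 0.05, and the large-template decline
(9.7 g/L at 145 min falling to 7.1 g/L at 300 min for the 5299 bp template).

The cofactor salt is magnesium acetate for all seven reactions (the campaign
converged on MgAcetate; the benchmark patent medium is likewise an acetate
buffer system here).
"""

from __future__ import annotations

from dataclasses import dataclass

from .space import ReactionConditions

__all__ = [
    "AnchorReaction",
    "REFERENCE_REACTIONS",
    "KINETIC_ANCHORS",
    "TEMPLATE_SIZES_BP",
]


@dataclass(frozen=True)
class AnchorReaction:
    """One reference reaction: conditions, measured yield, replicate SD (g/L)."""

    name: str
    conditions: ReactionConditions
    yield_gL: float
    sd_gL: float


def _rc(cof_mM, dtt, rnase, ntps, dna, ppase, sperm, t7, temp, time, ph):
    return ReactionConditions(
        {
            "cofactor": "MgAcetate",
            "cofactor_mM": cof_mM,
            "DTT_mM": dtt,
            "RNaseInh_UmL": rnase,
            "NTPs_mM": ntps,
            "DNA_nM": dna,
            "PPase_UmL": ppase,
            "spermidine_mM": sperm,
            "T7_UmL": t7,
            "temperature_C": temp,
            "time_min": time,
            "pH": ph,
        }
    )


REFERENCE_REACTIONS: tuple[AnchorReaction, ...] = (
    AnchorReaction("reaction1", _rc(60.00, 7.09, 829, 8.57, 61, 10, 2.65, 7346, 43, 263, 6.89), 12.61, 0.82),
    AnchorReaction("reaction2", _rc(48.46, 3.85, 1072, 8.81, 100, 9, 1.35, 7320, 39, 98, 6.80), 10.76, 0.47),
    AnchorReaction("reaction3", _rc(41.79, 5.57, 1217, 9.89, 89, 5, 2.24, 6607, 44, 120, 6.65), 11.76, 0.66),
    AnchorReaction("reaction4", _rc(59.87, 9.85, 986, 8.50, 100, 2, 1.31, 6166, 40, 148, 6.78), 12.27, 0.77),
    AnchorReaction("reaction5", _rc(49.28, 5.27, 1474, 7.75, 89, 8, 2.25, 7743, 44, 121, 6.67), 12.18, 0.98),
    AnchorReaction("reaction6", _rc(40.00, 3.99, 1045, 9.29, 72, 7, 2.03, 7748, 44, 279, 6.60), 11.52, 0.23),
    AnchorReaction("reaction7", _rc(40.00, 5.00, 1000, 7.50, 40, 1, 1.00, 7000, 37, 240, 8.00), 7.64, 0.87),
)

# Kinetic anchors (best run, run 5).
KINETIC_ANCHORS = {
    "mrna_at_120min_gL": 10.65,  # = 80% of the 5-h plateau
    "plateau_fraction_at_120min": 0.80,
    "dsrna_ratio_at_completion": 0.05,  # mg/mg at 300 min
    "dsrna_onset_min": 115.0,  # by-product band appears after ~115 min
    "large_template_bp": 5299,
    "large_template_mrna_145min_gL": 9.7,
    "large_template_mrna_300min_gL": 7.1,
}

# EGFP, RBD_EGFP, Cas9_EGFP template lengths.
TEMPLATE_SIZES_BP = {"EGFP": 1195, "RBD_EGFP": 1864, "Cas9_EGFP": 5299}
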