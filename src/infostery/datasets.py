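"""Curated benchmark lists for the PSD95 PDZ3 - CRIPT peptide complex.

Deep mutational scanning of this complex measured the binding-affinity
change (deltaE, kcal/mol) of every single amino-acid substitution over 83
scanned positions, identifying 20 positions as highly sensitive to
mutations.  The residue lists below are the published reference prediction
sets of the communication-bridge strategies on that benchmark, used here as
worked examples for the confusion-metric machinery (the underlying MD
trajectories are not shipped; the lists and class sizes are the inputs).
"""

from __future__ import annotations

from .metrics import Confusion

__all__ = [
    "UNIVERSE_SIZE",
    "SENSITIVE_POSITIONS",
    "STRATEGY_PREDICTIONS",
    "MUTATION_SET_SIZES",
    "TABLE1_CONFUSIONS",
    "evaluate_position_prediction",
]

#: number of scanned positions in the deep-mutational-scanning matrix
UNIVERSE_SIZE = 83

#: the 20 positions experimentally identified as highly sensitive
SENSITIVE_POSITIONS = frozenset(
    {
        "L323", "G324", "F325", "I327", "V328", "G329", "G330", "I336",
        "I338", "I341", "A347", "L353", "I359", "V362", "L367", "H372",
        "A375", "A376", "L379", "I388",
    }
)

#: reference prediction sets per strategy (wild-type analysis)
STRATEGY_PREDICTIONS: dict[str, frozenset[str]] = {
    "unit_overlap": frozenset({"G324", "I341", "H372", "A376", "L379"}),
    "ligand_direct": frozenset({"F325", "I327", "H372", "N326"}),
    "isolated_direct": frozenset(
        {
            "L323", "I327", "G329", "G330", "I336", "I341", "A347", "L353",
            "V362", "L367", "H372", "A375", "L379", "G356",
        }
    ),
    "all_20ns": frozenset(
        {
            "L323", "G324", "F325", "I327", "G329", "G330", "I336", "I341",
            "A347", "L353", "V362", "L367", "H372", "A375", "A376", "L379",
            "N326", "G356",
        }
    ),
    "all_50ns": frozenset(
        {
            "L323", "G324", "F325", "I327", "G329", "G330", "I336", "I338",
            "I341", "A347", "L353", "V362", "L367", "H372", "A375", "A376",
            "L379", "N326", "I337",
        }
    ),
}

#: mutation-set compositions used for the deleterious/neutral classifier
MUTATION_SET_SIZES = {
    "all": {"neutral": 45, "highly_deleterious": 59},
    "filtered": {"neutral": 15, "highly_deleterious": 41},
}

#: confusion matrices implied by the published classifier operating points
#: (counts recovered from sensitivity/precision/specificity and class sizes)
TABLE1_CONFUSIONS = {
    ("all", 2.2): Confusion(tp=42, fp=14, tn=31, fn=17),
    ("filtered", 1.2): Confusion(tp=38, fp=8, tn=7, fn=3),
}


def evaluate_position_prediction(predicted: frozenset[str] | set[str]) -> Confusion:
    """Confusion of a predicted position set against the 20-position
    reference over the 83 scanned positions."""
    predicted = set(predicted)
    tp = len(predicted & SENSITIVE_POSITIONS)
    fp = len(predicted - SENSITIVE_POSITIONS)
    fn = len(SENSITIVE_POSITIONS) - tp
    tn = UNIVERSE_SIZE - tp - fp - fn
    return Confusion(tp=tp, fp=fp, tn=tn, fn=fn)
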