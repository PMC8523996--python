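"""End-to-end per-subject model fitting.

Glues the modules together: blood-curve fit -> plasma input ->
semiquantitative, graphical and compartmental analyses, producing the
per-subject parameter table consumed by the comparison stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compartmental, graphical, input_function, semiquant, tac

__all__ = ["fit_subject", "fit_cohort", "PARAMETER_COLUMNS"]

PARAMETER_COLUMNS = [
    "ttp", "slope",
    "a1", "a2", "p", "q", "A", "B",
    "ttp_ratio", "slope_ratio",
    "ved", "int_logan",
    "dvr", "rrt",
    "K1", "k2", "k3", "k4", "Ki", "Vb",
]


def fit_subject(
    record: tac.SubjectRecord,
    config: input_function.InputFunctionConfig | None = None,
    window_min=graphical.DEFAULT_WINDOW_MIN,
    seed: int = 0,
) -> dict:
    """Fit all six dynamic models to one subject; returns a flat parameter dict.

    Requires the tumor TAC under both protocols, the brain reference TAC
    under the uniform protocol and the blood TAC under the
    input-function protocol.
    """
    config = config or input_function.InputFunctionConfig()
    tumor_uni = record.tac(tac.REGION_TUMOR, tac.PROTOCOL_UNIFORM)
    tumor_if = record.tac(tac.REGION_TUMOR, tac.PROTOCOL_INPUT_FUNCTION)
    brain_uni = record.tac(tac.REGION_BRAIN, tac.PROTOCOL_UNIFORM)
    blood_if = record.tac(tac.REGION_BLOOD, tac.PROTOCOL_INPUT_FUNCTION)

    # input function chain
    blood_fit = input_function.fit_blood_tac(blood_if, n_starts=config.n_multistarts, seed=seed)
    plasma = input_function.build_plasma_input(blood_fit, config)

    # SQ / SQ Fit / Ref SQ
    tumor_fit = semiquant.fit_vascularization(tumor_uni, seed=seed)
    brain_fit = semiquant.fit_vascularization(brain_uni, seed=seed)
    sq = semiquant.sq_result(tumor_fit)
    ref = semiquant.ref_sq(tumor_fit, brain_fit)

    # graphical models
    lg = graphical.logan(tumor_uni, plasma.plasma_fdopa, window_min)
    rlg = graphical.ref_logan(tumor_uni, brain_uni, window_min)

    # compartmental model
    tcm = compartmental.fit_tcm(tumor_if, plasma.plasma_fdopa, plasma.whole_blood, seed=seed)

    return {
        "subject_id": record.subject_id,
        "idh_mutant": int(record.idh_mutant),
        "ttp": sq.ttp,
        "slope": sq.slope,
        "a1": tumor_fit.a1,
        "a2": tumor_fit.a2_s,
        "p": tumor_fit.p,
        "q": tumor_fit.q,
        "A": tumor_fit.A,
        "B": tumor_fit.B,
        "ttp_ratio": ref.ttp_ratio,
        "slope_ratio": ref.slope_ratio,
        "ved": lg.ved,
        "int_logan": lg.int_logan,
        "dvr": rlg.dvr,
        "rrt": rlg.rrt,
        "K1": tcm.params.k1,
        "k2": tcm.params.k2,
        "k3": tcm.params.k3,
        "k4": tcm.params.k4,
        "Ki": tcm.ki,
        "Vb": tcm.params.vb,
    }


def fit_cohort(records, config=None, window_min=graphical.DEFAULT_WINDOW_MIN, seed: int = 0) -> pd.DataFrame:
    """Parameter table for a cohort: one row per subject, one column per
    extracted kinetic parameter plus the IDH label."""
    rows = [fit_subject(rec, config=config, window_min=window_min, seed=seed) for rec in records]
    df = pd.DataFrame(rows).set_index("subject_id")
    return df[["idh_mutant"] + PARAMETER_COLUMNS]
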