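"""qPCR relative quantification and dual-readout knockdown-screen scoring.

Relative quantity is the standard delta-Ct form RQ = 2^-(Ct_target -
Ct_reference). The screen readout is a PSI fold change — the ratio of
exon-inclusion RQ to total-transcript RQ, normalized to the negative
control within each experiment — averaged across biological replicates.
Per readout, z-scores are computed over the detected library factors
(controls excluded by default), and a factor is a hit when both readout
z-scores exceed the positive control's and their sum exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

READOUTS = ("exon5", "exon21")


def relative_quantity(ct_target: float, ct_reference: float, detection_limit: float | None = None) -> float:
    """Delta-Ct relative quantity 2^-(Ct_target - Ct_reference).

    When a detection limit is given and either Ct reaches it, the
    quantity is undefined and NaN is returned.
    """
    if detection_limit is not None and (ct_target >= detection_limit or ct_reference >= detection_limit):
        return float("nan")
    return float(2.0 ** (-(ct_target - ct_reference)))


def psi_fold_change(rq_inclusion, rq_total, rq_inclusion_ctrl, rq_total_ctrl) -> float:
    """Inclusion-to-total RQ ratio, normalized to the control's ratio."""
    for v in (rq_inclusion, rq_total, rq_inclusion_ctrl, rq_total_ctrl):
        if not np.isfinite(v) or v <= 0:
            raise ValueError("all relative quantities must be positive and finite")
    return float((rq_inclusion / rq_total) / (rq_inclusion_ctrl / rq_total_ctrl))


def score_plate(
    plate: pd.DataFrame,
    positive_control: str = "SMCHD1",
    negative_control: str = "GFP",
    detection_limit: float = 35.0,
    readouts: tuple = READOUTS,
    total_amplicon: str = "total",
    reference_amplicon: str = "reference",
) -> pd.DataFrame:
    """Per-factor PSI fold changes from a long Ct table.

    Expects columns factor_id / amplicon / replicate / ct. Within each
    replicate, every factor's inclusion-to-total ratio is normalized to
    the negative control's; fold changes are then averaged across
    replicates. A factor is detected when its total-transcript Ct is
    below the detection limit in every replicate.
    """
    required = {"factor_id", "amplicon", "replicate", "ct"}
    if not required <= set(plate.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    wide = plate.pivot_table(index=["factor_id", "replicate"], columns="amplicon", values="ct")
    for amp in (*readouts, total_amplicon, reference_amplicon):
        if amp not in wide.columns:
            raise ValueError(f"missing amplicon {amp!r}")
    if negative_control not in wide.index.get_level_values(0):
        raise ValueError(f"negative control {negative_control!r} absent from plate")

    detected = (wide[total_amplicon] < detection_limit).groupby("factor_id").all()
    rows = []
    for (factor, rep), cts in wide.iterrows():
        ct_ref = cts[reference_amplicon]
        ctrl = wide.loc[(negative_control, rep)]
        rec = {"factor_id": factor, "replicate": rep}
        for r in readouts:
            rq_inc = relative_quantity(cts[r], ct_ref)
            rq_tot = relative_quantity(cts[total_amplicon], ct_ref)
            rq_inc_c = relative_quantity(ctrl[r], ctrl[reference_amplicon])
            rq_tot_c = relative_quantity(ctrl[total_amplicon], ctrl[reference_amplicon])
            rec[f"fc_{r}"] = psi_fold_change(rq_inc, rq_tot, rq_inc_c, rq_tot_c)
        rows.append(rec)
    per_rep = pd.DataFrame(rows)
    fc = per_rep.groupby("factor_id", sort=False).mean(numeric_only=True).drop(columns=["replicate"])
    fc["detected"] = detected.reindex(fc.index).fillna(False)
    fc["is_positive_control"] = fc.index == positive_control
    fc["is_negative_control"] = fc.index == negative_control
    return fc.reset_index()


def call_hits(
    records: pd.DataFrame,
    positive_control: str = "SMCHD1",
    sum_threshold: float = 2.0,
    readouts: tuple = READOUTS,
    include_controls_in_stats: bool = False,
) -> pd.DataFrame:
    """Z-score both readouts and apply the dual-readout hit rule.

    z = (fc - mean) / sd, with mean and sample sd (n-1) taken over the
    detected library factors (controls excluded unless
    ``include_controls_in_stats``). A factor is a hit when it is
    detected, both z-scores exceed the positive control's, and their sum
    exceeds ``sum_threshold``.
    """
    rec = records.copy()
    if positive_control not in set(rec["factor_id"]):
        raise ValueError(f"positive control {positive_control!r} absent")
    pos_row = rec[rec["factor_id"] == positive_control].iloc[0]
    if not pos_row["detected"]:
        raise ValueError("positive control is undetected; screen cannot be scored")
    lib = rec["detected"].astype(bool).copy()
    if not include_controls_in_stats:
        lib &= ~(rec["is_positive_control"] | rec["is_negative_control"])
    if lib.sum() < 3:
        raise ValueError("need >= 3 detected library factors")
    for r in readouts:
        col = f"fc_{r}"
        mu = rec.loc[lib, col].mean()
        sd = rec.loc[lib, col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("degenerate screen: zero variance in fold changes")
        rec[f"z_{r}"] = (rec[col] - mu) / sd
    zpos = {r: float(rec.loc[rec["factor_id"] == positive_control, f"z_{r}"].iloc[0]) for r in readouts}
    both_greater = np.logical_and.reduce([rec[f"z_{r}"] > zpos[r] for r in readouts])
    zsum = sum(rec[f"z_{r}"] for r in readouts)
    is_library = ~(rec["is_positive_control"] | rec["is_negative_control"])
    rec["is_hit"] = rec["detected"].astype(bool) & is_library & both_greater & (zsum > sum_threshold)
    return rec


def run_screen(
    plate: pd.DataFrame,
    positive_control: str = "SMCHD1",
    negative_control: str = "GFP",
    detection_limit: float = 35.0,
    sum_threshold: float = 2.0,
    readouts: tuple = READOUTS,
) -> pd.DataFrame:
    """Score a Ct plate and call hits in one step."""
    fc = score_plate(
        plate,
        positive_control=positive_control,
        negative_control=negative_control,
        detection_limit=detection_limit,
        readouts=readouts,
    )
    return call_hits(fc, positive_control=positive_control, sum_threshold=sum_threshold, readouts=readouts)
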