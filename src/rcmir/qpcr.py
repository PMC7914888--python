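"""Efficiency-adjusted relative expression ratio (rER) for qPCR data.

A transcript's abundance ratio between control and treated samples is
estimated from cycle-threshold (Ct) values of the target and of a reference
gene (GAPDH for mRNAs, U6 snRNA for miRNAs), each corrected by its own
amplification efficiency E (ideal doubling: E = 2):

    rER = E_target^(dCt_target) / E_ref^(dCt_ref),   dCt = Ct_control - Ct_treated

With the control-minus-treated convention, rER > 1 means the target is
up-regulated in treated cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: plausible efficiency window: above 1 (some amplification) up to slightly
#: beyond perfect doubling, tolerating standard-curve overshoot
E_MIN, E_MAX = 1.0, 2.2


def _check_efficiency(e: float, name: str = "efficiency") -> None:
    if not (E_MIN < e <= E_MAX):
        raise ValueError(f"{name} must lie in ({E_MIN}, {E_MAX}]; got {e}")


@dataclass
class QpcrRecord:
    """Ct means and efficiencies for one target/reference pair and contrast."""

    target_id: str
    reference_id: str
    e_target: float
    e_ref: float
    ct_target_control: float
    ct_target_treated: float
    ct_ref_control: float
    ct_ref_treated: float

    def __post_init__(self) -> None:
        _check_efficiency(self.e_target, "target efficiency")
        _check_efficiency(self.e_ref, "reference efficiency")


def rer(rec: QpcrRecord) -> float:
    """Relative expression ratio of one record (closed form above)."""
    dct_t = rec.ct_target_control - rec.ct_target_treated
    dct_r = rec.ct_ref_control - rec.ct_ref_treated
    return float(rec.e_target**dct_t / rec.e_ref**dct_r)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope: E = 10^(-1/slope).

    The standard curve regresses Ct on log10(template amount); a slope of
    -3.32 corresponds to perfect doubling (E = 2).
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    return float(10.0 ** (-1.0 / slope))


def rer_table(
    measurements: pd.DataFrame,
    control_condition: str = "control",
    aggregate: str = "pairing",
) -> pd.DataFrame:
    """Per-target rER (mean +/- sd over replicates) from a long-format table.

    ``measurements`` columns: target_id, reference_id, condition, replicate,
    Ct, efficiency.  Every non-control condition is contrasted against
    ``control_condition``.

    aggregate = "pairing" computes one rER per replicate index (control
    replicate i paired with treated replicate i) and reports mean and sd;
    aggregate = "mean_ct" averages Ct over replicates first and reports a
    single rER with sd 0.
    """
    required = {"target_id", "reference_id", "condition", "replicate", "Ct",
                "efficiency"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    if aggregate not in ("pairing", "mean_ct"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    df = measurements.sort_values(["target_id", "condition", "replicate"],
                                  kind="stable")
    conditions = [c for c in df["condition"].unique() if c != control_condition]
    references = set(df["reference_id"])
    rows = []
    for (target, ref), sub in df.groupby(["target_id", "reference_id"], sort=True):
        if target in references:
            continue  # reference genes are not themselves contrasted
        ref_rows = df[df["target_id"] == ref]
        if ref_rows.empty:
            raise ValueError(f"reference {ref!r} has no measurement rows")
        e_t = float(sub["efficiency"].iloc[0])
        e_r = float(ref_rows["efficiency"].iloc[0])
        for cond in conditions:

            def cts(frame, c):
                out = frame.loc[frame["condition"] == c]
                if out.empty:
                    raise ValueError(
                        f"missing rows for condition {c!r} of {target!r}/{ref!r}"
                    )
                return out.sort_values("replicate", kind="stable")["Ct"].to_numpy()

            tc, tt = cts(sub, control_condition), cts(sub, cond)
            rc, rt = cts(ref_rows, control_condition), cts(ref_rows, cond)
            if aggregate == "mean_ct":
                vals = np.array(
                    [e_t ** (tc.mean() - tt.mean()) / e_r ** (rc.mean() - rt.mean())]
                )
            else:
                n = min(map(len, (tc, tt, rc, rt)))
                vals = e_t ** (tc[:n] - tt[:n]) / e_r ** (rc[:n] - rt[:n])
            rows.append(
                (
                    target,
                    ref,
                    cond,
                    float(vals.mean()),
                    float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    len(vals),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["target_id", "reference_id", "condition", "rer_mean", "rer_sd",
                 "n_replicates"],
    )
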