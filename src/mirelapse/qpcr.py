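"""Replicate-aware 2^-ddCt relative quantification.

Ct tables hold one row per technical replicate: (sample, assay, role,
replicate, ct), with role ``target`` or ``endogenous_control`` (5S RNA or
GAPDH-style normalizers).  Replicates are aggregated on the Ct scale
(arithmetic mean) *before* forming dCt — the conventional reading of the
2^-ddCt method — with the replicate SD propagated for QC.  Amplification
efficiency is fixed at 2 (the method's assumption); there is no efficiency
correction.

dCt   = Ct(target) - Ct(control)            per specimen
ddCt  = dCt(sample) - dCt(calibrator)
rq    = 2 ** -ddCt                           (exact arithmetic)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CT_COLUMNS = ("sample", "assay", "role", "replicate", "ct")
ROLES = ("target", "endogenous_control")


def validate_ct_table(ct: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")
    bad = set(ct["role"].unique()) - set(ROLES)
    if bad:
        raise ValueError(f"unknown roles {sorted(bad)}")


@dataclass
class RelativeExpression:
    """A 2^-ddCt quantity with its replicate provenance."""

    sample: str
    assay: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    log2_rq: float
    replicate_sd: float = np.nan

    def __post_init__(self) -> None:
        # identities of the method, enforced rather than trusted
        if not np.isclose(self.rq, 2.0**-self.delta_delta_ct, rtol=1e-12):
            raise ValueError("rq must equal 2**-ddCt")
        if not np.isclose(self.log2_rq, -self.delta_delta_ct, rtol=1e-12):
            raise ValueError("log2_rq must equal -ddCt")


def aggregate_replicates(ct: pd.DataFrame, max_sd: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (sample, assay) with SD-based QC.

    ``qc`` is "pass" when the replicate SD is <= ``max_sd`` Ct units,
    "high_sd" above it, and "unassessable" for a single replicate.
    """
    validate_ct_table(ct)
    rows = []
    for (sample, assay), grp in ct.groupby(["sample", "assay"], sort=True):
        vals = grp["ct"].to_numpy(dtype=float)
        mean = float(vals.mean())
        if len(vals) < 2:
            sd, qc = np.nan, "unassessable"
        else:
            sd = float(vals.std(ddof=1))
            qc = "pass" if sd <= max_sd else "high_sd"
        rows.append(
            {
                "sample": sample,
                "assay": assay,
                "role": grp["role"].iloc[0],
                "mean_ct": mean,
                "sd_ct": sd,
                "n_replicates": len(vals),
                "qc": qc,
            }
        )
    return pd.DataFrame(rows)


def ddct(
    sample_target_ct: float,
    sample_control_ct: float,
    calibrator_target_ct: float,
    calibrator_control_ct: float,
    sample: str = "sample",
    assay: str = "assay",
    replicate_sd: float = np.nan,
) -> RelativeExpression:
    """Relative quantity of one sample against a calibrator specimen."""
    d_sample = float(sample_target_ct) - float(sample_control_ct)
    d_cal = float(calibrator_target_ct) - float(calibrator_control_ct)
    dd = d_sample - d_cal
    return RelativeExpression(
        sample=sample,
        assay=assay,
        delta_ct=d_sample,
        delta_delta_ct=dd,
        rq=2.0**-dd,
        log2_rq=-dd,
        replicate_sd=replicate_sd,
    )


def relative_expression_from_table(
    ct: pd.DataFrame,
    calibrator: str,
    max_sd: float = 0.5,
) -> list[RelativeExpression]:
    """2^-ddCt for every (sample, target assay) against a calibrator sample.

    Replicates are first averaged on the Ct scale; the control assay is the
    table's ``endogenous_control`` row for the same sample.
    """
    agg = aggregate_replicates(ct, max_sd=max_sd)
    out = []
    controls = agg[agg["role"] == "endogenous_control"].set_index("sample")
    targets = agg[agg["role"] == "target"]
    if calibrator not in set(agg["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    for _, row in targets.iterrows():
        sample = row["sample"]
        if sample == calibrator:
            continue
        if sample not in controls.index or calibrator not in controls.index:
            raise ValueError(f"missing endogenous control for {sample!r} or calibrator")
        cal_t = targets[targets["sample"] == calibrator]
        cal_row = cal_t[cal_t["assay"] == row["assay"]]
        if cal_row.empty:
            raise ValueError(f"calibrator lacks assay {row['assay']!r}")
        out.append(
            ddct(
                row["mean_ct"],
                float(controls.loc[sample, "mean_ct"]),
                float(cal_row["mean_ct"].iloc[0]),
                float(controls.loc[calibrator, "mean_ct"]),
                sample=sample,
                assay=row["assay"],
                replicate_sd=float(row["sd_ct"]),
            )
        )
    return out


def paired_log2_comparison(
    rq_primary: dict[str, float],
    rq_relapse: dict[str, float],
) -> tuple[float, float, int]:
    """Mean +/- SD of log2(rq_relapse / rq_primary) over patients.

    A negative mean means lower expression in relapse.  Patients with a
    missing or non-positive quantity in either phase (undetected
    expression) are excluded with a logged note; the count of patients
    used is returned alongside mean and SD.
    """
    ratios = []
    for patient in sorted(set(rq_primary) & set(rq_relapse)):
        a, b = rq_primary[patient], rq_relapse[patient]
        if a is None or b is None or not np.isfinite([a, b]).all() or a <= 0 or b <= 0:
            logger.info("patient %s excluded: undetected expression", patient)
            continue
        ratios.append(np.log2(b / a))
    if not ratios:
        raise ValueError("no patient with detectable expression in both phases")
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr)


def relative_expression_frame(rows: list[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample for r in rows],
            "assay": [r.assay for r in rows],
            "delta_ct": [r.delta_ct for r in rows],
            "delta_delta_ct": [r.delta_delta_ct for r in rows],
            "rq": [r.rq for r in rows],
            "log2_rq": [r.log2_rq for r in rows],
            "replicate_sd": [r.replicate_sd for r in rows],
        }
    )
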