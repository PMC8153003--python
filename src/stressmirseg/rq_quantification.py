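"""Relative quantification of triplicate Ct values by the 2^-ddCt method.

Technical triplicates are averaged on the Ct scale (with a QC flag when
the replicate SD exceeds 0.5 cycles), delta-Ct is formed against the
endogenous reference (GAPDH for mRNAs, U6 snRNA for miRNAs), and the
calibrator delta-Ct per (area, analyte) is the mean delta-Ct of the
calibrator group (controls by default), so the calibrator group's
geometric-mean RQ is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic_cohort import DEFAULT_REFERENCE_MAP

logger = logging.getLogger(__name__)

DEFAULT_MAX_REPLICATE_SD = 0.5  # cycles


class QuantificationError(ValueError):
    """Invalid input to the RQ layer."""


@dataclass(frozen=True)
class ReplicateSummary:
    mean_ct: float
    sd: float
    flagged: bool


def aggregate_replicates(cts, max_sd: float = DEFAULT_MAX_REPLICATE_SD
                         ) -> ReplicateSummary:
    """Mean Ct of a technical triplicate, with a QC flag on high SD."""
    cts = np.asarray(cts, dtype=float)
    if cts.size != 3:
        raise QuantificationError(
            f"expected exactly 3 technical replicates, got {cts.size}"
        )
    mean = float(cts.mean())
    sd = float(cts.std(ddof=1))
    flagged = sd > max_sd
    if flagged:
        logger.warning("replicate SD %.3f cycles exceeds QC threshold %.2f",
                       sd, max_sd)
    return ReplicateSummary(mean, sd, flagged)


def relative_quantity(ct_target: float, ct_reference: float,
                      calibrator_delta_ct: float) -> float:
    """RQ = 2^-(ddCt) with ddCt = (ct_target - ct_reference) - calibrator."""
    for name, v in (("ct_target", ct_target), ("ct_reference", ct_reference),
                    ("calibrator_delta_ct", calibrator_delta_ct)):
        if not np.isfinite(v):
            raise QuantificationError(f"{name} is not finite: {v!r}")
    ddct = (ct_target - ct_reference) - calibrator_delta_ct
    return float(2.0 ** (-ddct))


def quantify_cohort(ct_table: pd.DataFrame,
                    phenotypes: Mapping[str, str] | pd.Series,
                    reference_map: Mapping[str, str] | None = None,
                    calibrator_group: str = "control",
                    max_replicate_sd: float = DEFAULT_MAX_REPLICATE_SD,
                    ) -> pd.DataFrame:
    """Per-mouse relative quantities for every (area, analyte).

    ``phenotypes`` maps mouse_id to its label (control / susceptible /
    resilient, or raw group labels); the calibrator delta-Ct per
    (area, analyte) is the mean delta-Ct over mice whose label equals
    ``calibrator_group``. Returns one row per (mouse, area, analyte) with
    delta_ct, rq, phenotype and a replicate-SD QC flag.
    """
    reference_map = dict(reference_map or DEFAULT_REFERENCE_MAP)
    phenotypes = pd.Series(dict(phenotypes) if not isinstance(phenotypes, pd.Series)
                           else phenotypes)

    agg = (ct_table.groupby(["mouse_id", "area", "analyte"], sort=False)["ct"]
           .agg(["mean", lambda v: v.std(ddof=1), "size"])
           .reset_index())
    agg.columns = ["mouse_id", "area", "analyte", "ct_mean", "ct_sd", "n_rep"]
    short = agg[agg["n_rep"] != 3]
    if len(short):
        row = short.iloc[0]
        raise QuantificationError(
            f"mouse {row['mouse_id']} {row['area']}/{row['analyte']} has "
            f"{row['n_rep']} replicates, expected 3"
        )
    n_flagged = int((agg["ct_sd"] > max_replicate_sd).sum())
    if n_flagged:
        logger.warning("%d (mouse, area, analyte) triplicates exceed the "
                       "%.2f-cycle SD QC threshold", n_flagged, max_replicate_sd)

    ref_ct = agg[agg["analyte"].isin(set(reference_map.values()))]
    ref_lookup = ref_ct.set_index(["mouse_id", "area", "analyte"])["ct_mean"]

    rows = []
    targets = agg[agg["analyte"].isin(reference_map)]
    for row in targets.itertuples(index=False):
        ref_analyte = reference_map[row.analyte]
        key = (row.mouse_id, row.area, ref_analyte)
        if key not in ref_lookup.index:
            raise QuantificationError(
                f"mouse {row.mouse_id} area {row.area}: reference analyte "
                f"{ref_analyte} required for {row.analyte} is missing"
            )
        delta_ct = row.ct_mean - float(ref_lookup[key])
        rows.append((row.mouse_id, row.area, row.analyte, delta_ct,
                     row.ct_sd > max_replicate_sd))
    out = pd.DataFrame(rows, columns=["mouse_id", "area", "analyte",
                                      "delta_ct", "replicate_qc_flag"])
    out["phenotype"] = out["mouse_id"].map(phenotypes)
    if out["phenotype"].isna().any():
        missing = out.loc[out["phenotype"].isna(), "mouse_id"].unique()
        raise QuantificationError(
            f"no phenotype label for mice: {sorted(missing)[:5]}"
        )

    calib = (out[out["phenotype"] == calibrator_group]
             .groupby(["area", "analyte"])["delta_ct"].mean())
    if calib.empty:
        raise QuantificationError(
            f"calibrator group {calibrator_group!r} has no mice"
        )
    keys = pd.MultiIndex.from_frame(out[["area", "analyte"]])
    out["rq"] = 2.0 ** (-(out["delta_ct"].to_numpy()
                          - calib.reindex(keys).to_numpy()))
    if out["rq"].isna().any():
        bad = out[out["rq"].isna()].iloc[0]
        raise QuantificationError(
            f"no calibrator-group mice for area {bad['area']} analyte "
            f"{bad['analyte']}"
        )
    cols = ["mouse_id", "area", "analyte", "delta_ct", "rq", "phenotype",
            "replicate_qc_flag"]
    return out[cols]


def rq_wide(rq_table: pd.DataFrame, area: str,
            value: str = "rq") -> pd.DataFrame:
    """Mouse-by-analyte matrix for one brain area."""
    sub = rq_table[rq_table["area"] == area]
    return sub.pivot(index="mouse_id", columns="analyte", values=value)
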