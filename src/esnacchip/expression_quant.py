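"""Exactly-specified quantitative conversions: delta-delta-Ct relative
expression, ChIP-qPCR input-normalized enrichment, and yeast beta-galactosidase
units. Amplification efficiency is fixed at 2.0 (classical ddCt)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class QpcrMeasurement:
    """Quantification cycles for target/reference genes in sample and calibrator."""

    gene_id: str
    ct_target_sample: float
    ct_ref_sample: float
    ct_target_calibrator: float
    ct_ref_calibrator: float
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        for name in ("ct_target_sample", "ct_ref_sample",
                     "ct_target_calibrator", "ct_ref_calibrator"):
            x = getattr(self, name)
            if not math.isfinite(x) or x <= 0:
                raise ValidationError(f"{self.gene_id}: {name} must be finite and > 0")


def rel_expression_ddct(m: QpcrMeasurement) -> float:
    """log2 relative expression = -ddCt, normalized to the calibrator line.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator, so
    the returned value is log2 of the classical 2^-ddCt fold change.
    """
    d_sample = m.ct_target_sample - m.ct_ref_sample
    d_cal = m.ct_target_calibrator - m.ct_ref_calibrator
    return -(d_sample - d_cal)


def chip_qpcr_percent_input(
    ct_ip: float, ct_input: float, input_dilution_cycles: float = 0.0
) -> float:
    """IP enrichment as a fraction of input: 2^((Ct_input - dilution) - Ct_ip)."""
    for name, x in (("ct_ip", ct_ip), ("ct_input", ct_input)):
        if not math.isfinite(x):
            raise ValidationError(f"{name} must be finite")
    return 2.0 ** ((ct_input - input_dilution_cycles) - ct_ip)


def beta_gal_units(od574: float, t: float, v: float, od600: float) -> float:
    """Miller-style units: 1000 * OD574 / (t[min] * V[mL] * OD600)."""
    if od574 < 0:
        raise ValidationError("od574 must be >= 0")
    for name, x in (("t", t), ("v", v), ("od600", od600)):
        if not (math.isfinite(x) and x > 0):
            raise ValidationError(f"{name} must be finite and > 0")
    return 1000.0 * od574 / (t * v * od600)


def ddct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Vectorized ddCt over a table with the QpcrMeasurement columns.

    Returns gene_id, replicate_id, rel_log2 (one row per input row).
    """
    required = ["gene_id", "ct_target_sample", "ct_ref_sample",
                "ct_target_calibrator", "ct_ref_calibrator"]
    missing = [c for c in required if c not in ct.columns]
    if missing:
        raise ValidationError(f"Ct table missing column(s): {', '.join(missing)}")
    rows = []
    for row in ct.itertuples(index=False):
        m = QpcrMeasurement(
            gene_id=str(row.gene_id),
            ct_target_sample=float(row.ct_target_sample),
            ct_ref_sample=float(row.ct_ref_sample),
            ct_target_calibrator=float(row.ct_target_calibrator),
            ct_ref_calibrator=float(row.ct_ref_calibrator),
            replicate_id=str(getattr(row, "replicate_id", "rep1")),
        )
        rows.append({"gene_id": m.gene_id, "replicate_id": m.replicate_id,
                     "rel_log2": rel_expression_ddct(m)})
    return pd.DataFrame(rows)


def betagal_table(od: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "od574", "t", "v", "od600"]
    missing = [c for c in required if c not in od.columns]
    if missing:
        raise ValidationError(f"OD table missing column(s): {', '.join(missing)}")
    out = od.copy()
    out["mu"] = [
        beta_gal_units(float(r.od574), float(r.t), float(r.v), float(r.od600))
        for r in od.itertuples(index=False)
    ]
    return out[["sample_id", "mu"]]
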