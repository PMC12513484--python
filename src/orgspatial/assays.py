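"""Quantitation utilities for the bench assays that accompany the
spatial analysis: relative qPCR expression by the 2^-ddCt method, and
radiolabeled deiodinase activity expressed as fractional conversion
normalized to protein and time (fmol/mg/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass
class CtRecord:
    """One qPCR measurement: target and reference cycle thresholds."""

    sample: str
    target_ct: float
    ref_ct: float
    condition: str = "control"

    def __post_init__(self) -> None:
        for name in ("target_ct", "ref_ct"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{name} must be finite (got {v!r})")
            if v <= 0:
                raise ValueError(f"{name} must be positive (got {v})")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.ref_ct


@dataclass
class ConversionAssay:
    """A radiolabeled iodothyronine conversion assay.

    ``product_counts`` is the T3 peak (cpm), ``total_counts`` the sum of
    all iodothyronine peaks; ``background_fraction`` is the product
    fraction measured in a no-cells assay and is subtracted before
    normalization to protein (mg) and incubation time (hours).
    """

    product_counts: float
    total_counts: float
    substrate_amount: float  # fmol
    protein: float  # mg
    duration: float  # hours
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.product_counts < 0 or self.total_counts < 0:
            raise ValueError("counts must be nonnegative")
        if self.product_counts > self.total_counts:
            raise ValueError("product counts cannot exceed total counts")
        if self.protein <= 0:
            raise ValueError("protein mass must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def ddct_fold_change(treated: CtRecord, control: CtRecord) -> float:
    """Relative expression of treated vs control by 2^-ddCt.

    ``dCt = target_ct - ref_ct`` within each condition;
    ``ddCt = dCt_treated - dCt_control``; the fold change is ``2**-ddCt``.
    """
    ddct = treated.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def ddct_from_table(
    table: pd.DataFrame,
    treated_label: str,
    control_label: str,
) -> dict:
    """Replicate-aware 2^-ddCt from a tidy Ct table.

    ``table`` needs columns ``sample, condition, target_ct, ref_ct``.
    Per-replicate dCt values are averaged within each condition, the fold
    change is formed on the ddCt (log) scale, and the spread is reported
    as the SD of per-replicate dCt in the treated condition.
    """
    required = {"sample", "condition", "target_ct", "ref_ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    dct = table["target_ct"] - table["ref_ct"]
    by_cond = dct.groupby(table["condition"])
    for label in (treated_label, control_label):
        if label not in by_cond.groups:
            raise ValueError(f"condition {label!r} absent from Ct table")
    ddct = by_cond.mean()[treated_label] - by_cond.mean()[control_label]
    sd_dct = float(by_cond.std(ddof=1).fillna(0.0)[treated_label])
    return {
        "fold_change": float(2.0**-ddct),
        "ddct": float(ddct),
        "sd_delta_ct": sd_dct,
        "n_treated": int(by_cond.size()[treated_label]),
        "n_control": int(by_cond.size()[control_label]),
    }


def deiodinase_activity(assay: ConversionAssay) -> float:
    """Deiodinase activity as fractional conversion per mg protein per hour.

    The net converted fraction is ``product/total - background_fraction``
    (floored at zero); the activity is
    ``net_fraction * substrate_amount / (protein * duration)`` in
    fmol / mg / h when the substrate is given in fmol and time in hours.
    """
    if assay.total_counts == 0:
        raise ValueError("total counts are zero; no chromatogram signal")
    fraction = assay.product_counts / assay.total_counts
    net = max(fraction - assay.background_fraction, 0.0)
    return net * assay.substrate_amount / (assay.protein * assay.duration)


def activity_from_fraction_table(
    fractions: pd.DataFrame,
    product_species: str,
    substrate_amount: float,
    protein: float,
    duration: float,
    background_fraction: float = 0.0,
) -> float:
    """Activity from a chromatogram fraction table (columns: species, cpm)."""
    required = {"species", "cpm"}
    missing = required - set(fractions.columns)
    if missing:
        raise ValueError(f"fraction table is missing columns {sorted(missing)}")
    total = float(fractions["cpm"].sum())
    product = float(
        fractions.loc[fractions["species"] == product_species, "cpm"].sum()
    )
    assay = ConversionAssay(
        product_counts=product,
        total_counts=total,
        substrate_amount=substrate_amount,
        protein=protein,
        duration=duration,
        background_fraction=background_fraction,
    )
    return deiodinase_activity(assay)
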