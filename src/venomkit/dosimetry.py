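"""Secretion dosimetry and activation-rate summaries.

Converts bulk venom-collection measurements (micrograms of protein from
millions of pooled worms over a few hours) into per-worm secretion rates,
extrapolates linearly in time, and expresses a lethal dose as the number of
worms needed to secrete it. Also summarizes infective-juvenile activation
time courses (non / partially / fully activated counts per replicate) into
mean proportions with standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from venomkit.errors import ValidationError


@dataclass(frozen=True)
class SecretionMeasurement:
    """Bulk collection: total protein (µg) from n_worms over duration hours."""

    total_protein_ug: float
    n_worms: int
    duration_h: float

    def __post_init__(self) -> None:
        if self.total_protein_ug <= 0 or self.duration_h <= 0:
            raise ValidationError("protein amount and duration must be positive")
        if self.n_worms <= 0:
            raise ValidationError("n_worms must be positive")


@dataclass(frozen=True)
class DoseEstimate:
    rate_per_worm_ng: float
    duration_h: float
    extrapolated_24h_ng: float
    worm_equivalents: int | None = None


def per_worm_rate(m: SecretionMeasurement) -> float:
    """ng of protein secreted per worm over the measured window."""
    return m.total_protein_ug * 1000.0 / m.n_worms


def extrapolate(rate_ng: float, duration_h: float, target_h: float) -> float:
    """Linear time-scaling of a per-worm rate, reported to 2 decimals (ng)."""
    if duration_h <= 0:
        raise ValidationError("duration must be positive")
    return round(rate_ng * target_h / duration_h, 2)


def worm_equivalents(dose_ng: float, per_worm_24h_ng: float) -> int:
    """Worms needed to secrete ``dose_ng`` in 24 h, to the nearest integer."""
    if per_worm_24h_ng <= 0:
        raise ValidationError("per-worm rate must be positive")
    return int(np.floor(dose_ng / per_worm_24h_ng + 0.5))


def dose_estimate(
    rate_ng: float,
    duration_h: float,
    lethal_dose_ng: float | None = None,
) -> DoseEstimate:
    """Bundle the 24 h extrapolation and (optionally) worm-equivalents."""
    rate_24h = extrapolate(rate_ng, duration_h, 24.0)
    return DoseEstimate(
        rate_per_worm_ng=rate_ng,
        duration_h=duration_h,
        extrapolated_24h_ng=rate_24h,
        worm_equivalents=(
            worm_equivalents(lethal_dose_ng, rate_24h)
            if lethal_dose_ng is not None
            else None
        ),
    )


def activation_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point activation proportions with standard errors.

    ``counts`` needs columns time_h, replicate, n_non, n_partial, n_full.
    For each replicate, proportions are computed over its total worms; per
    time point the replicate proportions are averaged and the standard error
    is sd/sqrt(n) with the sample (n-1) standard deviation. A single
    replicate yields SE = 0 by convention, flagged via ``n_replicates``.
    """
    required = {"time_h", "replicate", "n_non", "n_partial", "n_full"}
    if not required.issubset(counts.columns):
        raise ValidationError(f"activation table needs columns {sorted(required)}")
    totals = counts[["n_non", "n_partial", "n_full"]].sum(axis=1)
    if (totals <= 0).any():
        bad = counts.loc[totals <= 0, ["time_h", "replicate"]]
        raise ValidationError(
            f"replicates with zero total worms: {bad.to_dict('records')[:5]}"
        )
    props = counts.assign(
        p_partial=counts["n_partial"] / totals,
        p_full=counts["n_full"] / totals,
    )
    props["p_activated"] = props["p_partial"] + props["p_full"]

    rows = []
    for t, block in props.groupby("time_h"):
        n = len(block)
        row = {"time_h": t, "n_replicates": n}
        for col in ("p_partial", "p_full", "p_activated"):
            vals = block[col].to_numpy()
            row[f"mean_{col[2:]}"] = float(vals.mean())
            row[f"se_{col[2:]}"] = (
                float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("time_h").reset_index(drop=True)


def read_activation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
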