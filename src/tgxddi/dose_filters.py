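"""Cytotoxicity-based concentration exclusion (MTT viability threshold).

Treated conditions whose mean viability falls below 50% of the matched
vehicle control are excluded from the transcriptomic classification input;
the comet analysis keeps them but flags them as cytotoxic, since DNA damage
at overtly cytotoxic concentrations is not considered biologically relevant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError, PairingError

__all__ = ["relative_viability", "cytotoxic_exclusions"]


def relative_viability(absorbance: pd.DataFrame) -> pd.DataFrame:
    """Convert raw absorbance (e.g. MTT at 570 nm) to % of matched vehicle.

    ``absorbance`` needs columns chemical, concentration_uM, is_vehicle,
    replicate, absorbance. Each treated well is expressed as
    100 x absorbance / mean absorbance of that chemical's vehicle wells.
    Blank-corrected negative absorbances are clamped to 0 with a warning.
    """
    required = {"chemical", "concentration_uM", "is_vehicle", "replicate", "absorbance"}
    missing = required - set(absorbance.columns)
    if missing:
        raise DataError(f"absorbance table missing columns: {sorted(missing)}")
    df = absorbance.copy()
    if (df["absorbance"] < 0).any():
        warnings.warn("negative absorbance values clamped to 0", stacklevel=2)
        df["absorbance"] = df["absorbance"].clip(lower=0.0)
    rows = []
    for chem, g in df.groupby("chemical", sort=True):
        veh = g.loc[g["is_vehicle"].astype(bool), "absorbance"]
        if veh.empty:
            raise PairingError(f"no vehicle wells for chemical {chem!r}")
        ref = veh.mean()
        if ref <= 0:
            raise DataError(f"vehicle mean absorbance <= 0 for chemical {chem!r}")
        for _, r in g.iterrows():
            rows.append(
                {
                    "chemical": chem,
                    "concentration_uM": float(r["concentration_uM"]),
                    "replicate": r["replicate"],
                    "viability_pct": 100.0 * r["absorbance"] / ref,
                }
            )
    return pd.DataFrame(rows)


def cytotoxic_exclusions(
    viability: pd.DataFrame, threshold: float = 50.0
) -> dict[str, list[float]]:
    """Concentrations whose mean viability is strictly below the threshold.

    Decided on the mean across replicates; a condition at exactly the
    threshold is retained. Vehicle rows (concentration 0) are never excluded.
    Returns {chemical: sorted list of excluded concentrations (uM)}.
    """
    required = {"chemical", "concentration_uM", "viability_pct"}
    missing = required - set(viability.columns)
    if missing:
        raise DataError(f"viability table missing columns: {sorted(missing)}")
    out: dict[str, list[float]] = {}
    means = viability.groupby(["chemical", "concentration_uM"])["viability_pct"].mean()
    for (chem, conc), m in means.items():
        if conc > 0 and m < threshold:
            out.setdefault(chem, []).append(float(conc))
    return {c: sorted(v) for c, v in out.items()}
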