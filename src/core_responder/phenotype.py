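"""Drought-tolerance screening arithmetic on plant phenotype tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED = ("ecotype", "treatment", "soil_state", "fresh_weight_mg", "wilting_score")


def validate_phenotypes(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if (frame["fresh_weight_mg"] <= 0).any():
        raise ValueError("fresh weights must be positive")
    scores = frame["wilting_score"]
    if not scores.isin([1, 2, 3, 4, 5]).all():
        raise ValueError("wilting scores must be integers 1-5")
    if not frame["soil_state"].isin(["live", "sterilized"]).all():
        raise ValueError("soil_state must be 'live' or 'sterilized'")
    return frame


def tolerance_index(frame: pd.DataFrame, ecotype: str, soil_state: str = "live") -> float:
    """Mean wilting score of the ecotype's drought-treated plants."""
    sub = frame[
        (frame["ecotype"] == ecotype)
        & (frame["treatment"] == "drought")
        & (frame["soil_state"] == soil_state)
    ]
    if len(sub) == 0:
        raise ValueError(f"no drought plants for ecotype {ecotype!r}")
    return float(sub["wilting_score"].mean())


def rank_by_tolerance(frame: pd.DataFrame, top_k: int = 10, soil_state: str = "live"):
    """(top_k most tolerant, top_k most sensitive) ecotypes by tolerance index."""
    ecotypes = list(pd.unique(frame["ecotype"]))
    idx = {e: tolerance_index(frame, e, soil_state=soil_state) for e in ecotypes}
    ranked = sorted(ecotypes, key=lambda e: (-idx[e], e))
    return ranked[:top_k], ranked[-top_k:][::-1]


def relative_fresh_weight(frame: pd.DataFrame, ecotype: str, soil_state: str = "live") -> np.ndarray:
    """Each drought plant's weight over the matched control-group mean."""
    sub = frame[(frame["ecotype"] == ecotype) & (frame["soil_state"] == soil_state)]
    control = sub[sub["treatment"] == "control"]["fresh_weight_mg"]
    drought = sub[sub["treatment"] == "drought"]["fresh_weight_mg"]
    if len(control) < 2:
        raise ValueError(
            f"ecotype {ecotype!r}/{soil_state}: need >= 2 control plants, have {len(control)}"
        )
    return (drought / control.mean()).to_numpy()


def protection_effect(frame: pd.DataFrame, ecotype: str, mode: str = "ratio") -> float:
    """Microbiome-mediated protection: live-soil vs sterilized-soil tolerance.

    ratio mode (default): mean relative fresh weight in live soil divided by
    that in sterilized soil; > 1 indicates protection. ``mode='difference'``
    returns the difference instead.
    """
    live = relative_fresh_weight(frame, ecotype, "live").mean()
    sterilized = relative_fresh_weight(frame, ecotype, "sterilized").mean()
    if mode == "ratio":
        if sterilized == 0:
            raise ZeroDivisionError("sterilized-soil relative fresh weight is 0")
        return float(live / sterilized)
    if mode == "difference":
        return float(live - sterilized)
    raise ValueError(f"unknown mode: {mode!r}")


def rank_by_protection(frame: pd.DataFrame, top_k: int = 5, mode: str = "ratio"):
    ecotypes = list(pd.unique(frame["ecotype"]))
    eff = {e: protection_effect(frame, e, mode=mode) for e in ecotypes}
    ranked = sorted(ecotypes, key=lambda e: (-eff[e], e))
    return ranked[:top_k]
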