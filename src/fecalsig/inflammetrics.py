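"""Clinical harmonization and host-inflammation summary metrics.

Disease-activity indices (pediatric pUCAI/pCDAI, adult HBI/SCCAI) are
mapped to remission/mild/moderate/severe with standard conversion tables,
then collapsed to remission vs active.  Fecal calprotectin is capped at
2100 ug/g (assay saturation); capped records are excluded from downstream
regressions.  Treatment advancement encodes the therapy tier 0-4 (none ->
ASA/antibiotics/diet -> steroids -> immunomodulators ->
immunosuppressants/biologics).

The methylation-derived ratios NLR (neutrophil over B+T lymphocyte DNA)
and NER (neutrophil over small-intestine+colon epithelial DNA) summarize
the cellular balance of host DNA shed into stool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylprofile import SampleMethylationProfile

__all__ = [
    "ActivityResult",
    "harmonize_activity",
    "cap_calprotectin",
    "treatment_advancement",
    "nlr",
    "ner",
    "high_human_fraction",
    "harmonize_table",
    "DEFAULT_ACTIVITY_TABLES",
    "DEFAULT_TREATMENT_TIERS",
    "CALPROTECTIN_CAP",
]

CALPROTECTIN_CAP = 2100.0  # ug/g
DEFAULT_EPSILON = 0.01  # percentage points added to ratio denominators
DEFAULT_HUMAN_THRESHOLD = 1.0  # percent

# Upper bounds (inclusive) per level; anything above the last bound is severe.
DEFAULT_ACTIVITY_TABLES: dict[str, list[tuple[float, str]]] = {
    "pUCAI": [(9.999, "remission"), (34.999, "mild"), (64.999, "moderate"), (math.inf, "severe")],
    "pCDAI": [(9.999, "remission"), (30.0, "mild"), (math.inf, "moderate")],
    "HBI": [(4.0, "remission"), (7.0, "mild"), (16.0, "moderate"), (math.inf, "severe")],
    "SCCAI": [(2.0, "remission"), (5.0, "mild"), (11.0, "moderate"), (math.inf, "severe")],
}

DEFAULT_TREATMENT_TIERS: dict[str, int] = {
    "none": 0,
    "asa": 1, "asa_oral": 1, "asa_rectal": 1, "antibiotics": 1, "dietary_supplement": 1,
    "steroids": 2,
    "immunomodulators": 3,
    "immunosuppressants": 4, "biologics": 4,
}


@dataclass(frozen=True)
class ActivityResult:
    level: str  # remission / mild / moderate / severe
    activity: str  # remission / active


def harmonize_activity(
    score: float,
    scale: str,
    tables: Mapping[str, Sequence[tuple[float, str]]] | None = None,
) -> ActivityResult:
    """Map a raw activity score to a level, collapsed to remission/active."""
    tables = tables or DEFAULT_ACTIVITY_TABLES
    if scale not in tables:
        raise ValueError(f"unknown activity scale {scale!r}")
    level = None
    for bound, name in tables[scale]:
        if score <= bound:
            level = name
            break
    if level is None:  # pragma: no cover - tables end with +inf
        level = tables[scale][-1][1]
    return ActivityResult(level, "remission" if level == "remission" else "active")


def cap_calprotectin(value: float, cap: float = CALPROTECTIN_CAP) -> tuple[float, bool]:
    """Cap a calprotectin value at assay saturation; flag strictly-above values."""
    if value < 0:
        raise ValueError("calprotectin cannot be negative")
    return min(value, cap), value > cap


def treatment_advancement(
    treatments: Sequence[str],
    tiers: Mapping[str, int] | None = None,
) -> int:
    """Maximum therapy tier among the listed treatments (ordinal 0-4)."""
    tiers = tiers or DEFAULT_TREATMENT_TIERS
    out = 0
    for t in treatments:
        key = t.strip().lower().replace(" ", "_")
        if key not in tiers:
            raise ValueError(f"unknown treatment {t!r}")
        out = max(out, tiers[key])
    return out


def _ratio(
    profile: SampleMethylationProfile,
    numerator: Sequence[str],
    denominator: Sequence[str],
    epsilon: float,
    normalized: bool,
) -> float:
    source = profile.normalized_fraction if normalized else profile.per_cell_type_fraction
    if normalized and source is None:
        raise ValueError(f"{profile.sample_id}: profile has no normalized fractions")
    missing = [c for c in (*numerator, *denominator) if c not in source]
    if missing:
        raise ValueError(f"{profile.sample_id}: missing cell types {missing}")
    num = sum(source[c] for c in numerator)
    den = sum(source[c] for c in denominator) + epsilon
    if den == 0:
        raise ZeroDivisionError(
            "ratio denominator is zero; set epsilon > 0 to stabilize"
        )
    return num / den


def nlr(
    profile: SampleMethylationProfile,
    epsilon: float = DEFAULT_EPSILON,
    normalized: bool = False,
) -> float:
    """Neutrophil / (B cell + T cell) DNA-percentage ratio."""
    return _ratio(profile, ["neutrophil"], ["B_cell", "T_cell"], epsilon, normalized)


def ner(
    profile: SampleMethylationProfile,
    epsilon: float = DEFAULT_EPSILON,
    normalized: bool = False,
) -> float:
    """Neutrophil / (small intestine + colon) DNA-percentage ratio."""
    return _ratio(profile, ["neutrophil"], ["small_intestine", "colon"], epsilon, normalized)


def high_human_fraction(
    samples: pd.DataFrame,
    threshold: float = DEFAULT_HUMAN_THRESHOLD,
    group_cols: Sequence[str] = ("group", "activity"),
    human_col: str = "human_pct",
) -> pd.DataFrame:
    """Fraction of samples with human DNA strictly above threshold, per cell.

    Cells (group x activity) with no samples yield NaN with a warning.
    """
    if human_col not in samples.columns:
        raise ValueError(f"missing column {human_col!r}")
    rows = []
    grouped = samples.groupby(list(group_cols), dropna=False, observed=True)
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        n = len(sub)
        if n == 0:  # pragma: no cover
            warnings.warn(f"empty cell {key}", stacklevel=2)
            frac = np.nan
        else:
            frac = float((sub[human_col] > threshold).sum()) / n
        rows.append(dict(zip(group_cols, key), n=n, fraction_above=frac))
    return pd.DataFrame(rows)


def harmonize_table(
    clinical: pd.DataFrame,
    tables: Mapping[str, Sequence[tuple[float, str]]] | None = None,
    relabel_ibdu: bool = True,
    cap: float = CALPROTECTIN_CAP,
) -> pd.DataFrame:
    """Harmonize a raw clinical table: activity, calprotectin cap, IBDU.

    Expects columns sample_id, group, activity_score_raw, activity_scale,
    calprotectin; adds activity, activity_level, calprotectin_capped, and
    relabels IBDU records as UC when requested.
    """
    out = clinical.copy()
    if relabel_ibdu and "group" in out.columns:
        out.loc[out["group"] == "IBDU", "group"] = "UC"
    levels, acts = [], []
    for _, r in out.iterrows():
        scale = r.get("activity_scale", "none")
        if scale in (None, "none", "") or pd.isna(r.get("activity_score_raw")):
            levels.append("NA")
            acts.append("NA")
        else:
            res = harmonize_activity(float(r["activity_score_raw"]), str(scale), tables)
            levels.append(res.level)
            acts.append(res.activity)
    out["activity_level"] = levels
    out["activity"] = acts
    capped_vals, flags = [], []
    for v in out["calprotectin"]:
        if pd.isna(v):
            capped_vals.append(np.nan)
            flags.append(False)
        else:
            cv, fl = cap_calprotectin(float(v), cap)
            capped_vals.append(cv)
            flags.append(fl)
    out["calprotectin"] = capped_vals
    new_flags = pd.Series(flags, index=out.index)
    if "calprotectin_capped" in out.columns:
        out["calprotectin_capped"] = out["calprotectin_capped"].astype(bool) | new_flags
    else:
        out["calprotectin_capped"] = new_flags
    return out
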