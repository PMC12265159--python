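"""Droplet digital PCR absolute quantification of human DNA.

Droplet partitioning follows Poisson statistics: with lambda copies per
droplet on average, a droplet stays negative with probability exp(-lambda),
so lambda = -ln(negative / total).  Each detected copy of a single-copy
human locus represents one genome equivalent, taken as 3.3 pg of human DNA;
dividing by the assay input mass gives the human percentage of fecal DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .methylprofile import SampleMethylationProfile

__all__ = [
    "DropletCounts",
    "DdpcrQuant",
    "SaturationError",
    "EmptyReactionError",
    "quantify",
    "normalize_cell_fractions",
    "quantify_table",
]

GENOME_EQUIVALENT_PG = 3.3
DEFAULT_INPUT_MASS_NG = 5.0


class SaturationError(ValueError):
    """All droplets positive: copy number is unbounded."""


class EmptyReactionError(ValueError):
    """No droplets generated in the reaction."""


@dataclass(frozen=True)
class DropletCounts:
    total: int
    positive: int
    negative: int

    def __post_init__(self) -> None:
        if min(self.total, self.positive, self.negative) < 0:
            raise ValueError("droplet counts must be non-negative")
        if self.positive + self.negative != self.total:
            raise ValueError(
                f"positive ({self.positive}) + negative ({self.negative}) "
                f"!= total ({self.total})"
            )


@dataclass(frozen=True)
class DdpcrQuant:
    """Absolute quantification result for one reaction."""

    lambda_per_droplet: float
    copies: float
    mass_pg: float
    human_pct: float
    input_mass_ng: float
    saturated: bool = False


def quantify(
    d: DropletCounts,
    input_mass_ng: float = DEFAULT_INPUT_MASS_NG,
    genome_equiv_pg: float = GENOME_EQUIVALENT_PG,
) -> DdpcrQuant:
    """Convert droplet counts into copies, mass and human DNA percentage.

    lambda = -ln(negative/total); copies = lambda * total;
    mass_pg = copies * genome_equiv_pg;
    human_pct = mass_pg / (input_mass_ng * 1000) * 100, capped at 100 with a
    saturation flag when the nominal value exceeds 100.
    """
    if d.total == 0:
        raise EmptyReactionError("reaction has zero droplets")
    if d.negative == 0:
        raise SaturationError(
            f"all {d.total} droplets positive; copy number unbounded"
        )
    lam = -math.log(d.negative / d.total)
    copies = lam * d.total
    mass_pg = copies * genome_equiv_pg
    human_pct = mass_pg / (input_mass_ng * 1000.0) * 100.0
    saturated = human_pct > 100.0
    if saturated:
        human_pct = 100.0
    return DdpcrQuant(lam, copies, mass_pg, human_pct, input_mass_ng, saturated)


def normalize_cell_fractions(
    profile: "SampleMethylationProfile", quant: DdpcrQuant
) -> "SampleMethylationProfile":
    """Scale per-cell-type fractions of human DNA to fractions of total fecal DNA.

    normalized[c] = per_cell_type_fraction[c] * human_pct / 100.  Re-normalizing
    an already-normalized profile is rejected.
    """
    if not profile.qc_pass:
        raise ValueError(f"profile {profile.sample_id} failed QC ({profile.qc_reason})")
    if profile.normalized_fraction is not None:
        raise ValueError(f"profile {profile.sample_id} is already normalized")
    normalized = {
        c: f * quant.human_pct / 100.0
        for c, f in profile.per_cell_type_fraction.items()
    }
    return replace(profile, normalized_fraction=normalized)


def quantify_table(
    droplets: pd.DataFrame,
    input_mass_ng: float = DEFAULT_INPUT_MASS_NG,
    genome_equiv_pg: float = GENOME_EQUIVALENT_PG,
) -> pd.DataFrame:
    """Vector version over a TSV-shaped table.

    Expects columns sample_id, total_droplets, positive, negative; adds
    lambda, copies, mass_pg, human_pct, saturated.
    """
    out = droplets.copy()
    rows = []
    for _, r in droplets.iterrows():
        q = quantify(
            DropletCounts(int(r["total_droplets"]), int(r["positive"]), int(r["negative"])),
            input_mass_ng=input_mass_ng,
            genome_equiv_pg=genome_equiv_pg,
        )
        rows.append((q.lambda_per_droplet, q.copies, q.mass_pg, q.human_pct, q.saturated))
    out[["lambda", "copies", "mass_pg", "human_pct", "saturated"]] = pd.DataFrame(
        rows, index=droplets.index
    )
    return out


def read_droplet_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "total_droplets", "positive", "negative"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"droplet table missing columns: {sorted(missing)}")
    return df
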