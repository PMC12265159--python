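"""Metagenomic host-read fraction and species-profile handling.

The host signal in shotgun fecal metagenomics is the percentage of reads
mapping to the human genome.  Species-level community profiles arrive as
MetaPhlAn-style merged tables (rows = clade lineages, columns = samples,
values = relative abundance in percent); only species-level rows are kept.

Subsampling to a fixed non-human depth reconstructs approximate read counts
as abundance x non-human reads and multinomially resamples them — the
control analysis showing richness differences are not a sequencing-depth
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReadCounts",
    "TaxProfile",
    "TaxProfileParseError",
    "human_read_pct",
    "load_taxprofile",
    "subsample_nonhuman",
]

DEFAULT_SUBSAMPLE_DEPTH = 1_000_000


class TaxProfileParseError(ValueError):
    pass


@dataclass(frozen=True)
class ReadCounts:
    total_reads: int
    human_reads: int
    nonhuman_reads: int

    def __post_init__(self) -> None:
        if min(self.total_reads, self.human_reads, self.nonhuman_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.human_reads + self.nonhuman_reads != self.total_reads:
            raise ValueError("human + nonhuman must equal total")


@dataclass
class TaxProfile:
    """Species x sample relative-abundance matrix (percent) with read counts."""

    matrix: pd.DataFrame  # species x samples
    read_counts: pd.DataFrame | None = None  # indexed by sample_id
    unnormalized: bool = False

    def __post_init__(self) -> None:
        if (self.matrix.values < 0).any():
            raise ValueError("negative abundance")
        if not self.unnormalized and len(self.matrix):
            sums = self.matrix.sum(axis=0)
            bad = sums[(sums < 99) | (sums > 101)]
            if len(bad):
                raise ValueError(
                    f"per-sample abundance sums outside [99, 101] for "
                    f"{list(bad.index[:5])}; pass unnormalized=True to keep"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.index)


def human_read_pct(c: ReadCounts) -> float:
    """Percentage of total reads that are human."""
    if c.total_reads == 0:
        raise ValueError("total_reads is zero")
    return 100.0 * c.human_reads / c.total_reads


def load_taxprofile(
    path: str | Path,
    read_counts: pd.DataFrame | None = None,
) -> TaxProfile:
    """Parse a MetaPhlAn-style merged abundance table down to species level.

    Keeps rows whose deepest rank token starts with ``s__`` (no ``t__``
    strain level below), strips the lineage prefix, and rejects duplicated
    species ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.name is None and df.empty:
        raise TaxProfileParseError(f"{path}: malformed or empty header")
    species_rows = {}
    for lineno, (lineage, row) in enumerate(df.iterrows(), start=2):
        last = str(lineage).split("|")[-1]
        if not last.startswith("s__"):
            continue
        name = last[3:]
        if name in species_rows:
            raise TaxProfileParseError(f"{path}:{lineno}: duplicated species {name!r}")
        vals = pd.to_numeric(row, errors="coerce")
        if vals.isna().any():
            raise TaxProfileParseError(f"{path}:{lineno}: non-numeric abundance")
        if (vals < 0).any():
            raise TaxProfileParseError(f"{path}:{lineno}: negative abundance")
        species_rows[name] = vals
    if not species_rows:
        import warnings

        warnings.warn(f"{path}: no species-level rows found", stacklevel=2)
        matrix = pd.DataFrame(columns=df.columns)
    else:
        matrix = pd.DataFrame(species_rows).T
        matrix.columns = df.columns
    matrix.index.name = "species"
    return TaxProfile(matrix=matrix, read_counts=read_counts, unnormalized=True)


@dataclass
class SubsampleReport:
    depth: int
    dropped_samples: list[str] = field(default_factory=list)


def subsample_nonhuman(
    profile: TaxProfile,
    depth: int = DEFAULT_SUBSAMPLE_DEPTH,
    seed: int = 0,
) -> tuple[TaxProfile, SubsampleReport]:
    """Multinomial subsampling of every sample to a fixed non-human depth.

    Per-species read counts are reconstructed as abundance x non-human
    reads (rounded), then ``depth`` reads are drawn without replacement
    approximation (multinomial) and renormalized to percent.  Samples with
    fewer non-human reads than ``depth`` are dropped and listed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if profile.read_counts is None:
        raise ValueError("profile carries no read counts; cannot subsample")
    rng = np.random.default_rng(seed)
    report = SubsampleReport(depth=depth)
    cols = {}
    rc = profile.read_counts.set_index("sample_id") if "sample_id" in profile.read_counts.columns else profile.read_counts
    for sid in profile.samples:
        nonhuman = int(rc.loc[sid, "nonhuman_reads"])
        if nonhuman < depth:
            report.dropped_samples.append(sid)
            continue
        ab = profile.matrix[sid].to_numpy(dtype=float)
        counts = np.rint(ab / ab.sum() * nonhuman).astype(np.int64)
        tot = counts.sum()
        if tot == 0:
            report.dropped_samples.append(sid)
            continue
        sub = rng.multinomial(depth, counts / tot)
        cols[sid] = sub / depth * 100.0
    matrix = pd.DataFrame(cols, index=profile.matrix.index)
    matrix.index.name = "species"
    kept = [s for s in profile.samples if s in cols]
    new_rc = rc.loc[kept].reset_index() if len(kept) else None
    return TaxProfile(matrix=matrix[kept] if kept else matrix, read_counts=new_rc), report
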