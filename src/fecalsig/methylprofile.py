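"""Targeted bisulfite amplicon methylation profiling and deconvolution.

Reads are compared to each marker reference in *bisulfite space*: after
conversion an unmethylated C reads as T, so a reference C (CpG or not)
matches either C or T in the read while every other position must match
literally.  The comparison is ungapped and anchored at the 5' end — the
amplicons are fixed-locus, so no alignment is needed.

At each CpG site a molecule reads "CG" (methylated) or "TG" (unmethylated);
anything else is ambiguous.  The fraction of molecules whose CpG sites are
all unmethylated estimates the marker's target cell-type fraction of the
human DNA in the sample.

QC rules: reads below 80% similarity to every marker are discarded; reads
with more than 10% unconverted non-CpG cytosines are discarded (failed
bisulfite conversion); samples with fewer than 1000 retained reads, or with
cell-type fractions summing below 5% or above 150%, fail sample QC.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markers import Marker, MarkerPanel, PanelError

__all__ = [
    "CpGState",
    "MoleculeCall",
    "MarkerFraction",
    "SampleMethylationProfile",
    "match_read",
    "call_cpgs",
    "marker_fraction",
    "aggregate_sample",
    "read_fastq",
    "profiles_to_frame",
]

DEFAULT_MIN_SIMILARITY = 80.0
DEFAULT_MIN_READS = 1000
DEFAULT_SUM_BOUNDS = (5.0, 150.0)  # percent
DEFAULT_MAX_UNCONVERTED = 0.10

_C = ord("C")
_G = ord("G")
_T = ord("T")


class CpGState(IntEnum):
    UNMETH = 0
    METH = 1
    AMBIG = -1


@dataclass(frozen=True)
class MoleculeCall:
    marker_id: str
    similarity: float
    cpg_states: tuple[CpGState, ...]
    conversion_ok: bool

    @property
    def fully_unmethylated(self) -> bool:
        return all(s == CpGState.UNMETH for s in self.cpg_states)

    @property
    def has_ambiguous(self) -> bool:
        return any(s == CpGState.AMBIG for s in self.cpg_states)


@dataclass(frozen=True)
class MarkerFraction:
    n: int
    n_all_unmeth: int
    fraction: float
    warning: bool = False  # true when no usable molecules remained


@dataclass(frozen=True)
class SampleMethylationProfile:
    sample_id: str
    per_marker: dict[str, MarkerFraction]
    per_cell_type_fraction: dict[str, float]  # percent of human DNA
    total_reads: int  # retained after similarity + conversion QC
    qc_pass: bool
    qc_reason: str
    normalized_fraction: dict[str, float] | None = None  # percent of fecal DNA
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# read/reference comparison
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _similarity_matrix(reads: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Percent identity of each read row vs one reference, bisulfite space."""
    ov = min(reads.shape[1], ref.size)
    r = ref[:ov]
    block = reads[:, :ov]
    match = (block == r) | ((r == _C) & (block == _T))
    return match.sum(axis=1) / ov * 100.0


def match_read(
    read: str,
    panel: MarkerPanel,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> tuple[str, float] | None:
    """Assign a read to its best marker, or None below the similarity cutoff.

    Ties go to the first marker in panel order; reads shorter than half of
    every reference are unassignable.
    """
    if not read:
        raise ValueError("empty read")
    enc = _encode(read)[None, :]
    best: tuple[str, float] | None = None
    for marker in panel:
        if enc.shape[1] < 0.5 * len(marker.sequence):
            continue
        sim = float(_similarity_matrix(enc, _encode(marker.sequence))[0])
        if best is None or sim > best[1]:
            best = (marker.marker_id, sim)
    if best is None or best[1] < min_similarity:
        return None
    return best


def call_cpgs(
    read: str,
    marker: Marker,
    max_unconverted_frac: float = DEFAULT_MAX_UNCONVERTED,
) -> MoleculeCall:
    """Call the methylation state at each CpG site of a matched read.

    "CG" -> methylated, "TG" -> unmethylated, anything else (including a
    site beyond the read end) -> ambiguous.  A read whose non-CpG reference
    cytosines remained cytosine at more than ``max_unconverted_frac`` of
    positions failed bisulfite conversion.
    """
    enc = _encode(read)
    ref = _encode(marker.sequence)
    states = []
    for o in marker.cpg_offsets:
        if o + 1 >= enc.size:
            states.append(CpGState.AMBIG)
        elif enc[o] == _C and enc[o + 1] == _G:
            states.append(CpGState.METH)
        elif enc[o] == _T and enc[o + 1] == _G:
            states.append(CpGState.UNMETH)
        else:
            states.append(CpGState.AMBIG)
    noncpg_c = [
        i for i in range(min(enc.size, ref.size))
        if ref[i] == _C and i not in marker.cpg_offsets
    ]
    if noncpg_c:
        unconverted = sum(1 for i in noncpg_c if enc[i] == _C) / len(noncpg_c)
    else:
        unconverted = 0.0
    sim = float(_similarity_matrix(enc[None, : ], ref)[0])
    return MoleculeCall(
        marker_id=marker.marker_id,
        similarity=sim,
        cpg_states=tuple(states),
        conversion_ok=unconverted <= max_unconverted_frac,
    )


def marker_fraction(calls: Sequence[MoleculeCall]) -> MarkerFraction:
    """Fully-unmethylated fraction over one marker's molecules.

    Molecules with any ambiguous site are excluded from numerator and
    denominator; with no usable molecules the fraction is 0 with a warning.
    """
    usable = [c for c in calls if not c.has_ambiguous]
    n = len(usable)
    if n == 0:
        return MarkerFraction(0, 0, 0.0, warning=True)
    n_unmeth = sum(1 for c in usable if c.fully_unmethylated)
    return MarkerFraction(n, n_unmeth, n_unmeth / n)


# ---------------------------------------------------------------------------
# vectorized per-sample aggregation
# ---------------------------------------------------------------------------

def _assign_reads(
    seqs: Sequence[str], panel: MarkerPanel, min_similarity: float
) -> np.ndarray:
    """Best-marker index per read (-1 = no match), vectorized by read length."""
    assign = np.full(len(seqs), -1, dtype=int)
    lengths = np.array([len(s) for s in seqs])
    refs = [_encode(m.sequence) for m in panel]
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        block = np.frombuffer(
            "".join(seqs[i] for i in idx).upper().encode("ascii"), dtype=np.uint8
        ).reshape(len(idx), L)
        best_sim = np.full(len(idx), -1.0)
        best_m = np.full(len(idx), -1, dtype=int)
        for mi, ref in enumerate(refs):
            if L < 0.5 * ref.size:
                continue
            sim = _similarity_matrix(block, ref)
            better = sim > best_sim  # strict: ties keep earlier marker
            best_sim[better] = sim[better]
            best_m[better] = mi
        ok = best_sim >= min_similarity
        assign[idx[ok]] = best_m[ok]
    return assign


def aggregate_sample(
    reads: Iterable[tuple[str, str] | str],
    panel: MarkerPanel,
    ddpcr_human_pct: float | None = None,
    *,
    sample_id: str = "sample",
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    min_reads: int = DEFAULT_MIN_READS,
    sum_bounds: tuple[float, float] = DEFAULT_SUM_BOUNDS,
    max_unconverted_frac: float = DEFAULT_MAX_UNCONVERTED,
    weight_by_depth: bool = False,
) -> SampleMethylationProfile:
    """Full per-sample deconvolution: match, QC, call, aggregate.

    Cell-type fractions are the unweighted mean of the cell type's marker
    fractions (depth-weighted optional), expressed in percent of human DNA.
    Raw fractions are not renormalized; their sum is only checked against
    the QC window.
    """
    if len(panel) == 0:
        raise PanelError("empty marker panel")
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    warnings: list[str] = []
    per_marker: dict[str, MarkerFraction] = {}
    retained_total = 0

    if seqs:
        assign = _assign_reads(seqs, panel, min_similarity)
    else:
        assign = np.empty(0, dtype=int)

    for mi, marker in enumerate(panel):
        idx = np.flatnonzero(assign == mi)
        if idx.size == 0:
            per_marker[marker.marker_id] = MarkerFraction(0, 0, 0.0, warning=True)
            warnings.append(f"no_reads:{marker.marker_id}")
            continue
        ref = _encode(marker.sequence)
        L = ref.size
        sub = [seqs[i] for i in idx]
        maxlen = max(len(s) for s in sub)
        block = np.full((len(sub), maxlen), 0, dtype=np.uint8)
        for r, s in enumerate(sub):
            block[r, : len(s)] = _encode(s)
        read_len = np.array([len(s) for s in sub])

        cpg = np.array(marker.cpg_offsets, dtype=int)
        # conversion QC on non-CpG reference cytosines within the read
        noncpg_c = np.array(
            [i for i in np.flatnonzero(ref == _C) if i not in set(marker.cpg_offsets)],
            dtype=int,
        )
        if noncpg_c.size:
            in_read = read_len[:, None] > noncpg_c[None, :]
            still_c = (block[:, noncpg_c] == _C) & in_read
            denom = in_read.sum(axis=1)
            unconv = np.where(denom > 0, still_c.sum(axis=1) / np.maximum(denom, 1), 0.0)
            conv_ok = unconv <= max_unconverted_frac
        else:
            conv_ok = np.ones(len(sub), dtype=bool)
        n_conv_fail = int((~conv_ok).sum())
        if n_conv_fail:
            warnings.append(f"conversion_fail:{marker.marker_id}:{n_conv_fail}")
        retained_total += int(conv_ok.sum())

        kept = block[conv_ok]
        klen = read_len[conv_ok]
        if kept.shape[0] == 0:
            per_marker[marker.marker_id] = MarkerFraction(0, 0, 0.0, warning=True)
            continue
        within = klen[:, None] > (cpg[None, :] + 1)
        c_at = kept[:, cpg]
        g_at = kept[:, cpg + 1]
        meth = (c_at == _C) & (g_at == _G) & within
        unmeth = (c_at == _T) & (g_at == _G) & within
        ambig = ~(meth | unmeth)
        usable = ~ambig.any(axis=1)
        n = int(usable.sum())
        if n == 0:
            per_marker[marker.marker_id] = MarkerFraction(0, 0, 0.0, warning=True)
            warnings.append(f"all_ambiguous:{marker.marker_id}")
            continue
        n_unmeth = int(unmeth[usable].all(axis=1).sum())
        per_marker[marker.marker_id] = MarkerFraction(n, n_unmeth, n_unmeth / n)

    # aggregate markers -> cell types (percent of human DNA)
    per_cell: dict[str, float] = {}
    for ct in panel.cell_types:
        fracs = []
        weights = []
        for m in panel.markers_for(ct):
            mf = per_marker[m.marker_id]
            fracs.append(mf.fraction)
            weights.append(mf.n)
        if weight_by_depth and sum(weights) > 0:
            val = float(np.average(fracs, weights=weights))
        else:
            val = float(np.mean(fracs))
        per_cell[ct] = val * 100.0

    qc_pass, qc_reason = True, ""
    if retained_total < min_reads:
        qc_pass, qc_reason = False, "low_reads"
    else:
        total_frac = sum(per_cell.values())
        if total_frac < sum_bounds[0] or total_frac > sum_bounds[1]:
            qc_pass, qc_reason = False, "fraction_sum"

    normalized = None
    if ddpcr_human_pct is not None:
        normalized = {c: f * ddpcr_human_pct / 100.0 for c, f in per_cell.items()}

    return SampleMethylationProfile(
        sample_id=sample_id,
        per_marker=per_marker,
        per_cell_type_fraction=per_cell,
        total_reads=retained_total,
        qc_pass=qc_pass,
        qc_reason=qc_reason,
        normalized_fraction=normalized,
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file (plain or gzip) into (name, sequence) pairs."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]


def profiles_to_frame(profiles: Sequence[SampleMethylationProfile]) -> pd.DataFrame:
    """Cohort-level wide table: samples x cell types plus QC columns."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"sample_id": p.sample_id}
        row.update(p.per_cell_type_fraction)
        row["total_reads"] = p.total_reads
        row["qc_pass"] = p.qc_pass
        row["qc_reason"] = p.qc_reason
        if p.normalized_fraction is not None:
            row.update({f"{c}_normalized": v for c, v in p.normalized_fraction.items()})
        rows.append(row)
    return pd.DataFrame(rows)
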