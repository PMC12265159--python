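"""Synthetic fecal-DNA cohort generator.

Produces every input the analysis pipeline consumes — targeted bisulfite
amplicon reads, ddPCR droplet counts, metagenomic read counts, species-level
taxonomic tables and a clinical metadata table — with the statistical
structure the downstream stages assume:

* human DNA in feces is a cell-type mixture; a molecule originating from a
  marker's own cell type is fully unmethylated at that marker's CpG sites
  and fully methylated otherwise (all-or-none per molecule);
* droplet partitioning is Poisson, so a droplet is positive with
  probability 1 - exp(-copies/droplets);
* species presence is Bernoulli per group with log-normal abundance within
  presence, with optional planted lost/expanded taxa per disease group;
* fecal calprotectin follows a linear predictor over human-DNA percentage,
  disease activity, treatment tier and age, with a per-subject random
  intercept and Gaussian noise truncated at zero.

Every operation is deterministic under its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddpcr import DropletCounts, GENOME_EQUIVALENT_PG, DEFAULT_INPUT_MASS_NG
from .markers import Marker, MarkerPanel, PanelError

__all__ = [
    "MixtureSpec",
    "PlantedEffect",
    "CohortConfig",
    "SyntheticCohort",
    "generate_marker_panel",
    "simulate_bisulfite_reads",
    "simulate_ddpcr",
    "simulate_cohort",
    "write_fastq",
    "default_planted_categories",
]

GROUPS = ("Control", "CD", "UC")
CATEGORIES = (
    "IBD_LOST", "CD_LOST", "UC_LOST",
    "IBD_EXPANDED", "CD_EXPANDED", "UC_EXPANDED",
    "UNCHANGED",
)

DEFAULT_CELL_TYPES = (
    "neutrophil", "monocyte", "B_cell", "T_cell", "colon", "small_intestine",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (int(b) for b in _BASES)


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth composition of one sample's human DNA."""

    cell_fractions: Mapping[str, float]
    total_human_pct: float

    def __post_init__(self) -> None:
        fracs = np.array(list(self.cell_fractions.values()), dtype=float)
        if (fracs < 0).any():
            raise ValueError("cell fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"cell fractions sum to {fracs.sum()}, expected 1")
        if not 0.0 <= self.total_human_pct <= 100.0:
            raise ValueError("total_human_pct must lie in [0, 100]")


@dataclass(frozen=True)
class PlantedEffect:
    """Planted differential-abundance effect for one species.

    abundance_fold multiplies the within-presence abundance; presence_fold
    multiplies the presence probability (defaults to the abundance fold,
    clipped to [0.02, 5]) in the affected disease groups.
    """

    category: str
    abundance_fold: float = 1.0
    presence_fold: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.presence_fold is None:
            object.__setattr__(
                self, "presence_fold", float(np.clip(self.abundance_fold, 0.02, 5.0))
            )

    @property
    def affected_groups(self) -> tuple[str, ...]:
        if self.category == "UNCHANGED":
            return ()
        prefix = self.category.split("_")[0]
        return ("CD", "UC") if prefix == "IBD" else (prefix,)


def default_planted_categories(n_pool: int) -> dict[str, PlantedEffect]:
    """A representative planted set: strong losses and expansions.

    Fold changes of 0.05 (20-fold loss) and 20 (20-fold expansion) give the
    classifier a clear presence-driven signal.
    """
    names = [f"Species_{i:04d}" for i in range(n_pool)]
    planted = {}
    specs = [
        ("IBD_LOST", 0.05, 4), ("CD_LOST", 0.05, 2), ("UC_LOST", 0.05, 2),
        ("IBD_EXPANDED", 20.0, 4), ("CD_EXPANDED", 20.0, 2), ("UC_EXPANDED", 20.0, 2),
    ]
    i = 0
    for cat, fold, count in specs:
        for _ in range(count):
            planted[names[i]] = PlantedEffect(cat, fold)
            i += 1
    return planted


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Richness means default to the observed Control/CD/UC species-count
    levels (~275/130/170); activity probabilities give half of IBD patients
    active disease; the calprotectin model's treatment coefficient defaults
    to -159.04 ug/g per tier.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"Control": 30, "CD": 30, "UC": 30}
    )
    samples_per_subject: int = 1
    activity_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Control": 0.0, "CD": 0.5, "UC": 0.5}
    )
    richness_means: Mapping[str, float] = field(
        default_factory=lambda: {"Control": 275.0, "CD": 130.0, "UC": 170.0}
    )
    n_species_pool: int = 400
    planted_categories: Mapping[str, PlantedEffect] = field(default_factory=dict)
    # log10-scale (mean, sd) of human DNA percent by stratum
    human_pct_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Control": (-1.0, 0.45),
            "remission": (-0.7, 0.55),
            "active": (0.0, 0.65),
        }
    )
    calprotectin_model: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 1200.0,
            "human_pct": 40.0,
            "active": 250.0,
            "treatment_advancement": -159.04,
            "age": -1.5,
            "subject_sd": 100.0,
            "noise_sd": 120.0,
        }
    )
    # methylation panel / read simulation
    n_cell_types: int = 6
    markers_per_type: int = 2
    amplicon_len: int = 150
    n_cpgs: int = 5
    reads_per_marker: int = 200
    conversion_rate: float = 0.99
    seq_error_rate: float = 0.001
    # metagenomics
    total_reads_mean: float = 8_000_000.0
    n_droplets: int = 20_000
    seed: int = 0
    # species-pool parameters (presence weights, abundance locations) are
    # properties of the simulated ecosystem; sharing this seed across two
    # cohorts draws them from the same species universe
    species_seed: int | None = None

    def __post_init__(self) -> None:
        for g, p in self.activity_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"activity_probs[{g}]={p} outside [0,1]")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g} has {n} subjects; need >= 2")


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------

def generate_marker_panel(
    n_cell_types: int,
    markers_per_type: int,
    amplicon_len: int = 150,
    n_cpgs: int = 5,
    seed: int = 0,
    cell_type_names: Sequence[str] | None = None,
) -> MarkerPanel:
    """Random amplicon references with planted CpG sites, one cell type each.

    CpG dinucleotides occur only at the recorded offsets; accidental CGs in
    the random background are removed so the bisulfite-space readout of each
    molecule is unambiguous.
    """
    if 2 * n_cpgs > amplicon_len:
        raise PanelError(
            f"cannot place {n_cpgs} non-overlapping CpGs in {amplicon_len} bp"
        )
    if cell_type_names is None:
        cell_type_names = [
            DEFAULT_CELL_TYPES[i] if i < len(DEFAULT_CELL_TYPES) else f"cell_type_{i}"
            for i in range(n_cell_types)
        ]
    rng = np.random.default_rng(seed)
    markers = []
    for ci in range(n_cell_types):
        for mi in range(markers_per_type):
            # choose strictly increasing offsets with gap >= 2 (no overlap)
            span = amplicon_len - 1 - 2 * (n_cpgs - 1)
            picks = np.sort(rng.choice(span, size=n_cpgs, replace=False))
            offsets = picks + 2 * np.arange(n_cpgs)
            seq = rng.choice(_BASES, size=amplicon_len)
            seq[offsets] = _C
            seq[offsets + 1] = _G
            # destroy accidental CG dinucleotides outside the offsets
            offset_set = set(int(o) for o in offsets)
            for i in range(amplicon_len - 1):
                if i in offset_set:
                    continue
                if seq[i] == _C and seq[i + 1] == _G:
                    seq[i + 1] = _A if rng.random() < 0.5 else _T
            markers.append(
                Marker(
                    marker_id=f"{cell_type_names[ci]}_m{mi}",
                    cell_type=cell_type_names[ci],
                    sequence=seq.tobytes().decode("ascii"),
                    cpg_offsets=tuple(int(o) for o in offsets),
                )
            )
    return MarkerPanel(markers)


# ---------------------------------------------------------------------------
# bisulfite reads
# ---------------------------------------------------------------------------

def simulate_bisulfite_reads(
    panel: MarkerPanel,
    mix: MixtureSpec,
    reads_per_marker: int,
    conversion_rate: float = 1.0,
    seq_error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str = "S",
) -> list[tuple[str, str]]:
    """Simulate amplicon bisulfite reads as (read_name, sequence) pairs.

    Each molecule's cell of origin is drawn from the mixture.  At the
    marker's CpG sites the readout is deterministic: TG when the molecule
    comes from the marker's own cell type (fully unmethylated), CG
    otherwise.  Bisulfite conversion turns each non-CpG cytosine into T with
    probability ``conversion_rate``; uniform substitution errors are applied
    at ``seq_error_rate``.  Read names carry the ground-truth origin and
    marker for confusion accounting.
    """
    if len(panel) == 0:
        raise PanelError("empty marker panel")
    if not (0.0 <= conversion_rate <= 1.0 and 0.0 <= seq_error_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cell_types = list(mix.cell_fractions)
    probs = np.array([mix.cell_fractions[c] for c in cell_types], dtype=float)
    probs = probs / probs.sum()
    reads: list[tuple[str, str]] = []
    for marker in panel:
        ref = np.frombuffer(marker.sequence.encode("ascii"), dtype=np.uint8)
        L = len(ref)
        n = reads_per_marker
        origins = rng.choice(len(cell_types), size=n, p=probs)
        own = np.array(
            [cell_types[o] == marker.cell_type for o in origins], dtype=bool
        )
        mat = np.tile(ref, (n, 1))
        cpg = np.array(marker.cpg_offsets, dtype=int)
        # CpG C positions: unmethylated (own cell type) molecules read T
        mat[np.ix_(own, cpg)] = _T
        # non-CpG cytosines convert C->T with probability conversion_rate
        noncpg_c = np.flatnonzero(ref == _C)
        noncpg_c = noncpg_c[~np.isin(noncpg_c, cpg)]
        if noncpg_c.size:
            conv = rng.random((n, noncpg_c.size)) < conversion_rate
            block = mat[:, noncpg_c]
            block[conv] = _T
            mat[:, noncpg_c] = block
        # uniform substitution errors
        if seq_error_rate > 0:
            err = rng.random((n, L)) < seq_error_rate
            if err.any():
                idx = np.searchsorted(_BASES, mat[err])
                shifted = (idx + rng.integers(1, 4, size=idx.size)) % 4
                mat[err] = _BASES[shifted]
        for i in range(n):
            name = (
                f"{sample_id}:{marker.marker_id}:{i}"
                f"|origin={cell_types[origins[i]]}|marker={marker.marker_id}"
            )
            reads.append((name, mat[i].tobytes().decode("ascii")))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# ddPCR droplets
# ---------------------------------------------------------------------------

def simulate_ddpcr(true_copies: float, n_droplets: int = 20_000, seed: int = 0) -> DropletCounts:
    """Partition ``true_copies`` template molecules into droplets.

    Under Poisson loading each droplet is positive with probability
    1 - exp(-copies/droplets).
    """
    if true_copies < 0:
        raise ValueError("true_copies must be >= 0")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    rng = np.random.default_rng(seed)
    p_pos = 1.0 - np.exp(-true_copies / n_droplets)
    positive = int(rng.binomial(n_droplets, p_pos))
    return DropletCounts(total=n_droplets, positive=positive, negative=n_droplets - positive)


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """All pipeline inputs for one simulated cohort, plus the ground truth."""

    clinical: pd.DataFrame
    panel: MarkerPanel
    mixtures: dict[str, MixtureSpec]
    reads: dict[str, list[tuple[str, str]]]
    droplets: pd.DataFrame
    read_counts: pd.DataFrame
    species_pct: pd.DataFrame  # species x samples, percent (columns sum to 100)
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.panel.to_tsv(outdir / "panel.tsv")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        self.droplets.to_csv(outdir / "droplets.tsv", sep="\t", index=False)
        self.read_counts.to_csv(outdir / "read_counts.tsv", sep="\t", index=False)
        prof = self.species_pct.copy()
        prof.index = ["k__Bacteria|s__" + s for s in prof.index]
        prof.index.name = "clade_name"
        prof.to_csv(outdir / "species_profile.tsv", sep="\t")
        fq = outdir / "fastq"
        fq.mkdir(exist_ok=True)
        for sid, rds in self.reads.items():
            write_fastq(rds, fq / f"{sid}.fastq")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)


def _presence_scale(u: np.ndarray, target: float) -> np.ndarray:
    """Scale raw presence weights so expected richness hits target (bisection)."""
    lo, hi = 0.0, max(4.0, 2 * target / max(u.sum(), 1e-12))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.clip(u * mid, 0, 1).sum() < target:
            lo = mid
        else:
            hi = mid
    return np.clip(u * 0.5 * (lo + hi), 0.0, 1.0)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic dataset for one cohort."""
    rng = np.random.default_rng(config.seed)
    panel = generate_marker_panel(
        config.n_cell_types,
        config.markers_per_type,
        config.amplicon_len,
        config.n_cpgs,
        seed=int(rng.integers(2**31)),
    )
    cell_types = panel.cell_types

    # --- species pool ---------------------------------------------------
    n_pool = config.n_species_pool
    species = [f"Species_{i:04d}" for i in range(n_pool)]
    sp_seed = config.species_seed if config.species_seed is not None else config.seed
    sp_rng = np.random.default_rng(sp_seed)
    u = sp_rng.uniform(0.05, 1.0, size=n_pool)  # raw presence weight per species
    log_mu = sp_rng.normal(0.0, 1.8, size=n_pool)  # log-abundance location
    presence = {
        g: _presence_scale(u, float(config.richness_means[g])) for g in GROUPS
    }
    abund_shift = {g: np.zeros(n_pool) for g in GROUPS}
    planted_table = {}
    for name, eff in config.planted_categories.items():
        if name not in species:
            raise ValueError(f"planted species {name!r} not in pool")
        j = species.index(name)
        planted_table[name] = eff.category
        for g in eff.affected_groups:
            presence[g][j] = float(np.clip(presence[g][j] * eff.presence_fold, 0.0, 1.0))
            abund_shift[g][j] = np.log(eff.abundance_fold)

    # --- per-sample generation ------------------------------------------
    clinical_rows = []
    mixtures: dict[str, MixtureSpec] = {}
    reads: dict[str, list[tuple[str, str]]] = {}
    droplet_rows = []
    count_rows = []
    abundance_cols = {}
    truth_samples = {}
    cm = config.calprotectin_model

    subj_idx = 0
    for group in GROUPS:
        n_subj = int(config.n_per_group.get(group, 0))
        for _ in range(n_subj):
            subject_id = f"subj_{subj_idx:04d}"
            subj_idx += 1
            age = float(rng.uniform(6.0, 18.0))
            subj_re = float(rng.normal(0.0, cm["subject_sd"]))
            for rep in range(config.samples_per_subject):
                sid = f"{subject_id}_s{rep}"
                # activity + raw score on the group's scale
                if group == "Control":
                    active = False
                    scale, score = "none", np.nan
                else:
                    active = bool(rng.random() < config.activity_probs[group])
                    if group == "UC":
                        scale = "pUCAI"
                        score = float(rng.uniform(10, 85) if active else rng.uniform(0, 9.9))
                    else:
                        scale = "pCDAI"
                        score = float(rng.uniform(10, 60) if active else rng.uniform(0, 9.9))
                activity = "NA" if group == "Control" else ("active" if active else "remission")
                treatment = 0 if group == "Control" else int(rng.integers(0, 5))

                stratum = "Control" if group == "Control" else ("active" if active else "remission")
                mu_h, sd_h = config.human_pct_model[stratum]
                human_pct = float(np.clip(10.0 ** rng.normal(mu_h, sd_h), 1e-3, 80.0))

                linpred = (
                    cm["intercept"]
                    + cm["human_pct"] * human_pct
                    + cm["active"] * (1.0 if active else 0.0)
                    + cm["treatment_advancement"] * treatment
                    + cm["age"] * age
                )
                calpro_raw = max(0.0, linpred + subj_re + float(rng.normal(0, cm["noise_sd"])))
                capped = calpro_raw > 2100.0
                calpro = min(calpro_raw, 2100.0)

                # cell-type mixture: neutrophils expand with inflammation
                alpha = np.full(len(cell_types), 2.0)
                if "neutrophil" in cell_types:
                    k = cell_types.index("neutrophil")
                    alpha[k] = 2.0 + (10.0 if active else 0.0) + (2.0 if group != "Control" else 0.0)
                fracs = rng.dirichlet(alpha)
                mix = MixtureSpec(dict(zip(cell_types, fracs.tolist())), human_pct)
                mixtures[sid] = mix

                reads[sid] = simulate_bisulfite_reads(
                    panel, mix, config.reads_per_marker,
                    config.conversion_rate, config.seq_error_rate,
                    seed=int(rng.integers(2**31)), sample_id=sid,
                )

                true_copies = human_pct / 100.0 * DEFAULT_INPUT_MASS_NG * 1000.0 / GENOME_EQUIVALENT_PG
                d = simulate_ddpcr(true_copies, config.n_droplets, seed=int(rng.integers(2**31)))
                droplet_rows.append((sid, d.total, d.positive, d.negative))

                total_reads = int(rng.poisson(config.total_reads_mean))
                human_reads = int(rng.binomial(total_reads, human_pct / 100.0))
                count_rows.append((sid, total_reads, human_reads, total_reads - human_reads))

                present = rng.random(n_pool) < presence[group]
                if not present.any():
                    present[int(np.argmax(presence[group]))] = True
                raw = np.where(
                    present,
                    np.exp(rng.normal(log_mu + abund_shift[group], 1.0)),
                    0.0,
                )
                abundance_cols[sid] = raw / raw.sum() * 100.0

                clinical_rows.append(
                    dict(
                        sample_id=sid, subject_id=subject_id, cohort="SZ",
                        group=group, activity_score_raw=score, activity_scale=scale,
                        activity=activity, calprotectin=calpro,
                        calprotectin_capped=capped,
                        treatment_advancement=treatment, age=age,
                    )
                )
                truth_samples[sid] = dict(
                    cell_fractions=dict(zip(cell_types, fracs.tolist())),
                    human_pct=human_pct,
                    true_copies=true_copies,
                    calprotectin_raw=calpro_raw,
                    linpred=linpred,
                    subject_effect=subj_re,
                    active=active,
                )

    clinical = pd.DataFrame(clinical_rows)
    droplets = pd.DataFrame(
        droplet_rows, columns=["sample_id", "total_droplets", "positive", "negative"]
    )
    read_counts = pd.DataFrame(
        count_rows, columns=["sample_id", "total_reads", "human_reads", "nonhuman_reads"]
    )
    species_pct = pd.DataFrame(abundance_cols, index=species)
    species_pct.index.name = "species"

    truth = dict(
        seed=config.seed,
        calprotectin_model=dict(cm),
        planted_categories=planted_table,
        presence_probs={g: presence[g].tolist() for g in GROUPS},
        samples=truth_samples,
    )
    return SyntheticCohort(
        clinical=clinical, panel=panel, mixtures=mixtures, reads=reads,
        droplets=droplets, read_counts=read_counts, species_pct=species_pct,
        truth=truth,
    )
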