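"""Microbiome richness, diversity, ordination and species classification.

Richness is the species count (entries > 0); alpha diversity is the
Shannon index in nats.  Ordination uses the robust Aitchison convention:
each sample's nonzero abundances are log-ratio transformed against the
geometric mean of its own nonzero parts (rclr), zeros stay 0, and samples
are projected by principal components of the column-centered transformed
matrix, so Euclidean distance between coordinates is the robust Aitchison
distance.

Species are classified into six lost/expanded categories against the
Control group with one-sided Mann-Whitney tests (loss: alternative "less",
expansion: "greater"), Benjamini-Hochberg correction within each direction
family, and the lowest adjusted p wins when both directions reach
significance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrdinationResult",
    "species_count",
    "shannon",
    "rclr",
    "rclr_pcoa",
    "classify_species",
    "spearman",
    "group_median_curve",
]

CATEGORY_ORDER = (
    "IBD_LOST", "CD_LOST", "UC_LOST",
    "IBD_EXPANDED", "CD_EXPANDED", "UC_EXPANDED",
    "UNCHANGED",
)
EXACT_MW_MAX_N = 12


def species_count(abundances) -> int:
    """Number of species with abundance strictly greater than zero."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundance")
    return int((a > 0).sum())


def shannon(abundances) -> float:
    """Shannon diversity H = -sum p ln p (nats) over nonzero proportions."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundance")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero profile has undefined diversity")
    p = a[a > 0] / total
    p = p[p > 0]  # guard against underflow of extreme dynamic ranges
    return float(-(p * np.log(p)).sum())


def rclr(matrix: pd.DataFrame) -> pd.DataFrame:
    """Robust centered log-ratio transform, per sample (column).

    Nonzero entries become ln(x / gmean of the sample's nonzero entries);
    zeros map to 0.  Rows are species, columns samples.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative abundance")
    out = np.zeros_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        nz = col > 0
        if not nz.any():
            raise ValueError(f"sample {matrix.columns[j]!r} has no nonzero entries")
        logx = np.log(col[nz])
        out[nz, j] = logx - logx.mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance: np.ndarray  # fraction per component, non-increasing
    distance_kind: str = "robust_aitchison"


def rclr_pcoa(matrix: pd.DataFrame, n_components: int | None = None) -> OrdinationResult:
    """Principal coordinates of the rclr-transformed species table.

    With Euclidean distance on the transformed matrix, PCoA coincides with
    principal component analysis of the sample x species rclr matrix.
    """
    if matrix.shape[1] < 3 or matrix.shape[0] < 2:
        raise ValueError("need >= 3 samples and >= 2 species")
    X = rclr(matrix).to_numpy().T  # samples x species
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(S.size):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U * S
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var
    k = n_components or min(S.size, matrix.shape[1] - 1)
    coords = pd.DataFrame(
        coords[:, :k],
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return OrdinationResult(coords, explained[:k])


# ---------------------------------------------------------------------------
# six-category species classification
# ---------------------------------------------------------------------------

def _mw_pvalues(
    case: np.ndarray, control: np.ndarray, alternative: str
) -> np.ndarray:
    """Row-wise one-sided Mann-Whitney p-values, exact for small groups."""
    method = "exact" if max(case.shape[1], control.shape[1]) <= EXACT_MW_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(
        case, control, alternative=alternative, method=method, axis=1
    )
    return np.atleast_1d(res.pvalue)


def classify_species(
    matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    family_mode: str = "pooled",
) -> pd.DataFrame:
    """Classify each species as lost/expanded in CD, UC or both vs Control.

    The species universe is restricted to species with median relative
    abundance > 0 in at least one group.  For each species four one-sided
    tests run against Control (CD less, UC less, CD greater, UC greater);
    BH correction is applied within the loss family and within the
    expansion family, pooled across species and both IBD groups
    (``family_mode="per_comparison"`` corrects each of the four columns
    separately).  Significance in both CD and UC gives the IBD_ category;
    in exactly one, that group's category; when loss and expansion
    categories both apply the family with the lower minimal adjusted p
    wins.

    Returns a DataFrame indexed by species with the category and the four
    adjusted p-values.
    """
    groups = pd.Series(groups)
    for g in ("Control", "CD", "UC"):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} missing or has < 2 samples")
    cols = {g: matrix.columns[groups.reindex(matrix.columns).eq(g)] for g in ("Control", "CD", "UC")}

    medians = pd.DataFrame(
        {g: matrix[cols[g]].median(axis=1) for g in ("Control", "CD", "UC")}
    )
    universe = matrix.index[(medians > 0).any(axis=1)]
    sub = matrix.loc[universe]
    ctrl = sub[cols["Control"]].to_numpy(dtype=float)
    arr = {g: sub[cols[g]].to_numpy(dtype=float) for g in ("CD", "UC")}

    raw = {}
    for g in ("CD", "UC"):
        raw[("loss", g)] = _mw_pvalues(arr[g], ctrl, "less")
        raw[("expansion", g)] = _mw_pvalues(arr[g], ctrl, "greater")

    adj = {}
    if family_mode == "pooled":
        for fam in ("loss", "expansion"):
            pooled = np.concatenate([raw[(fam, "CD")], raw[(fam, "UC")]])
            _, padj, _, _ = multipletests(pooled, method="fdr_bh")
            n = len(universe)
            adj[(fam, "CD")], adj[(fam, "UC")] = padj[:n], padj[n:]
    elif family_mode == "per_comparison":
        for key, p in raw.items():
            _, padj, _, _ = multipletests(p, method="fdr_bh")
            adj[key] = padj
    else:
        raise ValueError(f"unknown family_mode {family_mode!r}")

    records = []
    for i, sp in enumerate(universe):
        best: tuple[float, str] | None = None
        for fam, suffix in (("loss", "LOST"), ("expansion", "EXPANDED")):
            sig_cd = adj[(fam, "CD")][i] < alpha
            sig_uc = adj[(fam, "UC")][i] < alpha
            if not (sig_cd or sig_uc):
                continue
            if sig_cd and sig_uc:
                cat = f"IBD_{suffix}"
                pmin = min(adj[(fam, "CD")][i], adj[(fam, "UC")][i])
            elif sig_cd:
                cat, pmin = f"CD_{suffix}", adj[(fam, "CD")][i]
            else:
                cat, pmin = f"UC_{suffix}", adj[(fam, "UC")][i]
            if best is None or pmin < best[0]:
                best = (pmin, cat)
        records.append(
            dict(
                species=sp,
                category=best[1] if best else "UNCHANGED",
                p_adj_loss_CD=adj[("loss", "CD")][i],
                p_adj_loss_UC=adj[("loss", "UC")][i],
                p_adj_expansion_CD=adj[("expansion", "CD")][i],
                p_adj_expansion_UC=adj[("expansion", "UC")][i],
            )
        )
    return pd.DataFrame(records).set_index("species")


# ---------------------------------------------------------------------------
# correlation and summary curves
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation for n > 10 and the exact
    permutation distribution for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 10:
        # exact permutation distribution of the rank correlation (two-sided)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        chunk: list[tuple[int, ...]] = []
        perm_iter = itertools.permutations(range(n))
        while True:
            chunk = list(itertools.islice(perm_iter, 200_000))
            if not chunk:
                break
            idx = np.array(chunk, dtype=np.int8)
            stat = np.abs(ry_c[idx] @ rx_c)
            count += int((stat >= obs - 1e-12).sum())
            total += idx.shape[0]
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, float(min(p, 1.0))


def group_median_curve(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-species per-group median relative abundance, arcsine-transformed.

    Abundances in percent are divided by 100 and transformed as
    arcsin(sqrt(p)); species are ordered by the Control median descending.
    """
    groups = pd.Series(groups)
    out = {}
    for g in sorted(groups.unique()):
        med = matrix[matrix.columns[groups.reindex(matrix.columns).eq(g)]].median(axis=1) / 100.0
        if ((med < 0) | (med > 1)).any():
            raise ValueError("proportions outside [0, 1]")
        out[g] = np.arcsin(np.sqrt(med))
    df = pd.DataFrame(out)
    if "Control" in df.columns:
        df = df.sort_values("Control", ascending=False)
    return df
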