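"""Genome scans and multi-locus QTL models for RI panels.

Marker regression throughout: at each marker the trait is regressed on
the {0,1} founder-allele code by ordinary least squares over the
pairwise-complete strains, and

    LOD = (n/2) * log10(RSS0 / RSS1) = -(n/2) * log10(1 - R^2),

the log10 likelihood ratio of the single-marker model against the null
(intercept-only) model.  No pseudomarkers are imputed between markers;
the panel's marker maps are dense enough that peak markers, not interval
positions, are reported.

Genome-wide thresholds come from permutation of the phenotype across
strains: the 95th percentile of the permutation maxima is the
significant threshold and, by convention, the 63rd percentile the
suggestive threshold (both configurable).  Approximate 95% confidence
regions for a QTL location are 1.5-LOD support intervals: the region
around the peak bounded by the first markers whose LOD falls 1.5 units
below the peak.
"""
from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeVector, align
from .errors import ScanError

__all__ = [
    "LodCurve",
    "ScanThresholds",
    "SupportInterval",
    "QtlModel",
    "PairScanResult",
    "single_scan",
    "permutation_thresholds",
    "support_interval",
    "fit_multi_qtl",
    "pair_scan",
]

LOD_CAP = 300.0  # reported when the model fit is numerically perfect


@dataclass
class LodCurve:
    """Per-marker LOD profile of a single-locus genome scan.

    ``table`` has one row per scanned marker with columns
    ``marker, chrom, pos_bp, lod, sign, n``; ``sign`` is +1 when the
    1-coded (D-type) allele increases the trait, -1 when the 0-coded
    allele does, 0 when undefined (monomorphic marker or zero slope).
    ``skipped`` records markers excluded from the scan with a reason.
    """

    table: pd.DataFrame
    skipped: tuple[tuple[str, str], ...] = ()

    def lod_of(self, marker_id: str) -> float:
        rows = self.table[self.table["marker"] == marker_id]
        if rows.empty:
            raise KeyError(f"marker {marker_id!r} not on the curve")
        return float(rows["lod"].iloc[0])

    def peak_marker(self, chromosome: str | None = None) -> str:
        """Marker with the highest LOD (lowest coordinate breaks ties)."""
        t = self.table
        if chromosome is not None:
            t = t[t["chrom"] == chromosome]
        if t.empty:
            raise ScanError("no scanned markers in the requested region")
        best = t[t["lod"] == t["lod"].max()]
        best = best.sort_values(["chrom", "pos_bp"]).iloc[0]
        return str(best["marker"])

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


@dataclass(frozen=True)
class ScanThresholds:
    """Genome-wide LOD thresholds from permutation maxima."""

    significant: float
    suggestive: float
    n_perm: int
    seed: int
    significant_percentile: float = 95.0
    suggestive_percentile: float = 63.0

    def __post_init__(self):
        if not (self.significant >= self.suggestive >= 0):
            raise ScanError("thresholds must satisfy significant >= suggestive >= 0")


@dataclass(frozen=True)
class SupportInterval:
    """LOD-drop support interval around a peak marker on one chromosome."""

    chrom: str
    peak_marker: str
    peak_lod: float
    left_bp: int
    right_bp: int
    drop: float = 1.5

    def __post_init__(self):
        if self.drop <= 0:
            raise ScanError("drop must be positive")
        if self.left_bp > self.right_bp:
            raise ScanError("interval bounds out of order")


@dataclass(frozen=True)
class QtlModel:
    """Fitted multi-locus OLS model with percent-variance decomposition."""

    loci: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    term_percents: tuple[tuple[str, float], ...]
    total_percent: float
    residual_df: int
    n: int
    excluded: tuple[tuple[str, str], ...] = ()  # (term, reason)

    def percent_of(self, term: str) -> float:
        for name, pct in self.term_percents:
            if name == term:
                return pct
        raise KeyError(f"term {term!r} not in model")


@dataclass(frozen=True)
class PairScanResult:
    """Best interacting marker pair from an exhaustive two-locus scan."""

    marker_a: str
    marker_b: str
    interaction_lod: float
    full_model_lod: float
    p_value: float | None
    n_perm: int
    n: int
    perm_interaction_max: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# single-marker scan


def _scan_moments(G: np.ndarray, Y: np.ndarray):
    """Masked cross-moments of every marker column against every phenotype
    column.  ``G`` is strains x markers with NaN for missing calls; ``Y``
    strains x p (no missing).  Returns per-marker counts and the r^2
    matrix (markers x p) over pairwise-complete strains."""
    M = ~np.isnan(G)
    Gz = np.where(M, G, 0.0)
    n = M.sum(axis=0).astype(float)
    sg = Gz.sum(axis=0)
    sgg = (Gz * Gz).sum(axis=0)
    Mf = M.astype(float)
    sy = Mf.T @ Y
    syy = Mf.T @ (Y * Y)
    sgy = Gz.T @ Y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n[:, None] * sgy - sg[:, None] * sy
        var_g = n * sgg - sg * sg
        var_y = n[:, None] * syy - sy * sy
        denom = var_g[:, None] * var_y
        r2 = np.where(denom > 0, cov * cov / np.where(denom > 0, denom, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    return n, var_g, cov, r2


def _lod_from_r2(n: np.ndarray, r2: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lod = -(n[:, None] / 2.0) * np.log10(1.0 - r2)
    return np.minimum(np.where(np.isfinite(lod), lod, LOD_CAP), LOD_CAP)


def single_scan(genotypes: GenotypeMatrix, phenotype: PhenotypeVector) -> LodCurve:
    """Single-locus genome scan by marker regression.

    Markers with fewer than 3 pairwise-complete observations are skipped
    and flagged; monomorphic markers get LOD 0 with sign 0.
    """
    strains, G, y = align(genotypes, phenotype)
    if len(strains) < 3:
        raise ScanError("need at least 3 strains shared between genotypes and phenotype")
    n, var_g, cov, r2 = _scan_moments(G, y[:, None])
    lod = _lod_from_r2(n, r2)[:, 0]
    sign = np.sign(cov[:, 0]).astype(int)
    sign[var_g <= 0] = 0
    lod[var_g <= 0] = 0.0

    mm = genotypes.markers
    usable = n >= 3
    skipped = tuple(
        (str(mm.marker[j]), f"only {int(n[j])} complete observations")
        for j in np.flatnonzero(~usable)
    )
    table = pd.DataFrame(
        {
            "marker": mm.marker[usable],
            "chrom": mm.chrom[usable],
            "pos_bp": mm.pos_bp[usable],
            "lod": lod[usable],
            "sign": sign[usable],
            "n": n[usable].astype(int),
        }
    ).reset_index(drop=True)
    return LodCurve(table=table, skipped=skipped)


def permutation_thresholds(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    n_perm: int = 1000,
    seed: int = 0,
    significant_percentile: float = 95.0,
    suggestive_percentile: float = 63.0,
) -> ScanThresholds:
    """Genome-wide significance thresholds from phenotype permutation.

    Each permutation shuffles trait values across strains, rescans the
    genome, and records the maximum LOD; thresholds are percentiles of
    the ``n_perm`` maxima.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is low for stable genome-wide thresholds",
            stacklevel=2,
        )
    strains, G, y = align(genotypes, phenotype)
    if len(strains) < 3:
        raise ScanError("need at least 3 strains shared between genotypes and phenotype")
    rng = np.random.default_rng(seed)
    Y = np.empty((len(y), n_perm))
    for j in range(n_perm):
        Y[:, j] = rng.permutation(y)
    n, var_g, _, r2 = _scan_moments(G, Y)
    lod = _lod_from_r2(n, r2)
    lod[(n < 3) | (var_g <= 0), :] = 0.0
    maxima = lod.max(axis=0)
    significant = float(np.quantile(maxima, significant_percentile / 100.0))
    suggestive = float(np.quantile(maxima, suggestive_percentile / 100.0))
    return ScanThresholds(
        significant=significant,
        suggestive=suggestive,
        n_perm=n_perm,
        seed=seed,
        significant_percentile=significant_percentile,
        suggestive_percentile=suggestive_percentile,
    )


def support_interval(curve: LodCurve, peak_marker: str, drop: float = 1.5) -> SupportInterval:
    """LOD-drop support interval around ``peak_marker``.

    Walks outward from the peak along its chromosome; each bound is the
    position of the first marker whose LOD falls to ``peak - drop`` or
    below, clamped to the terminal scanned marker when no marker drops
    that far.  Bounds are inclusive.
    """
    t = curve.table
    rows = t[t["marker"] == peak_marker]
    if rows.empty:
        raise ScanError(f"peak marker {peak_marker!r} not on the curve")
    peak = rows.iloc[0]
    chrom = peak["chrom"]
    sub = t[t["chrom"] == chrom].sort_values("pos_bp").reset_index(drop=True)
    k = int(sub.index[sub["marker"] == peak_marker][0])
    threshold = float(peak["lod"]) - drop

    left = int(sub["pos_bp"].iloc[0])
    for i in range(k - 1, -1, -1):
        if sub["lod"].iloc[i] <= threshold:
            left = int(sub["pos_bp"].iloc[i])
            break
    right = int(sub["pos_bp"].iloc[len(sub) - 1])
    for i in range(k + 1, len(sub)):
        if sub["lod"].iloc[i] <= threshold:
            right = int(sub["pos_bp"].iloc[i])
            break
    return SupportInterval(
        chrom=str(chrom),
        peak_marker=str(peak_marker),
        peak_lod=float(peak["lod"]),
        left_bp=left,
        right_bp=right,
        drop=drop,
    )


# ---------------------------------------------------------------------------
# multi-locus models


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_multi_qtl(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    loci: Sequence[str],
    interactions: Sequence[tuple[str, str]] = (),
    decomposition: str = "drop_one",
) -> QtlModel:
    """Multi-locus additive(+interaction) OLS model of the trait.

    Strains missing data at any model marker are dropped listwise.
    ``total_percent`` is ``100 * (1 - RSS_model / RSS_null)``.  Per-term
    percents use the drop-one decomposition (``R^2_full`` minus ``R^2``
    of the model without that term); ``decomposition="sequential"``
    switches to Type-I style increments in term order.
    """
    if not loci:
        raise ScanError("loci must be non-empty")
    if decomposition not in ("drop_one", "sequential"):
        raise ScanError(f"unknown decomposition {decomposition!r}")
    strains, G, y = align(genotypes, phenotype)
    mm = genotypes.markers
    model_markers = list(dict.fromkeys(list(loci) + [m for pair in interactions for m in pair]))
    cols = {m: G[:, mm.index_of(m)] for m in model_markers}
    complete = np.ones(len(strains), dtype=bool)
    for m in model_markers:
        complete &= ~np.isnan(cols[m])
    if complete.sum() < 3:
        raise ScanError("fewer than 3 complete observations for the model markers")
    y = y[complete]
    n = len(y)

    terms: list[tuple[str, np.ndarray]] = []
    for m in loci:
        terms.append((m, cols[m][complete]))
    for a, b in interactions:
        terms.append((f"{a}:{b}", cols[a][complete] * cols[b][complete]))

    # greedy rank screen: drop monomorphic or collinear columns
    included: list[tuple[str, np.ndarray]] = []
    excluded: list[tuple[str, str]] = []
    X = np.ones((n, 1))
    for name, col in terms:
        if np.var(col) == 0:
            excluded.append((name, "monomorphic"))
            continue
        trial = np.column_stack([X, col])
        if np.linalg.matrix_rank(trial) <= X.shape[1]:
            excluded.append((name, "collinear with earlier terms"))
            continue
        X = trial
        included.append((name, col))
    if not included:
        raise ScanError("all model terms are monomorphic or collinear")

    rss0 = float(((y - y.mean()) ** 2).sum())
    rss_full = _ols_rss(X, y)
    total_percent = 100.0 * (1.0 - rss_full / rss0) if rss0 > 0 else 0.0

    percents: list[tuple[str, float]] = []
    if decomposition == "drop_one":
        for i, (name, _) in enumerate(included):
            Xi = np.delete(X, i + 1, axis=1)
            rss_i = _ols_rss(Xi, y)
            percents.append((name, 100.0 * (rss_i - rss_full) / rss0 if rss0 > 0 else 0.0))
    else:
        prev = rss0
        Xi = np.ones((n, 1))
        for name, col in included:
            Xi = np.column_stack([Xi, col])
            rss_i = _ols_rss(Xi, y)
            percents.append((name, 100.0 * (prev - rss_i) / rss0 if rss0 > 0 else 0.0))
            prev = rss_i

    return QtlModel(
        loci=tuple(loci),
        interactions=tuple(tuple(p) for p in interactions),
        term_percents=tuple(percents),
        total_percent=total_percent,
        residual_df=n - X.shape[1],
        n=n,
        excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# two-locus pair scan


def _pair_eligibility(mm, min_separation) -> np.ndarray:
    m = len(mm)
    chrom = mm.chrom
    pos = mm.pos_bp
    same_chrom = chrom[:, None] == chrom[None, :]
    if min_separation == "chromosome":
        ok = ~same_chrom
    else:
        sep = np.abs(pos[:, None] - pos[None, :])
        ok = (~same_chrom) | (sep >= int(min_separation))
    upper = np.triu(np.ones((m, m), dtype=bool), k=1)
    return ok & upper


def pair_scan(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    min_separation: int | str = "chromosome",
    n_perm: int = 0,
    seed: int = 0,
) -> PairScanResult:
    """Exhaustive two-locus scan for the strongest interaction.

    For every eligible marker pair the interaction LOD is the LOD of the
    full model (two loci plus product term) minus the LOD of the additive
    two-locus model.  ``min_separation`` is a base-pair distance, or the
    string ``"chromosome"`` to require the loci on different chromosomes.
    With ``n_perm > 0`` a permutation p-value for the genome-wide maximum
    interaction LOD is computed.  Strains with any missing genotype or
    phenotype are dropped listwise before scanning.
    """
    strains, G, y = align(genotypes, phenotype)
    complete = ~np.isnan(G).any(axis=1)
    G = G[complete]
    y = y[complete]
    n = len(y)
    if n < 5:
        raise ScanError("too few complete strains for a pair scan")
    mm = genotypes.markers
    elig = _pair_eligibility(mm, min_separation)
    jj, kk = np.nonzero(elig)
    if len(jj) == 0:
        raise ScanError("no eligible marker pairs")

    interaction, full_lod = _pair_interaction_lods(G, y, jj, kk)
    best = int(np.argmax(interaction))
    obs_max = float(interaction.max())

    p_value = None
    perm_max: tuple[float, ...] = ()
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_perm)
        for t in range(n_perm):
            yp = rng.permutation(y)
            it, _ = _pair_interaction_lods(G, yp, jj, kk)
            maxima[t] = it.max()
        p_value = float((1 + (maxima >= obs_max).sum()) / (n_perm + 1))
        perm_max = tuple(maxima)

    return PairScanResult(
        marker_a=str(mm.marker[jj[best]]),
        marker_b=str(mm.marker[kk[best]]),
        interaction_lod=float(interaction[best]),
        full_model_lod=float(full_lod[best]),
        p_value=p_value,
        n_perm=n_perm,
        n=n,
        perm_interaction_max=perm_max,
    )


def _pair_interaction_lods(G: np.ndarray, y: np.ndarray, jj: np.ndarray, kk: np.ndarray):
    """Vectorized interaction and full-model LODs for the listed pairs.

    Exploits the binary {0,1} coding: with p = g_j * g_k elementwise,
    p^2 = p and p * g_j = p, so every cross-moment of the product term is
    available from two marker-by-marker matmuls.
    """
    n = len(y)
    yc = y - y.mean()
    syy = float(yc @ yc)
    Gc = G - G.mean(axis=0)
    S = Gc.T @ Gc                      # centered marker cross-products
    Sy = Gc.T @ yc
    N11 = G.T @ G                      # raw co-occurrence counts (= sum of p)
    Ty = (G * y[:, None]).T @ G        # sum of g_j g_k y (raw y)
    colsum = G.sum(axis=0)
    ysum = float(y.sum())

    sp = N11[jj, kk]
    Spp = sp - sp * sp / n
    Spy = (Ty[jj, kk] + Ty[kk, jj]) / 2.0 - sp * ysum / n
    Spj = sp - sp * colsum[jj] / n
    Spk = sp - sp * colsum[kk] / n

    Sjj = S[jj, jj]
    Skk = S[kk, kk]
    Sjk = S[jj, kk]
    Sjy = Sy[jj]
    Sky = Sy[kk]

    # additive model RSS via the 2x2 normal equations
    det = Sjj * Skk - Sjk * Sjk
    with np.errstate(invalid="ignore", divide="ignore"):
        quad = np.where(
            det > 1e-12,
            (Skk * Sjy * Sjy - 2 * Sjk * Sjy * Sky + Sjj * Sky * Sky) / det,
            np.where(Sjj > 0, Sjy * Sjy / np.where(Sjj > 0, Sjj, 1.0), 0.0),
        )
    rss_add = np.maximum(syy - quad, 0.0)

    # full model adds the product term: stacked 3x3 normal equations
    m = len(jj)
    A = np.empty((m, 3, 3))
    A[:, 0, 0] = Sjj
    A[:, 0, 1] = A[:, 1, 0] = Sjk
    A[:, 0, 2] = A[:, 2, 0] = Spj
    A[:, 1, 1] = Skk
    A[:, 1, 2] = A[:, 2, 1] = Spk
    A[:, 2, 2] = Spp
    b = np.stack([Sjy, Sky, Spy], axis=1)
    Ainv = np.linalg.pinv(A, rcond=1e-10)
    quad_full = np.einsum("mi,mij,mj->m", b, Ainv, b)
    rss_full = np.maximum(syy - quad_full, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        interaction = (n / 2.0) * np.log10(
            np.where(rss_full > 0, rss_add / np.where(rss_full > 0, rss_full, 1.0), np.inf)
        )
        full_lod = (n / 2.0) * np.log10(
            np.where(rss_full > 0, syy / np.where(rss_full > 0, rss_full, 1.0), np.inf)
        )
    interaction = np.clip(np.where(np.isfinite(interaction), interaction, LOD_CAP), 0.0, LOD_CAP)
    full_lod = np.clip(np.where(np.isfinite(full_lod), full_lod, LOD_CAP), 0.0, LOD_CAP)
    return interaction, full_lod
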