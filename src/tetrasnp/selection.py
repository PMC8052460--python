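"""Selection-signature scans: PCA-outlier, iHS, XP-EHH, and sweep consensus.

Three complementary statistics are provided. The PCA-outlier scan tests each
marker's association with population structure through the Mahalanobis
distance of its loadings on K principal components, rescaled by the genomic
inflation factor. The haplotype statistics are built on extended haplotype
homozygosity (EHH): iHS contrasts the EHH decay around the ancestral versus
derived allele within one population, XP-EHH contrasts whole-population EHH
decay between two populations. Storey-Tibshirani q-values control the FDR,
and markers flagged by at least two statistics seed candidate sweep regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DosageMatrix, MarkerMap

__all__ = [
    "HaplotypePanel",
    "ScanResult",
    "SweepRegion",
    "pca_outlier_scan",
    "ehh",
    "ihs_scan",
    "xpehh_scan",
    "storey_qvalues",
    "consensus_sweeps",
    "genes_near",
]


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes with a physical map.

    alleles[h, m] is 0 (ancestral) or 1 (derived); markers are sorted by
    (chromosome, position) and no missing alleles are allowed.
    """

    hap_ids: list[str]
    alleles: np.ndarray
    marker_map: MarkerMap
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.alleles)
        if not np.isin(A, [0, 1]).all():
            raise ValueError("haplotype alleles must be 0/1 with no missing values")
        t = self.marker_map.table
        if A.shape != (len(self.hap_ids), len(t)):
            raise ValueError("alleles shape inconsistent with haplotypes x markers")
        self.alleles = A.astype(np.int8)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_map.table["marker_id"])

    def subset_population(self, pop: str) -> "HaplotypePanel":
        if self.populations is None:
            raise ValueError("panel carries no population labels")
        idx = [i for i, p in enumerate(self.populations) if p == pop]
        return HaplotypePanel(
            [self.hap_ids[i] for i in idx],
            self.alleles[idx],
            self.marker_map,
            [pop] * len(idx),
        )


@dataclass
class ScanResult:
    method: str  # pca_outlier | ihs | xpehh
    table: pd.DataFrame  # marker_id, chrom, pos, raw, z, p, q
    lambda_gc: float | None = None
    pi0: float | None = None


@dataclass
class SweepRegion:
    chrom: int
    start: int
    end: int
    top_snp: str
    methods: list[str] = field(default_factory=list)
    stats: dict[str, float] = field(default_factory=dict)
    pvals: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------- PCA outlier


def _prep_genotypes(D: DosageMatrix) -> np.ndarray:
    X = D.dosage.copy()
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X / sd


def ld_prune(D: DosageMatrix, r2_max: float = 0.5, window: int = 50) -> np.ndarray:
    """Greedy LD clumping: indices of markers kept at pairwise r^2 <= r2_max
    within a sliding window of ``window`` markers."""
    X = _prep_genotypes(D)
    n, m = X.shape
    keep: list[int] = []
    for j in range(m):
        ok = True
        for k in reversed(keep):
            if j - k > window:
                break
            r = float(X[:, j] @ X[:, k]) / n
            if r * r > r2_max:
                ok = False
                break
        if ok:
            keep.append(j)
    return np.array(keep)


def pca_outlier_scan(
    D: DosageMatrix,
    K: int = 3,
    mmap: MarkerMap | None = None,
    ld_prune_r2: float | None = None,
) -> ScanResult:
    """Structure-outlier scan with genomic-control calibration.

    Each marker is regressed on K principal components of the standardized
    genotype matrix; the vector of regression z-scores gets a Mahalanobis
    distance D^2, the inflation factor lambda_GC = median(D^2)/median(chi2_K)
    rescales it, and p-values come from a chi-square with K df. Optional LD
    clumping restricts the PC estimation to a thinned marker set.
    """
    if K >= min(D.n_clones, D.n_markers):
        raise ValueError("K must be smaller than both matrix dimensions")
    X = _prep_genotypes(D)
    n, m = X.shape
    if ld_prune_r2 is not None:
        keep = ld_prune(D, r2_max=ld_prune_r2)
        Xp = X[:, keep]
    else:
        Xp = X
    U, s, _ = np.linalg.svd(Xp, full_matrices=False)
    scores = U[:, :K]  # orthonormal columns
    # OLS of each marker on the K orthonormal PC axes
    beta = scores.T @ X  # K x m
    resid_ss = np.maximum((X**2).sum(axis=0) - (beta**2).sum(axis=0), 1e-12)
    sigma2 = resid_ss / max(n - K - 1, 1)
    z = (beta / np.sqrt(sigma2)).T  # m x K (orthonormal design: se_k = sigma)
    zc = z - z.mean(axis=0)
    cov = np.cov(zc, rowvar=False)
    cov = np.atleast_2d(cov)
    d2 = np.einsum("ij,jk,ik->i", zc, np.linalg.pinv(cov), zc)
    lam = float(np.median(d2) / stats.chi2.median(K))
    p = stats.chi2.sf(d2 / lam, df=K)
    q, pi0 = storey_qvalues(p)
    table = _scan_table(D.marker_ids, mmap, raw=d2, z=np.sqrt(np.maximum(d2, 0)), p=p, q=q)
    return ScanResult("pca_outlier", table, lambda_gc=lam, pi0=pi0)


# ------------------------------------------------------------------------ EHH


def ehh(
    panel: HaplotypePanel,
    focal: int | str,
    allele: int | None = None,
    truncate: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Extended haplotype homozygosity around a focal marker.

    EHH(x) is the probability that two random carrier haplotypes are
    identical over every marker between the focal position and x; with
    ``allele`` None all haplotypes are carriers (the whole-population EHH used
    by XP-EHH). The curve is extended outward in both directions until it
    falls below ``truncate`` or the chromosome ends. Returns the curve
    (marker_id, pos, side, ehh) and iES, the trapezoid integral of EHH over
    physical distance.
    """
    t = panel.marker_map.table
    j = panel.marker_ids.index(focal) if isinstance(focal, str) else int(focal)
    chrom = t["chrom"].iloc[j]
    A = panel.alleles
    if allele is None:
        carriers = np.arange(panel.n_haplotypes)
    else:
        carriers = np.flatnonzero(A[:, j] == allele)
    if len(carriers) < 2:
        raise ValueError("fewer than 2 carrier haplotypes at the focal marker")
    nc = len(carriers)
    denom = nc * (nc - 1) / 2

    chrom_idx = np.flatnonzero(t["chrom"].to_numpy() == chrom)
    lo, hi = chrom_idx[0], chrom_idx[-1]
    pos = t["pos"].to_numpy()

    def homozygosity(codes: np.ndarray) -> float:
        counts = np.bincount(codes)
        return float((counts * (counts - 1) / 2).sum() / denom)

    # identity is over the closed interval [focal, x]: with all haplotypes as
    # carriers the focal site itself already separates the two alleles
    _, focal_codes = np.unique(A[carriers, j], return_inverse=True)
    focal_val = homozygosity(focal_codes)

    def walk(step: int):
        codes = focal_codes
        out = []
        k = j
        while True:
            k += step
            if k < lo or k > hi:
                break
            pairs = codes * 2 + A[carriers, k]
            _, codes = np.unique(pairs, return_inverse=True)
            val = homozygosity(codes)
            out.append((k, val))
            if val < truncate:
                break
        return out

    rows = [(j, pos[j], "focal", focal_val)]
    for step, side in ((-1, "left"), (1, "right")):
        for k, val in walk(step):
            rows.append((k, pos[k], side, val))
    curve = pd.DataFrame(rows, columns=["idx", "pos", "side", "ehh"]).sort_values("pos")
    curve["marker_id"] = [panel.marker_ids[i] for i in curve["idx"]]
    ies = float(np.trapezoid(curve["ehh"].to_numpy(), curve["pos"].to_numpy()))
    return curve[["marker_id", "pos", "side", "ehh"]].reset_index(drop=True), ies


def _ies_both(panel: HaplotypePanel, j: int, truncate: float) -> tuple[float, float] | None:
    """(iES_ancestral, iES_derived) at marker j, or None if either side < 2 carriers."""
    A = panel.alleles[:, j]
    if np.sum(A == 0) < 2 or np.sum(A == 1) < 2:
        return None
    _, ies_a = ehh(panel, j, allele=0, truncate=truncate)
    _, ies_d = ehh(panel, j, allele=1, truncate=truncate)
    return ies_a, ies_d


def ihs_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    bins: int = 20,
    min_bin: int = 10,
    truncate: float = 0.05,
) -> ScanResult:
    """Integrated haplotype score scan within one population.

    For each marker, unstandardized iHS = ln(iES_ancestral / iES_derived);
    scores are standardized to zero mean and unit variance within
    derived-allele-frequency bins (equal width, bins with fewer than
    ``min_bin`` markers merged with their neighbor), two-sided normal
    p-values, Storey q-values.
    """
    m = panel.n_markers
    freq = panel.alleles.mean(axis=0)
    raw = np.full(m, np.nan)
    for j in range(m):
        f = freq[j]
        if min(f, 1 - f) < maf_min:
            continue
        pair = _ies_both(panel, j, truncate)
        if pair is None or pair[0] <= 0 or pair[1] <= 0:
            continue
        raw[j] = np.log(pair[0] / pair[1])
    z = _bin_standardize(raw, freq, bins, min_bin)
    p = 2 * stats.norm.sf(np.abs(z))
    q, pi0 = _qvalues_with_nan(p)
    table = _scan_table(panel.marker_ids, panel.marker_map, raw=raw, z=z, p=p, q=q)
    return ScanResult("ihs", table, pi0=pi0)


def _bin_standardize(raw: np.ndarray, freq: np.ndarray, bins: int, min_bin: int) -> np.ndarray:
    z = np.full_like(raw, np.nan)
    scored = ~np.isnan(raw)
    if not scored.any():
        return z
    edges = np.linspace(0, 1, bins + 1)
    which = np.clip(np.digitize(freq, edges) - 1, 0, bins - 1)
    # merge sparse bins with their left neighbor (leftmost merges right)
    occupied = sorted(set(which[scored]))
    merged: dict[int, int] = {}
    groups: list[list[int]] = []
    for b in occupied:
        if groups and sum(np.sum(scored & (which == bb)) for bb in groups[-1]) < min_bin:
            groups[-1].append(b)
        else:
            groups.append([b])
    if len(groups) >= 2 and sum(np.sum(scored & (which == bb)) for bb in groups[-1]) < min_bin:
        groups[-2].extend(groups.pop())
    for gi, grp in enumerate(groups):
        for b in grp:
            merged[b] = gi
    gid = np.array([merged.get(b, -1) for b in which])
    for gi in range(len(groups)):
        sel = scored & (gid == gi)
        if sel.sum() < 2:
            vals = raw[sel]
            z[sel] = 0.0 if vals.size else np.nan
            continue
        mu, sd = raw[sel].mean(), raw[sel].std(ddof=0)
        z[sel] = (raw[sel] - mu) / sd if sd > 0 else 0.0
    return z


def xpehh_scan(
    panelA: HaplotypePanel,
    panelB: HaplotypePanel,
    truncate: float = 0.05,
) -> ScanResult:
    """Cross-population EHH scan: XP-EHH = ln(iES_A / iES_B) per marker.

    iES is the whole-population integrated EHH within each panel; scores are
    standardized genome-wide. Positive scores indicate longer haplotypes
    (a harder sweep) in population A.
    """
    if panelA.marker_ids != panelB.marker_ids:
        raise ValueError("panels must share a marker map")
    for name, p in (("A", panelA), ("B", panelB)):
        if p.n_haplotypes < 4:
            raise ValueError(f"population {name} has fewer than 4 haplotypes")
    m = panelA.n_markers
    raw = np.full(m, np.nan)
    for j in range(m):
        _, ies_a = ehh(panelA, j, allele=None, truncate=truncate)
        _, ies_b = ehh(panelB, j, allele=None, truncate=truncate)
        if ies_a > 0 and ies_b > 0:
            raw[j] = np.log(ies_a / ies_b)
    scored = ~np.isnan(raw)
    z = np.full(m, np.nan)
    if scored.sum() >= 2 and raw[scored].std() > 0:
        z[scored] = (raw[scored] - raw[scored].mean()) / raw[scored].std(ddof=0)
    elif scored.any():
        z[scored] = 0.0
    p = 2 * stats.norm.sf(np.abs(z))
    q, pi0 = _qvalues_with_nan(p)
    table = _scan_table(panelA.marker_ids, panelA.marker_map, raw=raw, z=z, p=p, q=q)
    return ScanResult("xpehh", table, pi0=pi0)


# ------------------------------------------------------------------- q-values


def storey_qvalues(
    pvals: np.ndarray, lambdas: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values and the null-proportion estimate pi0.

    pi0 is estimated on a lambda grid with a cubic-smoother extrapolation to
    lambda -> 1 (falling back to pi0 = 1 for small m), and
    q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 100:
        pi0 = 1.0
    else:
        pi0_l = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
        from scipy.interpolate import UnivariateSpline

        spl = UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(np.clip(spl(lambdas[-1]), 1e-8, 1.0))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def _qvalues_with_nan(p: np.ndarray) -> tuple[np.ndarray, float]:
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if not ok.any():
        return q, float("nan")
    q[ok], pi0 = storey_qvalues(p[ok])
    return q, pi0


# ------------------------------------------------------------------ consensus

DEFAULT_Q_THRESHOLDS = {"ihs": 0.01, "xpehh": 0.01, "pca_outlier": 0.05}


def consensus_sweeps(
    results: list[ScanResult],
    flank: int = 250_000,
    q_thresholds: dict[str, float] | None = None,
) -> list[SweepRegion]:
    """Candidate sweep regions supported by at least two statistics.

    A marker significant (q below its method's threshold) in >= 2 result sets
    seeds the region [pos - flank, pos + flank] (1-based, inclusive).
    Overlapping regions from distinct top SNPs are kept separate.
    """
    if len(results) < 2:
        raise ValueError("need at least two scan results")
    thr = dict(DEFAULT_Q_THRESHOLDS)
    if q_thresholds:
        thr.update(q_thresholds)
    ids = results[0].table["marker_id"].tolist()
    for r in results[1:]:
        if r.table["marker_id"].tolist() != ids:
            raise ValueError("scan results do not share a marker map")
    regions: list[SweepRegion] = []
    for i, mid in enumerate(ids):
        hits, stats_, pvals = [], {}, {}
        for r in results:
            row = r.table.iloc[i]
            t = thr.get(r.method, 0.05)
            if not np.isnan(row["q"]) and row["q"] < t:
                hits.append(r.method)
                stats_[r.method] = float(row["z"])
                pvals[r.method] = float(row["p"])
        if len(hits) >= 2:
            row0 = results[0].table.iloc[i]
            pos = int(row0["pos"])
            regions.append(
                SweepRegion(
                    chrom=int(row0["chrom"]),
                    start=max(pos - flank, 1),
                    end=pos + flank,
                    top_snp=mid,
                    methods=hits,
                    stats=stats_,
                    pvals=pvals,
                )
            )
    return regions


def genes_near(region: SweepRegion, gff_path: str, pad: int = 250_000) -> list[str]:
    """Gene IDs whose span intersects the padded sweep region.

    The interval [start - pad, end + pad] is closed on both sides: a gene
    ending exactly at start - pad is included. Chromosome names in the GFF
    must match ``chr<k>`` or ``<k>`` for region chromosome k.
    """
    import gffutils

    db = gffutils.create_db(
        gff_path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    lo, hi = region.start - pad, region.end + pad
    accepted = {str(region.chrom), f"chr{region.chrom}", f"chr{region.chrom:02d}"}
    seqids = {f.seqid for f in db.all_features()}
    match = seqids & accepted
    if not match:
        raise ValueError(
            f"no GFF chromosome matches region chromosome {region.chrom}; "
            f"seqids present: {sorted(seqids)[:5]}"
        )
    out = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in match:
            continue
        if gene.end >= lo and gene.start <= hi:
            out.append(gene.id)
    return out


# -------------------------------------------------------------------- helpers


def _scan_table(
    marker_ids: list[str],
    mmap: MarkerMap | None,
    raw: np.ndarray,
    z: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
) -> pd.DataFrame:
    df = pd.DataFrame({"marker_id": marker_ids, "raw": raw, "z": z, "p": p, "q": q})
    if mmap is not None:
        pos = mmap.table.set_index("marker_id").reindex(marker_ids)
        df.insert(1, "chrom", pos["chrom"].to_numpy())
        df.insert(2, "pos", pos["pos"].to_numpy())
    else:
        df.insert(1, "chrom", np.nan)
        df.insert(2, "pos", np.nan)
    return df
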