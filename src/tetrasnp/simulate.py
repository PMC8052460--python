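"""Synthetic tetraploid panels with known truth.

The generator emulates a mid-size autotetraploid potato breeding collection
genotyped on a SNP array: ~214 clones in three subpopulations of unequal
size, ~10,000 biallelic markers on 12 chromosomes, subpopulation allele
frequencies drawn from the Balding-Nichols model at differentiation levels
spanning roughly 0.02-0.14 pairwise Fst, minor allele frequencies in
[0.05, 0.50], and a few percent missing calls. Anomalies found in real clone
banks are injected on request: duplicated accessions, market-class
mislabels, and one diploid clone. Pedigreed offspring arise from random
bivalent chromatid segregation without double reduction, and sweep haplotype
panels are built by a founder-copying construction with distance-dependent
decay.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClonePanel, DosageMatrix, MarkerMap
from .selection import HaplotypePanel

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_structured_population",
    "simulate_neutral_sites",
    "simulate_cross",
    "simulate_sweep_panel",
    "simulate_sweep_pair",
    "inject_anomalies",
]

# pseudomolecule lengths are immaterial to the statistics; a uniform 73 Mb
# per chromosome reproduces the ~71 kb mean marker spacing at 10k markers
CHROM_LENGTH_BP = 73_000_000
N_CHROMOSOMES = 12

_POP_CLASSES = {
    0: ["Red", "Purple", "Yellow"],   # specialty subpopulation
    1: ["Russet"],                    # Russet Norkotah-like strain group
    2: ["Chipping", "Russet"],        # chip & russet subpopulation
}


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic collection."""

    n_per_pop: tuple[int, ...] = (94, 18, 102)   # three subpopulations, 214 clones
    m_markers: int = 10_000
    fst: tuple[float, ...] = (0.03, 0.22, 0.05)  # per-subpop drift; pairwise ~0.04-0.14
    maf_range: tuple[float, float] = (0.05, 0.50)
    missing_rate: float = 0.05
    seed: int = 0
    # anomaly counts (duplicates as extra copied rows; mislabels as class swaps)
    n_duplicates: int = 2
    n_mislabels: int = 5
    n_diploid: int = 1
    duplicate_error_rate: float = 0.0
    # sweep panel
    n_haplotypes: int = 120
    sweep_m_markers: int = 400
    sweep_pos_frac: float = 0.5        # sweep locus at this fraction of the chromosome
    sweep_derived_freq: float = 0.8
    sweep_homogeneity: float = 0.9     # per-marker copying fidelity of carrier haplotypes
    sweep_decay_bp: float = 2_000_000.0

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.duplicate_error_rate, self.sweep_homogeneity):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthSet:
    subpopulation: dict[str, int] = field(default_factory=dict)
    pedigree: pd.DataFrame | None = None
    duplicates: list[tuple[str, str]] = field(default_factory=list)
    mislabels: list[str] = field(default_factory=list)
    diploids: list[str] = field(default_factory=list)
    sweep_markers: list[str] = field(default_factory=list)
    ancestral_freq: np.ndarray | None = None
    subpop_freq: np.ndarray | None = None


def _random_map(rng: np.random.Generator, m: int, prefix: str = "snp") -> MarkerMap:
    chrom = rng.integers(1, N_CHROMOSOMES + 1, size=m)
    pos = rng.integers(1, CHROM_LENGTH_BP + 1, size=m)
    df = pd.DataFrame({"marker_id": [f"{prefix}_{i:06d}" for i in range(m)], "chrom": chrom, "pos": pos})
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df["marker_id"] = [f"{prefix}_{i:06d}" for i in range(m)]  # ids follow map order
    return MarkerMap(df)


def simulate_structured_population(
    cfg: SimConfig,
) -> tuple[DosageMatrix, ClonePanel, MarkerMap, TruthSet]:
    """Balding-Nichols structured tetraploid panel with metadata and truth.

    Ancestral frequencies are uniform on the configured MAF range; each
    subpopulation k draws its frequency from Beta(p(1-F_k)/F_k,
    (1-p)(1-F_k)/F_k) (kept at the ancestral value when F_k = 0), and each
    clone's dosage is Binomial(4, p_k). Missing calls are uniform at random.
    """
    rng = np.random.default_rng(cfg.seed)
    K = len(cfg.n_per_pop)
    fst = cfg.fst if len(cfg.fst) == K else tuple(cfg.fst[0] for _ in range(K))
    m = cfg.m_markers
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    sub = np.empty((K, m))
    for k in range(K):
        F = fst[k]
        if F <= 0:
            sub[k] = p_anc
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            sub[k] = rng.beta(a, b)
    clone_ids, rows, pops, classes = [], [], [], []
    for k, nk in enumerate(cfg.n_per_pop):
        opts = _POP_CLASSES.get(k, ["Chipping"])
        for i in range(nk):
            clone_ids.append(f"P{k + 1}_{i:03d}")
            rows.append(rng.binomial(4, sub[k]))
            pops.append(k)
            classes.append(opts[i % len(opts)])
    X = np.array(rows, dtype=float)
    if cfg.missing_rate > 0:
        mask = rng.random(X.shape) < cfg.missing_rate
        X[mask] = np.nan
    mmap = _random_map(rng, m)
    D = DosageMatrix(clone_ids, list(mmap.table["marker_id"]), X, ploidy=4)
    panel = ClonePanel(
        pd.DataFrame(
            {
                "clone_id": clone_ids,
                "market_class": classes,
                "code": [f"{c[:2].upper()}" for c in classes],
                "group": pops,
            }
        )
    )
    truth = TruthSet(
        subpopulation=dict(zip(clone_ids, pops)),
        ancestral_freq=p_anc,
        subpop_freq=sub,
    )
    return D, panel, mmap, truth


def simulate_cross(
    d_female: np.ndarray, d_male: np.ndarray, n_offspring: int, seed: int
) -> np.ndarray:
    """Offspring dosages from a tetraploid cross under bivalent segregation.

    Each gamete carries 2 of the parent's 4 chromatids drawn without
    replacement, so the gamete dosage is Hypergeometric(4, d, 2); offspring
    dosage is the sum of the two gametes. Markers segregate independently and
    double reduction is excluded.
    """
    d_f = np.asarray(d_female, dtype=float)
    d_m = np.asarray(d_male, dtype=float)
    if d_f.shape != d_m.shape:
        raise ValueError("parental dosage vectors differ in length")
    rng = np.random.default_rng(seed)
    m = d_f.size
    out = np.full((n_offspring, m), np.nan)
    ok = ~(np.isnan(d_f) | np.isnan(d_m))
    for i in range(n_offspring):
        gf = rng.hypergeometric(d_f[ok].astype(int), 4 - d_f[ok].astype(int), 2)
        gm = rng.hypergeometric(d_m[ok].astype(int), 4 - d_m[ok].astype(int), 2)
        out[i, ok] = gf + gm
    return out


def simulate_neutral_sites(n: int, L: int, seed: int) -> DosageMatrix:
    """Ploidy-2 panel whose sites follow the neutral frequency spectrum.

    Each clone is one sequence (calls coded 0/2, no heterozygotes); site
    minor-allele counts i are drawn with probability proportional to 1/i,
    the standard neutral site-frequency spectrum, which equates the
    expectations of pairwise diversity and Watterson's estimator so that
    Tajima's D is centred near zero.
    """
    rng = np.random.default_rng(seed)
    counts = np.arange(1, n)
    weights = (1.0 / counts) / (1.0 / counts).sum()
    X = np.zeros((n, L))
    for j in range(L):
        i = rng.choice(counts, p=weights)
        carriers = rng.choice(n, size=i, replace=False)
        X[carriers, j] = 2.0
    return DosageMatrix(
        [f"seq{k:03d}" for k in range(n)], [f"site{j:04d}" for j in range(L)], X, ploidy=2
    )


def _sweep_map(rng: np.random.Generator, m: int) -> MarkerMap:
    pos = np.sort(rng.choice(np.arange(1, CHROM_LENGTH_BP, 10_000), size=m, replace=False))
    return MarkerMap(
        pd.DataFrame(
            {"marker_id": [f"hap_{i:05d}" for i in range(m)], "chrom": 1, "pos": pos}
        )
    )


def simulate_sweep_panel(cfg: SimConfig) -> tuple[HaplotypePanel, TruthSet]:
    """Haplotype panel with one planted sweep on a single chromosome.

    Neutral haplotypes are marker-wise independent draws at uniform
    [0.05, 0.95] derived frequencies (array alleles carry no true ancestral
    polarity, so the derived-frequency spectrum spans both sides). A fraction
    ``sweep_derived_freq`` of haplotypes carry the derived allele at the
    sweep locus; every carrier copies one founder haplotype outward from the
    locus, switching out permanently at each step with probability
    1 - exp(-gap_bp / sweep_decay_bp) and copying each marker with fidelity
    ``sweep_homogeneity``. With infinite decay and fidelity 1 the carriers
    are identical over the whole chromosome.
    """
    if not 0.2 < cfg.sweep_derived_freq < 0.95:
        raise ValueError("sweep derived frequency must be in (0.2, 0.95)")
    rng = np.random.default_rng(cfg.seed)
    H, m = cfg.n_haplotypes, cfg.sweep_m_markers
    mmap = _sweep_map(rng, m)
    pos = mmap.table["pos"].to_numpy()
    freq = rng.uniform(0.05, 0.95, size=m)
    A = (rng.random((H, m)) < freq).astype(np.int8)
    locus = int(np.searchsorted(pos, pos[0] + cfg.sweep_pos_frac * (pos[-1] - pos[0])))
    locus = min(locus, m - 1)
    n_car = int(round(cfg.sweep_derived_freq * H))
    if n_car < 4:
        raise ValueError("fewer than 4 carrier haplotypes; raise derived frequency or panel size")
    carriers = rng.choice(H, size=n_car, replace=False)
    A[:, locus] = 0
    A[carriers, locus] = 1
    founder = (rng.random(m) < freq).astype(np.int8)
    for h in carriers:
        for step in (-1, 1):
            k = locus
            while True:
                nxt = k + step
                if nxt < 0 or nxt >= m:
                    break
                gap = abs(pos[nxt] - pos[k])
                if rng.random() < 1 - np.exp(-gap / cfg.sweep_decay_bp):
                    break
                if rng.random() < cfg.sweep_homogeneity:
                    A[h, nxt] = founder[nxt]
                k = nxt
    hap_ids = [f"h{j:04d}" for j in range(H)]
    truth = TruthSet(sweep_markers=[mmap.table["marker_id"].iloc[locus]])
    return HaplotypePanel(hap_ids, A, mmap, populations=["A"] * H), truth


def simulate_sweep_pair(cfg: SimConfig) -> tuple[HaplotypePanel, HaplotypePanel, TruthSet]:
    """Two panels on one map: a sweep in population A, population B neutral."""
    panelA, truth = simulate_sweep_panel(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    m = panelA.n_markers
    freq = rng.uniform(0.05, 0.95, size=m)
    B = (rng.random((cfg.n_haplotypes, m)) < freq).astype(np.int8)
    panelB = HaplotypePanel(
        [f"b{j:04d}" for j in range(cfg.n_haplotypes)],
        B,
        panelA.marker_map,
        populations=["B"] * cfg.n_haplotypes,
    )
    return panelA, panelB, truth


def inject_anomalies(
    D: DosageMatrix, panel: ClonePanel, cfg: SimConfig, truth: TruthSet | None = None
) -> tuple[DosageMatrix, ClonePanel, TruthSet]:
    """Add duplicate rows, market-class mislabels and a diploid clone.

    Duplicates are copied rows (optionally with per-call error); mislabels
    swap the declared market class of clones across true groups; the diploid
    clone draws dosages as twice a Binomial(2, p) so that simplex and triplex
    classes never occur.
    """
    rng = np.random.default_rng(cfg.seed + 7)
    if cfg.n_duplicates + cfg.n_mislabels + cfg.n_diploid > D.n_clones:
        raise ValueError("requested anomalies exceed panel size")
    truth = truth or TruthSet()
    X = D.dosage
    new_ids = list(D.clone_ids)
    new_rows = [X]
    meta = panel.table.copy().set_index("clone_id")

    src = rng.choice(D.n_clones, size=cfg.n_duplicates, replace=False)
    for s in src:
        sid = D.clone_ids[s]
        did = f"{sid}_dup"
        row = X[s].copy()
        if cfg.duplicate_error_rate > 0:
            sel = (rng.random(row.size) < cfg.duplicate_error_rate) & ~np.isnan(row)
            row[sel] = rng.integers(0, 5, size=int(sel.sum())).astype(float)
        new_ids.append(did)
        new_rows.append(row[None, :])
        meta.loc[did] = meta.loc[sid]
        truth.duplicates.append((sid, did))

    groups = meta["group"] if "group" in meta.columns else None
    candidates = [c for c in D.clone_ids if c not in {d for _, d in truth.duplicates}]
    swap = rng.choice(len(candidates), size=cfg.n_mislabels, replace=False)
    for idx in swap:
        cid = candidates[idx]
        own = meta.loc[cid, "market_class"]
        if groups is not None:
            other = meta.loc[(groups != groups.loc[cid]) & (meta["market_class"] != own)]
        else:
            other = meta.loc[meta["market_class"] != own]
        if other.empty:
            continue
        pick = rng.integers(0, len(other))
        meta.loc[cid, "market_class"] = other["market_class"].iloc[pick]
        truth.mislabels.append(cid)

    p_panel = np.nansum(X, axis=0) / (4 * np.maximum((~np.isnan(X)).sum(axis=0), 1))
    for d in range(cfg.n_diploid):
        did = f"DIPLOID_{d:02d}"
        row = 2.0 * rng.binomial(2, np.clip(p_panel, 0, 1)).astype(float)
        new_ids.append(did)
        new_rows.append(row[None, :])
        meta.loc[did] = {"market_class": "Yellow", "code": "Y/Y", "group": -1}
        truth.diploids.append(did)

    D2 = DosageMatrix(new_ids, list(D.marker_ids), np.vstack(new_rows), ploidy=4)
    panel2 = ClonePanel(meta.reset_index().rename(columns={"index": "clone_id"}))
    return D2, panel2, truth
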