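"""Marker- and clone-level diversity statistics and sequence diversity.

Per-marker statistics (He, PIC, MAF) are computed on tetraploid dosages with
allele frequencies pooled over all chromosome sets. The sequence-diversity
summary (pi, Watterson's theta, Tajima's D) treats each clone's diploidized
genotype as one sequence, mirroring the convention of genotype-table tools
that compute site diversity from diploid calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .io import DosageMatrix

__all__ = [
    "marker_stats",
    "clone_stats",
    "sequence_diversity",
    "DiversitySummary",
    "harmonic_number",
    "tajima_d_from_totals",
]

EULER_GAMMA = float(np.euler_gamma)


def harmonic_number(x: float) -> float:
    """Generalized harmonic number H_x = sum_{i<=x} 1/i, via digamma for real x."""
    return float(digamma(x + 1) + EULER_GAMMA)


@dataclass
class DiversitySummary:
    n: int                 # sequences (clones)
    S: int                 # segregating sites
    L: int                 # assayed sites
    pi: float              # mean pairwise diversity per site
    theta_w: float         # Watterson estimator per site
    tajima_d: float        # NaN when S < 3
    n_effective: float     # harmonic-mean non-missing sample size across sites


def marker_stats(D: DosageMatrix) -> pd.DataFrame:
    """Per-marker B-allele frequency, MAF, He and PIC.

    He = 2p(1-p); PIC = 1 - (p^2 + q^2) - 2 p^2 q^2 (biallelic Botstein
    index). Markers with every call missing get NaN statistics.
    """
    X = D.dosage
    nonmiss = ~np.isnan(X)
    n_nm = nonmiss.sum(axis=0)
    p = np.where(n_nm > 0, np.nansum(X, axis=0) / (D.ploidy * np.maximum(n_nm, 1)), np.nan)
    q = 1 - p
    maf = np.minimum(p, q)
    he = 2 * p * q
    pic = 1 - (p**2 + q**2) - 2 * p**2 * q**2
    return pd.DataFrame(
        {"marker_id": D.marker_ids, "p": p, "MAF": maf, "He": he, "PIC": pic}
    )


def clone_stats(D: DosageMatrix, he_mean: float) -> pd.DataFrame:
    """Per-clone observed heterozygosity and inbreeding coefficient.

    Ho is the fraction of non-missing markers called heterozygous (any dosage
    strictly between 0 and ploidy); F = 1 - Ho / He_mean, with He_mean the
    panel mean expected heterozygosity.
    """
    if not he_mean > 0:
        raise ValueError("he_mean must be positive")
    X = D.dosage
    het = (X > 0) & (X < D.ploidy)
    n_nm = (~np.isnan(X)).sum(axis=1)
    ho = np.where(n_nm > 0, het.sum(axis=1) / np.maximum(n_nm, 1), np.nan)
    f = 1 - ho / he_mean
    return pd.DataFrame({"clone_id": D.clone_ids, "Ho": ho, "F": f})


def _tajima_constants(n: float) -> dict[str, float]:
    from scipy.special import polygamma

    a1 = harmonic_number(n - 1)
    # a2 = sum_{i=1}^{n-1} 1/i^2, continued to real n via the trigamma function
    a2 = float(np.pi**2 / 6 - polygamma(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_from_totals(pi_total: float, S: int, n: float) -> float:
    """Tajima's D from total pairwise diversity, segregating sites and sample size."""
    if S < 3:
        return float("nan")
    c = _tajima_constants(n)
    theta_total = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi_total - theta_total) / np.sqrt(var)


def sequence_diversity(
    Ddip: DosageMatrix, small_sample_correction: bool = True
) -> DiversitySummary:
    """pi, Watterson's theta and Tajima's D on a diploidized matrix.

    Each clone contributes one diploid sequence (2 alleles per site). At a
    site with m non-missing clones and B-allele frequency p-hat among its 2m
    alleles, the site diversity is 2*p*(1-p) times the small-sample factor
    2m/(2m-1) (switchable); pi averages this over all assayed sites, including
    sites fixed after filtering. theta_w = S / (a1 * L) with the harmonic
    number a1 evaluated at the harmonic-mean per-site sample size, which under
    complete data reduces to the textbook a1 at n sequences. Tajima's D uses
    the standard variance terms with S segregating sites; it is NaN when
    S < 3.
    """
    if Ddip.ploidy != 2:
        raise ValueError("sequence_diversity expects a diploidized (ploidy-2) matrix")
    X = Ddip.dosage
    n, L = X.shape
    m = (~np.isnan(X)).sum(axis=0).astype(float)  # clones per site
    assayed = m > 0
    if not assayed.any():
        raise ValueError("no assayed sites")
    alleles = 2 * m
    p = np.where(assayed, np.nansum(X, axis=0) / np.maximum(alleles, 1), np.nan)
    site_pi = 2 * p * (1 - p)
    if small_sample_correction:
        with np.errstate(invalid="ignore", divide="ignore"):
            site_pi = site_pi * alleles / np.maximum(alleles - 1, 1)
    pi = float(np.nanmean(site_pi[assayed]))
    seg = assayed & (p > 0) & (p < 1)
    S = int(seg.sum())
    n_eff = float(len(m[assayed]) / np.sum(1.0 / m[assayed]))  # harmonic mean
    a1_eff = harmonic_number(n_eff - 1) if n_eff > 1 else float("nan")
    L_assayed = int(assayed.sum())
    theta_w = S / (a1_eff * L_assayed) if S > 0 and a1_eff > 0 else 0.0
    d = tajima_d_from_totals(pi * L_assayed, S, n_eff)
    return DiversitySummary(
        n=n, S=S, L=L_assayed, pi=pi, theta_w=theta_w, tajima_d=d, n_effective=n_eff
    )
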