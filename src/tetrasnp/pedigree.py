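"""Pedigree verification: A and G matrices and trio conflict rates.

The additive relationship matrix A follows the tabular method on the recorded
pedigree; the genomic matrix G is the marker-based covariance normalized so
that parent-offspring pairs sit near 0.5 and unrelated clones near 0. The
trio conflict statistic is the percentage of markers at which both recorded
parents are monomorphic (dosage 0 or 4) but the offspring genotype differs
from the Mendelian-forced value — exactly 0 for a correctly recorded,
error-free trio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DosageMatrix

__all__ = [
    "PedigreeTable",
    "TrioReport",
    "additive_matrix",
    "genomic_matrix",
    "trio_conflict",
    "single_parent_check",
]


@dataclass
class PedigreeTable:
    """Recorded ancestry: one row per clone with optional parents."""

    table: pd.DataFrame  # columns clone, female, male (NaN/'' = unknown)

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("clone", "female", "male"):
            if col not in t.columns:
                raise ValueError("pedigree needs columns clone, female, male")
            t[col] = t[col].astype(object).where(pd.notna(t[col]), None)
            t[col] = t[col].map(lambda v: None if v in (None, "") else str(v))
        if t["clone"].duplicated().any():
            raise ValueError("duplicate clones in pedigree")
        self.table = t
        self.order = self._toposort()

    def parents(self, clone: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table["clone"] == clone]
        if row.empty:
            return (None, None)
        return row["female"].iloc[0], row["male"].iloc[0]

    def individuals(self) -> list[str]:
        ids = list(self.table["clone"])
        for col in ("female", "male"):
            for v in self.table[col]:
                if v is not None and v not in ids:
                    ids.append(v)
        return ids

    def _toposort(self) -> list[str]:
        ids = self.individuals()
        par = {c: [p for p in self.parents(c) if p is not None] for c in ids}
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(x: str) -> None:
            if state.get(x) == 2:
                return
            if state.get(x) == 1:
                raise ValueError(f"pedigree cycle involving {x!r}")
            state[x] = 1
            for p in par.get(x, []):
                visit(p)
            state[x] = 2
            order.append(x)

        for c in ids:
            visit(c)
        return order


@dataclass
class TrioReport:
    clone: str
    female: str
    male: str
    n_informative: int
    conflict_pct: float
    verdict: str  # accurate | conflicted | untestable


def additive_matrix(ped: PedigreeTable) -> pd.DataFrame:
    """Additive relationship matrix by the tabular method.

    Individuals are processed parents-before-offspring; unknown parents
    contribute 0, so founders are non-inbred with A_ii = 1. A non-inbred
    parent-offspring pair has A = 0.5 and a grandparent-grandchild pair 0.25.
    """
    order = ped.order
    n = len(order)
    pos = {c: i for i, c in enumerate(order)}
    A = np.zeros((n, n))
    for c in order:
        i = pos[c]
        f, m = ped.parents(c)
        fi = pos.get(f) if f else None
        mi = pos.get(m) if m else None
        A[i, i] = 1.0 + 0.5 * (A[fi, mi] if fi is not None and mi is not None else 0.0)
        for j in range(i):
            val = 0.0
            if fi is not None:
                val += 0.5 * A[j, fi]
            if mi is not None:
                val += 0.5 * A[j, mi]
            A[i, j] = A[j, i] = val
    return pd.DataFrame(A, index=order, columns=order)


def genomic_matrix(D: DosageMatrix) -> pd.DataFrame:
    """Marker-based genomic relationship matrix for tetraploid dosages.

    G_ij = sum_m (x_im - 4 p_m)(x_jm - 4 p_m) / sum_m 4 p_m (1 - p_m), with
    panel allele frequencies p_m and, under pairwise missing-data exclusion,
    both sums restricted to markers non-missing in both clones. Monomorphic
    markers contribute nothing to either sum.
    """
    X = D.dosage
    valid = ~np.isnan(X)
    n_nm = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0) / (D.ploidy * np.maximum(n_nm, 1))
    w = D.ploidy * p * (1 - p)  # per-marker denominator weight
    informative = (w > 0) & (n_nm > 0)
    C = np.where(valid & informative, X - D.ploidy * p, 0.0)
    Vw = (valid & informative) * w
    num = C @ C.T
    den = (valid & informative).astype(float) @ Vw.T
    with np.errstate(invalid="ignore", divide="ignore"):
        G = num / den
    return pd.DataFrame(G, index=D.clone_ids, columns=D.clone_ids)


def trio_conflict(
    D: DosageMatrix,
    offspring: str,
    female: str,
    male: str,
    accurate_below: float = 1.0,
) -> TrioReport:
    """Conflict rate of an offspring against two recorded parents.

    Informative markers are those where both parents are monomorphic (dosage
    0 or ploidy) and all three calls are present; the forced offspring dosage
    is the sum of the parents' obligate gamete dosages (0x0 -> 0, 0x4 -> 2,
    4x4 -> 4). The conflict percentage is the share of informative markers at
    which the observed offspring dosage differs from the forced value. Trios
    below ``accurate_below`` percent are labeled accurate.
    """
    o, f, m = (D.row(c) for c in (offspring, female, male))
    P = D.ploidy
    present = ~(np.isnan(o) | np.isnan(f) | np.isnan(m))
    mono = np.isin(f, [0, P]) & np.isin(m, [0, P])
    informative = present & mono
    n_inf = int(informative.sum())
    if n_inf == 0:
        return TrioReport(offspring, female, male, 0, float("nan"), "untestable")
    forced = (f[informative] + m[informative]) / 2
    pct = 100.0 * float(np.mean(o[informative] != forced))
    verdict = "accurate" if pct < accurate_below else "conflicted"
    return TrioReport(offspring, female, male, n_inf, pct, verdict)


def single_parent_check(
    D: DosageMatrix,
    offspring: str,
    parent: str,
    A: pd.DataFrame,
    G: pd.DataFrame | None = None,
    tau: float = 0.15,
) -> tuple[str, pd.DataFrame]:
    """Verify a single recorded parent from the marker-vs-pedigree surface.

    Emits (A, G) pairs of the offspring against all genotyped clones and an
    opposing-homozygote rate for the putative parent (parent at dosage 0 with
    offspring at ploidy, or vice versa — impossible under true parentage
    without genotyping error). The verdict is "supported" when the parent's G
    lies in the parent band (G >= 0.5 - tau) and exceeds every A-unrelated
    clone's G; otherwise "rejected".
    """
    if G is None:
        G = genomic_matrix(D)
    records = []
    for c in D.clone_ids:
        if c == offspring:
            continue
        a = float(A.loc[offspring, c]) if offspring in A.index and c in A.columns else np.nan
        records.append({"clone_id": c, "A": a, "G": float(G.loc[offspring, c])})
    pairs = pd.DataFrame(records)
    o, p = D.row(offspring), D.row(parent)
    present = ~(np.isnan(o) | np.isnan(p))
    opposing = ((o == 0) & (p == D.ploidy)) | ((o == D.ploidy) & (p == 0))
    opp_rate = float(opposing[present].mean()) if present.any() else float("nan")
    g_par = float(G.loc[offspring, parent])
    unrelated = pairs.loc[(pairs["A"] == 0) & (pairs["clone_id"] != parent), "G"]
    band_ok = g_par >= 0.5 - tau
    above_unrelated = unrelated.empty or g_par > unrelated.max()
    verdict = "supported" if band_ok and above_unrelated else "rejected"
    pairs.attrs["opposing_homozygote_rate"] = opp_rate
    pairs.attrs["parent_G"] = g_par
    return verdict, pairs
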