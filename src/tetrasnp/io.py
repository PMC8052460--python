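"""Genotype and annotation input/output for tetraploid SNP dosage panels.

The central container is :class:`DosageMatrix`: a clones x markers table of
B-allele dosages. For an autotetraploid each call is one of the five genotype
classes nulliplex (0), simplex (1), duplex (2), triplex (3) or quadruplex (4);
after diploidization calls are coded 0/1/2. Missing calls are NaN.

Dosage orientation is fixed: a dosage counts copies of the B (alternate)
allele. Array platforms do not define an ancestral allele, so downstream
haplotype statistics that need polarity treat B as the derived proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DosageMatrix",
    "MarkerMap",
    "ClonePanel",
    "FilterReport",
    "SpacingSummary",
    "read_dosage_matrix",
    "write_dosage_csv",
    "read_marker_map",
    "read_clone_panel",
    "filter_markers",
    "diploidize",
    "five_cluster_frequencies",
    "infer_ploidy",
    "marker_spacing_summary",
]

GENOTYPE_CLASSES = ("nulliplex", "simplex", "duplex", "triplex", "quadruplex")

MARKET_CLASSES = frozenset({"Chipping", "Russet", "Red", "Purple", "Yellow"})


class GenotypeIOError(ValueError):
    """Malformed genotype input (located message in ``args[0]``)."""


@dataclass
class DosageMatrix:
    """Clones x markers allele-dosage matrix.

    Parameters
    ----------
    clone_ids : list of str
        Unique row identifiers.
    marker_ids : list of str
        Unique column identifiers.
    dosage : ndarray of float, shape (n_clones, n_markers)
        B-allele dosage in ``{0, ..., ploidy}``; NaN encodes missing.
    ploidy : int
        4 for tetraploid calls, 2 after diploidization.
    """

    clone_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    ploidy: int = 4

    def __post_init__(self) -> None:
        self.clone_ids = [str(c) for c in self.clone_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.clone_ids), len(self.marker_ids)):
            raise GenotypeIOError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.clone_ids)} clones x {len(self.marker_ids)} markers"
            )
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise GenotypeIOError("duplicate clone ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeIOError("duplicate marker ids")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and (
            np.any(vals < 0) or np.any(vals > self.ploidy) or np.any(vals != np.round(vals))
        ):
            raise GenotypeIOError(
                f"dosages must be integers in 0..{self.ploidy} or missing"
            )

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def clone_index(self, clone_id: str) -> int:
        try:
            return self.clone_ids.index(clone_id)
        except ValueError:
            raise KeyError(f"clone {clone_id!r} not in matrix") from None

    def row(self, clone_id: str) -> np.ndarray:
        return self.dosage[self.clone_index(clone_id)]

    def subset_clones(self, keep: list[str]) -> "DosageMatrix":
        idx = [self.clone_index(c) for c in keep]
        return DosageMatrix(list(keep), list(self.marker_ids), self.dosage[idx], self.ploidy)

    def subset_markers(self, keep_idx: np.ndarray) -> "DosageMatrix":
        keep_idx = np.asarray(keep_idx)
        return DosageMatrix(
            list(self.clone_ids),
            [self.marker_ids[i] for i in keep_idx],
            self.dosage[:, keep_idx],
            self.ploidy,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.clone_ids, columns=self.marker_ids)


@dataclass
class MarkerMap:
    """Physical map: marker -> (chromosome 1..12, bp position, 1-based)."""

    table: pd.DataFrame  # columns marker_id, chrom, pos

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker_id", "chrom", "pos"}
        if not required.issubset(t.columns):
            raise GenotypeIOError(f"marker map needs columns {sorted(required)}")
        if t["marker_id"].duplicated().any():
            raise GenotypeIOError("duplicate marker ids in map")
        if (t["pos"] < 0).any():
            raise GenotypeIOError("negative positions in map")
        self.table = t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def chromosomes(self) -> list[int]:
        return sorted(self.table["chrom"].unique())

    def positions(self, marker_ids: list[str]) -> pd.DataFrame:
        return self.table.set_index("marker_id").loc[marker_ids].reset_index()


@dataclass
class ClonePanel:
    """Clone metadata: market class and declared skin/flesh code."""

    table: pd.DataFrame  # columns clone_id, market_class, code (optional group)

    def __post_init__(self) -> None:
        t = self.table
        if "clone_id" not in t.columns or "market_class" not in t.columns:
            raise GenotypeIOError("clone panel needs clone_id and market_class columns")
        if t["clone_id"].duplicated().any():
            raise GenotypeIOError("duplicate clone ids in panel")
        bad = set(t["market_class"]) - MARKET_CLASSES
        if bad:
            raise GenotypeIOError(f"unknown market classes: {sorted(bad)}")

    def market_class(self, clone_id: str) -> str:
        sel = self.table.loc[self.table["clone_id"] == clone_id, "market_class"]
        if sel.empty:
            raise KeyError(clone_id)
        return sel.iloc[0]


@dataclass
class FilterReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int
    maf_min: float
    max_missing: float

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_maf + self.n_removed_missing + self.n_retained:
            raise ValueError("filter report counts do not sum to n_input")


@dataclass
class SpacingSummary:
    mean_gap_bp: float
    frac_lt_1kb: float
    frac_lt_10kb: float
    per_chrom_counts: dict[int, int] = field(default_factory=dict)
    n_duplicate_positions: int = 0


def read_dosage_matrix(path: str, format: str = "dosage-csv", ploidy: int = 4) -> DosageMatrix:
    """Read a dosage matrix from CSV or a ploidy-4 VCF.

    CSV dialect: header row of marker ids, first column clone id, cells in
    ``{0..4, NA}``. VCF: only GT is parsed; dosage is the count of ALT alleles;
    any missing subfield (``./0/0/1``) makes the whole call missing.
    """
    if format == "dosage-csv":
        df = pd.read_csv(path, index_col=0, na_values=["NA", "NaN", ""])
        try:
            return DosageMatrix(
                list(df.index.astype(str)),
                list(df.columns.astype(str)),
                df.to_numpy(dtype=float),
                ploidy=ploidy,
            )
        except GenotypeIOError as exc:
            raise GenotypeIOError(f"{path}: {exc}") from None
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: str) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    clones = list(vcf.samples)
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    seen: set[str] = set()
    for v in vcf:
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if mid in seen:
            raise GenotypeIOError(f"{path}: duplicate marker id {mid!r} at {v.CHROM}:{v.POS}")
        seen.add(mid)
        col = np.full(len(clones), np.nan)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 4:
                raise GenotypeIOError(
                    f"{path}: marker {mid!r} sample {clones[i]!r} has ploidy "
                    f"{len(alleles)}, expected 4"
                )
            if any(a < 0 for a in alleles):
                continue  # partially missing GT -> fully missing
            col[i] = sum(1 for a in alleles if a > 0)
        marker_ids.append(mid)
        cols.append(col)
    dosage = np.column_stack(cols) if cols else np.empty((len(clones), 0))
    return DosageMatrix(clones, marker_ids, dosage, ploidy=4)


def write_dosage_csv(D: DosageMatrix, path: str) -> None:
    df = D.to_frame()
    df.index.name = "clone_id"
    df.to_csv(path, na_rep="NA", float_format="%g")


def read_marker_map(path: str) -> MarkerMap:
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    ren = {"chromosome": "chrom", "position": "pos"}
    df = df.rename(columns=ren)
    df["marker_id"] = df["marker_id"].astype(str)
    return MarkerMap(df[["marker_id", "chrom", "pos"]])


def read_clone_panel(path: str) -> ClonePanel:
    df = pd.read_csv(path)
    df["clone_id"] = df["clone_id"].astype(str)
    return ClonePanel(df)


def filter_markers(
    D: DosageMatrix, maf_min: float = 0.05, max_missing: float = 0.10
) -> tuple[DosageMatrix, FilterReport]:
    """Two-stage marker filter: MAF first, then call rate.

    Markers with MAF < ``maf_min`` (monomorphic included) are removed first;
    among the survivors, markers whose missing fraction is >= ``max_missing``
    are removed. A marker with every call missing falls at the MAF stage.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    X = D.dosage
    nonmiss = ~np.isnan(X)
    n_nm = nonmiss.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(X, axis=0) / (D.ploidy * np.maximum(n_nm, 1))
    maf = np.minimum(p, 1 - p)
    pass_maf = (maf >= maf_min) & (n_nm > 0)
    # integer-count comparison so a marker at exactly the threshold is removed
    n_missing = D.n_clones - n_nm
    pass_missing = n_missing < max_missing * D.n_clones
    keep = pass_maf & pass_missing
    n_removed_maf = int(np.sum(~pass_maf))
    n_removed_missing = int(np.sum(pass_maf & ~pass_missing))
    report = FilterReport(
        n_input=D.n_markers,
        n_removed_maf=n_removed_maf,
        n_removed_missing=n_removed_missing,
        n_retained=int(keep.sum()),
        maf_min=maf_min,
        max_missing=max_missing,
    )
    if report.n_retained == 0:
        warnings.warn("no markers retained after filtering", UserWarning, stacklevel=2)
    return D.subset_markers(np.flatnonzero(keep)), report


def diploidize(D: DosageMatrix) -> DosageMatrix:
    """Collapse tetraploid dosages to diploid codes: 0->0, {1,2,3}->1, 4->2."""
    if D.ploidy != 4:
        raise ValueError("diploidize expects a tetraploid (ploidy-4) matrix")
    X = D.dosage
    out = np.where(np.isnan(X), np.nan, np.where(X == 0, 0.0, np.where(X == 4, 2.0, 1.0)))
    return DosageMatrix(list(D.clone_ids), list(D.marker_ids), out, ploidy=2)


def five_cluster_frequencies(D: DosageMatrix, clone: str) -> np.ndarray:
    """Frequencies of the five tetraploid genotype classes for one clone.

    Returns a length-5 vector over (nulliplex, simplex, duplex, triplex,
    quadruplex), computed over the clone's non-missing markers; sums to 1.
    """
    if D.ploidy != 4:
        raise ValueError("five-cluster frequencies are defined for tetraploid calls")
    row = D.row(clone)
    vals = row[~np.isnan(row)]
    if vals.size == 0:
        raise ValueError(f"clone {clone!r} has no non-missing calls")
    counts = np.bincount(vals.astype(int), minlength=5)
    return counts / counts.sum()


def infer_ploidy(freqs: np.ndarray, tau_low: float = 0.05, tau_high: float = 0.20) -> str:
    """Call ploidy from the simplex+triplex class frequency.

    Simplex and triplex genotypes cannot occur in a diploid, so their combined
    frequency ``s`` separates the ploidies: ``s < tau_low`` -> diploid,
    ``s > tau_high`` -> tetraploid, otherwise ambiguous.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (5,) or np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("freqs must be a length-5 frequency vector summing to 1")
    s = freqs[1] + freqs[3]
    if s < tau_low:
        return "diploid"
    if s > tau_high:
        return "tetraploid"
    return "ambiguous"


def marker_spacing_summary(mmap: MarkerMap) -> SpacingSummary:
    """Adjacent-marker gap statistics, computed within chromosomes.

    Gaps are position differences between consecutive markers after sorting by
    (chromosome, position); the "< 1 kb" and "< 10 kb" fractions use strict
    inequality. Duplicate (chrom, pos) pairs are allowed but counted.
    """
    t = mmap.table
    gaps: list[np.ndarray] = []
    counts: dict[int, int] = {}
    n_dup = 0
    for chrom, grp in t.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        counts[int(chrom)] = len(pos)
        n_dup += int(len(pos) - len(np.unique(pos)))
        if len(pos) >= 2:
            gaps.append(np.diff(pos))
    if not gaps:
        raise ValueError("need at least 2 markers on some chromosome")
    g = np.concatenate(gaps)
    if n_dup:
        warnings.warn(f"{n_dup} duplicate (chrom, position) pairs in map", UserWarning, stacklevel=2)
    return SpacingSummary(
        mean_gap_bp=float(g.mean()),
        frac_lt_1kb=float(np.mean(g < 1_000)),
        frac_lt_10kb=float(np.mean(g < 10_000)),
        per_chrom_counts=counts,
        n_duplicate_positions=n_dup,
    )
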