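"""SNP extraction and filtering cascade.

From raw per-isolate calls of two callers to the analysis-ready genotype
matrix: caller consensus, depth bounds, allele read-support rules,
per-site missingness, then (for structure analyses) MAF and sliding-window
LD pruning.  Every filter only removes entries or sites — genotypes are
never edited, except that zero-read entries are set to missing.

Boundary semantics follow the stated removal rules: depth >= min_coverage
kept, depth strictly greater than max_depth_fold x isolate mean removed,
missing fraction <= max_missing_frac kept, MAF >= maf_min kept, LD pairs
with r^2 strictly above r2_max resolved by dropping the lower-MAF member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import yaml

from .containers import (
    GT_MISSING,
    GT_TO_DOSAGE,
    MISSING,
    GenotypeMatrix,
    validate_site_calls,
)

logger = logging.getLogger(__name__)


@dataclass
class QCParams:
    min_coverage: int = 15
    max_depth_fold: float = 4.0
    hom_support: float = 0.80
    het_support: float = 0.20
    max_missing_frac: float = 0.01
    maf_min: float = 0.01
    ld_window: int = 50
    ld_step: int = 5
    r2_max: float = 0.5

    def __post_init__(self) -> None:
        for name in ("hom_support", "het_support", "max_missing_frac", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.ld_window >= self.ld_step >= 1:
            raise ValueError("need ld_window >= ld_step >= 1")

    @classmethod
    def from_yaml(cls, path) -> "QCParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown QC parameters in config: {sorted(unknown)}")
        return cls(**raw)


def _log_filter(name: str, n_in: int, n_out: int) -> None:
    logger.info("%s: %d in, %d out (%d removed)", name, n_in, n_out, n_in - n_out)


# ---------------------------------------------------------------------------
# call-level filters


def consensus_sites(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Entries present in both caller tables with identical non-missing genotypes.

    Read counts in the result come from caller A.
    """
    validate_site_calls(calls_a)
    validate_site_calls(calls_b)
    iso_a = set(calls_a["isolate"].unique())
    iso_b = set(calls_b["isolate"].unique())
    if iso_a != iso_b:
        raise ValueError(
            f"caller isolate sets differ: only-A={sorted(iso_a - iso_b)[:5]}, "
            f"only-B={sorted(iso_b - iso_a)[:5]}"
        )
    keys = ["isolate", "chrom", "pos", "genotype"]
    b_keys = calls_b.loc[calls_b["genotype"] != GT_MISSING, keys].copy()
    b_keys["isolate"] = b_keys["isolate"].astype(str)
    a = calls_a[calls_a["genotype"] != GT_MISSING].copy()
    a["isolate"] = a["isolate"].astype(str)
    out = a.merge(b_keys.drop_duplicates(), on=keys, how="inner")
    _log_filter("consensus_sites", len(calls_a), len(out))
    return out.reset_index(drop=True)


def mean_depth_per_isolate(calls: pd.DataFrame) -> dict[str, float]:
    """Mean coverage per isolate over its call entries."""
    return calls.groupby("isolate", observed=True)["depth"].mean().to_dict()


def depth_filter(
    calls: pd.DataFrame, isolate_mean_depth: dict[str, float], p: QCParams | None = None
) -> pd.DataFrame:
    """Keep entries with depth >= min_coverage and depth <= fold x isolate mean."""
    p = p or QCParams()
    validate_site_calls(calls)
    unknown = set(map(str, calls["isolate"].unique())) - set(isolate_mean_depth)
    if unknown:
        raise ValueError(f"no mean depth for isolates: {sorted(unknown)[:5]}")
    means = calls["isolate"].astype(str).map(isolate_mean_depth).to_numpy(float)
    depth = calls["depth"].to_numpy()
    keep = (depth >= p.min_coverage) & (depth <= p.max_depth_fold * means)
    out = calls[keep].reset_index(drop=True)
    _log_filter("depth_filter", len(calls), len(out))
    return out


def allele_support_filter(calls: pd.DataFrame, p: QCParams | None = None) -> pd.DataFrame:
    """Read-support rule: homozygous calls need >= hom_support of ref+alt reads
    on the called allele; heterozygous calls need >= het_support on the minor
    allele.  Entries with zero informative reads are set to missing.
    """
    p = p or QCParams()
    validate_site_calls(calls)
    out = calls.copy()
    ref = out["ref_reads"].to_numpy(float)
    alt = out["alt_reads"].to_numpy(float)
    total = ref + alt
    gt = out["genotype"].to_numpy()

    zero = (total == 0) & (gt != GT_MISSING)
    if zero.any():
        logger.warning("allele_support_filter: %d entries with zero informative reads set to missing", int(zero.sum()))
        out.loc[zero, "genotype"] = GT_MISSING
        gt = out["genotype"].to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        frac_ref = np.where(total > 0, ref / total, 0.0)
        frac_alt = np.where(total > 0, alt / total, 0.0)
    keep = np.ones(len(out), dtype=bool)
    keep[gt == "hom_ref"] = frac_ref[gt == "hom_ref"] >= p.hom_support
    keep[gt == "hom_alt"] = frac_alt[gt == "hom_alt"] >= p.hom_support
    het = gt == "het"
    keep[het] = np.minimum(frac_ref, frac_alt)[het] >= p.het_support
    res = out[keep].reset_index(drop=True)
    _log_filter("allele_support_filter", len(calls), len(res))
    return res


def site_calls_to_matrix(
    calls: pd.DataFrame, site_meta: pd.DataFrame, isolates: list[str]
) -> GenotypeMatrix:
    """Assemble a genotype matrix from retained calls; absent entries are missing.

    ``site_meta`` supplies (chrom, pos, ref, alt) for every site to emit.
    """
    site_meta = site_meta.sort_values(["chrom", "pos"]).reset_index(drop=True)
    site_idx = {(c, p): i for i, (c, p) in enumerate(zip(site_meta["chrom"], site_meta["pos"]))}
    iso_idx = {iso: j for j, iso in enumerate(isolates)}
    dosages = np.full((len(site_meta), len(isolates)), MISSING, dtype=np.int8)
    rows = calls["chrom"].astype(str).str.cat(calls["pos"].astype(str), sep=":")
    ii = np.array([site_idx.get((c, p), -1) for c, p in zip(calls["chrom"], calls["pos"])])
    jj = np.array([iso_idx.get(str(i), -1) for i in calls["isolate"]])
    dd = np.array([GT_TO_DOSAGE[g] for g in calls["genotype"]], dtype=np.int8)
    ok = (ii >= 0) & (jj >= 0)
    if not ok.all():
        raise ValueError(f"{int((~ok).sum())} call entries reference unknown sites or isolates ({rows[~ok].iloc[0]})")
    dosages[ii, jj] = dd
    return GenotypeMatrix(sites=site_meta, isolates=isolates, dosages=dosages)


# ---------------------------------------------------------------------------
# matrix-level filters


def missingness_filter(gm: GenotypeMatrix, p: QCParams | None = None) -> GenotypeMatrix:
    """Keep sites whose missing fraction is <= max_missing_frac."""
    p = p or QCParams()
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    frac = gm.missing_mask().mean(axis=1)
    keep = frac <= p.max_missing_frac
    _log_filter("missingness_filter", gm.n_sites, int(keep.sum()))
    return gm.take_sites(keep)


def maf_filter(gm: GenotypeMatrix, p: QCParams | None = None) -> GenotypeMatrix:
    """Keep sites with minor allele frequency >= maf_min over non-missing alleles."""
    p = p or QCParams()
    maf = gm.maf()
    all_missing = np.isnan(maf)
    if all_missing.any():
        logger.warning("maf_filter: %d all-missing sites removed", int(all_missing.sum()))
    keep = ~all_missing & (maf >= p.maf_min)
    _log_filter("maf_filter", gm.n_sites, int(keep.sum()))
    return gm.take_sites(keep)


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of rows over pairwise-complete columns."""
    M = ~np.isnan(X)
    Xz = np.where(M, X, 0.0)
    Mf = M.astype(float)
    n = Mf @ Mf.T
    Sx = Xz @ Mf.T
    Sy = Sx.T
    Sxy = Xz @ Xz.T
    Sxx = (Xz * Xz) @ Mf.T
    Syy = Sxx.T
    cov = n * Sxy - Sx * Sy
    var_prod = (n * Sxx - Sx * Sx) * (n * Syy - Sy * Sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(var_prod > 0, (cov * cov) / var_prod, 0.0)
    r2[n < 2] = 0.0
    return r2


def ld_prune(gm: GenotypeMatrix, p: QCParams | None = None) -> GenotypeMatrix:
    """Sliding-window LD pruning on alt-dosage vectors.

    Within each window (``ld_window`` sites, advanced by ``ld_step``), while
    any retained pair has r^2 > r2_max, the pair with the currently highest
    r^2 is resolved by removing its lower-MAF member (MAF tie: the later
    position goes).
    """
    p = p or QCParams()
    n = gm.n_sites
    if n == 0:
        return gm
    X = gm.dosages.astype(float)
    X[gm.dosages == MISSING] = np.nan
    maf = gm.maf()
    maf = np.where(np.isnan(maf), -1.0, maf)
    active = np.ones(n, dtype=bool)
    # windows slide over *retained* sites; sweep until no window removes
    # anything, so the retained set is a fixpoint (the filter is idempotent)
    changed = True
    while changed:
        changed = False
        survivors = np.flatnonzero(active)
        for start in range(0, survivors.size, p.ld_step):
            idx = survivors[start : start + p.ld_window]
            idx = idx[active[idx]]
            if idx.size < 2:
                continue
            r2 = _pairwise_r2(X[idx])
            np.fill_diagonal(r2, 0.0)
            local = np.ones(idx.size, dtype=bool)
            while True:
                masked = np.where(np.outer(local, local), r2, 0.0)
                flat = int(np.argmax(masked))
                i, j = divmod(flat, idx.size)
                if masked[i, j] <= p.r2_max:
                    break
                a, b = idx[i], idx[j]
                if maf[a] < maf[b]:
                    local[i] = False
                elif maf[b] < maf[a]:
                    local[j] = False
                else:
                    local[j if b > a else i] = False
            if (~local).any():
                active[idx[~local]] = False
                changed = True
    _log_filter("ld_prune", n, int(active.sum()))
    return gm.take_sites(active)


# ---------------------------------------------------------------------------
# drivers


def run_qc_cascade(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    site_meta: pd.DataFrame,
    isolates: list[str],
    p: QCParams | None = None,
    isolate_mean_depth: dict[str, float] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Caller consensus -> depth -> allele support -> matrix -> missingness.

    Returns the filtered matrix and a per-stage log of entry/site counts.
    """
    p = p or QCParams()
    log = []
    calls = consensus_sites(calls_a, calls_b)
    log.append(("consensus_sites", len(calls_a), len(calls)))
    means = isolate_mean_depth or mean_depth_per_isolate(calls_a)
    n_in = len(calls)
    calls = depth_filter(calls, means, p)
    log.append(("depth_filter", n_in, len(calls)))
    n_in = len(calls)
    calls = allele_support_filter(calls, p)
    log.append(("allele_support_filter", n_in, len(calls)))
    gm = site_calls_to_matrix(calls, site_meta, isolates)
    n_in = gm.n_sites
    gm = missingness_filter(gm, p)
    log.append(("missingness_filter", n_in, gm.n_sites))
    return gm, pd.DataFrame(log, columns=["filter", "n_in", "n_out"])


def structure_filters(gm: GenotypeMatrix, p: QCParams | None = None) -> GenotypeMatrix:
    """MAF filter then LD pruning — the preprocessing for PCA/ADMIXTURE-style analyses."""
    p = p or QCParams()
    return ld_prune(maf_filter(gm, p), p)
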